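"""Synthetic bounded-below quadratic SCF test problems with brute-force
reference minima.

The energy is the Hartree-Fock-form quadratic functional

    E(P) = sum_t Tr(H_t P_t) + 1/2 sum_k y_k^T W_k y_k,
    y_k[t] = Re sum_{blocks b of t} Tr(M_k[b] P_b),

built from random Hermitian channel matrices M_k and symmetric
positive-semidefinite per-channel coupling matrices W_k over the particle
types.  The Fock matrix F_b = H_b + sum_k (W_k y_k)[type(b)] M_k[b] is the
exact derivative of E with respect to the density, which is verified by
finite differences at construction.  Positive semidefiniteness of every
W_k, together with the compactness of the feasible set of densities,
keeps the energy bounded below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence
from typing import NamedTuple

import numpy as np
import scipy.optimize

from ._linalg import random_hermitian, random_unitary
from .core import SymmetryBlockSpec
from .diis import commutator_error, error_norm
from .occupations import aufbau_fill, density_from_orbitals

__all__ = [
    "ModelProblem",
    "make_quadratic_problem",
    "make_two_species_problem",
    "brute_force_reference",
    "BruteForceResult",
]


@dataclass
class ModelProblem:
    """Quadratic multi-species energy functional with its Fock evaluator."""

    specs: list[SymmetryBlockSpec]
    n_particles: dict[int, float]
    H: list[np.ndarray]
    channel_matrices: list[list[np.ndarray]]  # [channel][block]
    channel_weights: list[np.ndarray]  # [channel] -> T x T symmetric PSD
    scalar_field: str = "real"
    seed: int = 0

    @property
    def types(self) -> list[int]:
        return sorted({s.particle_type for s in self.specs})

    def _channel_traces(self, P: Sequence[np.ndarray]) -> list[np.ndarray]:
        types = self.types
        ys = []
        for M in self.channel_matrices:
            y = np.zeros(len(types))
            for b, spec in enumerate(self.specs):
                t = types.index(spec.particle_type)
                y[t] += float(np.trace(M[b] @ P[b]).real)
            ys.append(y)
        return ys

    def energy_complex(self, P: Sequence[np.ndarray]) -> complex:
        """Energy with the traces taken without discarding imaginary parts."""
        E = sum(np.trace(Hb @ Pb) for Hb, Pb in zip(self.H, self.P_as_list(P)))
        types = self.types
        for M, W in zip(self.channel_matrices, self.channel_weights):
            y = np.zeros(len(types), dtype=complex)
            for b, spec in enumerate(self.specs):
                t = types.index(spec.particle_type)
                y[t] += np.trace(M[b] @ P[b])
            E += 0.5 * (y @ W @ y)
        return complex(E)

    @staticmethod
    def P_as_list(P: Sequence[np.ndarray]) -> list[np.ndarray]:
        return list(P)

    def energy_from_density(self, P: Sequence[np.ndarray]) -> float:
        E = sum(
            float(np.trace(Hb @ Pb).real)
            for Hb, Pb in zip(self.H, P, strict=True)
        )
        for y, W in zip(self._channel_traces(P), self.channel_weights):
            E += 0.5 * float(y @ W @ y)
        return E

    def fock_from_density(self, P: Sequence[np.ndarray]) -> list[np.ndarray]:
        types = self.types
        F = [Hb.copy() for Hb in self.H]
        for M, W, y in zip(
            self.channel_matrices, self.channel_weights, self._channel_traces(P)
        ):
            coeff = W @ y
            for b, spec in enumerate(self.specs):
                t = types.index(spec.particle_type)
                F[b] = F[b] + coeff[t] * M[b]
        return F

    def evaluator(
        self, C: Sequence[np.ndarray], f: Sequence[np.ndarray]
    ) -> tuple[float, list[np.ndarray]]:
        """Fock-evaluator contract: (C, f) -> (E_total, F_blocks)."""
        P = [
            density_from_orbitals(Cb, fb) for Cb, fb in zip(C, f, strict=True)
        ]
        return self.energy_from_density(P), self.fock_from_density(P)

    def core_guess(self) -> list[np.ndarray]:
        """Core-Hamiltonian guess Fock matrices."""
        return [Hb.copy() for Hb in self.H]

    # -- construction-time validation ------------------------------------

    def check_fock_consistency(
        self, rng: np.random.Generator, step: float = 1e-6, atol: float = 1e-8
    ) -> None:
        """Central-difference check that F is the exact derivative of E."""
        complex_field = self.scalar_field == "complex"
        P = self.random_feasible_density(rng)
        F = self.fock_from_density(P)
        for b, spec in enumerate(self.specs):
            for _ in range(3):
                D = random_hermitian(rng, spec.dim, complex_field)
                Pp = [p.copy() for p in P]
                Pm = [p.copy() for p in P]
                Pp[b] = Pp[b] + step * D
                Pm[b] = Pm[b] - step * D
                fd = (
                    self.energy_from_density(Pp) - self.energy_from_density(Pm)
                ) / (2 * step)
                an = float(np.trace(F[b] @ D).real)
                if abs(fd - an) > atol * max(1.0, abs(an)):
                    raise AssertionError(
                        f"Fock derivative check failed in block {b}: "
                        f"{fd} vs {an}"
                    )

    def random_feasible_density(
        self, rng: np.random.Generator
    ) -> list[np.ndarray]:
        """Random density with eigenvalues in [0, f_max] and correct traces."""
        complex_field = self.scalar_field == "complex"
        occ_by_type: dict[int, list[np.ndarray]] = {}
        for t in self.types:
            idx = [b for b, s in enumerate(self.specs) if s.particle_type == t]
            dims = [self.specs[b].dim for b in idx]
            fmax = [self.specs[b].f_max for b in idx]
            f = [rng.uniform(0.0, fm, d) for d, fm in zip(dims, fmax)]
            total = sum(float(np.sum(x)) for x in f)
            target = self.n_particles[t]
            # iterative rescale with clipping keeps 0 <= f <= f_max
            for _ in range(200):
                total = sum(float(np.sum(x)) for x in f)
                if abs(total - target) < 1e-13 * max(1.0, target):
                    break
                scale = target / max(total, 1e-300)
                f = [
                    np.clip(x * scale, 0.0, fm)
                    for x, fm in zip(f, fmax, strict=True)
                ]
            occ_by_type[t] = f
        P = []
        for b, spec in enumerate(self.specs):
            idx = [
                i
                for i, s in enumerate(self.specs)
                if s.particle_type == spec.particle_type
            ]
            f = occ_by_type[spec.particle_type][idx.index(b)]
            U = random_unitary(rng, spec.dim, complex_field)
            P.append((U * f) @ U.conj().T)
        return P

    def check_bounded(
        self, rng: np.random.Generator, n_samples: int = 200
    ) -> float:
        """Sample feasible densities; return the lowest energy seen.

        Raises if any sample is non-finite (the feasible set is compact, so
        a finite floor always exists for the continuous quadratic energy)."""
        lo = math.inf
        for _ in range(n_samples):
            E = self.energy_from_density(self.random_feasible_density(rng))
            if not math.isfinite(E):
                raise AssertionError("non-finite energy on the feasible set")
            lo = min(lo, E)
        return lo


def _gapped_core(
    rng: np.random.Generator, dim: int, n_occ: int, complex_field: bool
) -> np.ndarray:
    """Random Hermitian with a guaranteed spectral gap after level n_occ."""
    levels = np.sort(rng.uniform(-2.0, 2.0, dim))
    if 0 < n_occ < dim:
        gap = levels[n_occ] - levels[n_occ - 1]
        if gap < 0.5:
            levels[n_occ:] += 0.5 - gap
    U = random_unitary(rng, dim, complex_field)
    return (U * levels) @ U.conj().T


def _aufbau_consistent(
    problem: ModelProblem,
    rng: np.random.Generator,
    n_starts: int = 16,
    gap_min: float = 1e-2,
    tol: float = 1e-6,
) -> bool:
    """Check that the idempotent-manifold minimum is an Aufbau state.

    The positive-semidefinite couplings make the energy convex over the
    convex hull of feasible densities, so an Aufbau-consistent idempotent
    minimizer with a positive frontier gap is also the global minimum over
    all fractional occupations; problems failing this check fall outside
    the Aufbau iteration's applicability and are rejected at generation.
    """
    patterns = _aufbau_pattern(problem)
    complex_field = problem.scalar_field == "complex"
    best_E = math.inf
    best_P: list[np.ndarray] | None = None
    starts: list[list[np.ndarray]] = []
    core = []
    for b, spec in enumerate(problem.specs):
        _, v = np.linalg.eigh(problem.H[b])
        f = np.sort(_pattern_for_block(problem, patterns, b))[::-1]
        core.append((v * f) @ v.conj().T)
    starts.append(core)
    for _ in range(n_starts):
        P = []
        for b, spec in enumerate(problem.specs):
            U = random_unitary(rng, spec.dim, complex_field)
            f = np.sort(_pattern_for_block(problem, patterns, b))[::-1]
            P.append((U * f) @ U.conj().T)
        starts.append(P)
    for P0 in starts:
        E, P = _descent(problem, P0, patterns)
        if E < best_E:
            best_E, best_P = E, P
    F = problem.fock_from_density(best_P)
    # rebuild the Aufbau density from the minimizer's Fock matrices
    types = problem.types
    eigs = [np.linalg.eigh(Fb) for Fb in F]
    P_aufbau: list[np.ndarray | None] = [None] * len(problem.specs)
    for t in types:
        idx = [b for b, s in enumerate(problem.specs) if s.particle_type == t]
        occ = aufbau_fill(
            [eigs[b][0] for b in idx],
            [problem.specs[b].f_max for b in idx],
            problem.n_particles[t],
        )
        # frontier gap between the highest filled and lowest empty level
        levels = np.concatenate([eigs[b][0] for b in idx])
        fills = np.concatenate(occ)
        filled = levels[fills > 1e-12]
        empty = levels[fills < 1e-12]
        if filled.size and empty.size and np.min(empty) - np.max(filled) < gap_min:
            return False
        for b, f in zip(idx, occ, strict=True):
            w, v = eigs[b]
            P_aufbau[b] = (v * f) @ v.conj().T
    dev = sum(
        float(np.linalg.norm(Pa - Pb))
        for Pa, Pb in zip(P_aufbau, best_P, strict=True)
    )
    return dev < tol * max(1.0, sum(np.linalg.norm(p) for p in best_P))


def _pattern_for_block(
    problem: ModelProblem, patterns: dict[int, list[np.ndarray]], b: int
) -> np.ndarray:
    spec = problem.specs[b]
    idx = [
        i for i, s in enumerate(problem.specs)
        if s.particle_type == spec.particle_type
    ]
    return patterns[spec.particle_type][idx.index(b)]


def make_quadratic_problem(
    dim: int,
    n_occ_pairs: int,
    strength: float,
    field: str = "real",
    seed: int = 0,
    n_channels: int | None = None,
    ensure_aufbau: bool = True,
    max_attempts: int = 50,
) -> ModelProblem:
    """Single-type, single-block quadratic problem with f_max = 2.

    ``strength`` scales the positive channel weights; at 0 the Fock matrix
    is density independent and one Roothaan step solves the problem.  With
    ``ensure_aufbau`` (the default) instances whose ground state is not an
    Aufbau configuration are rejected and deterministically resampled, so
    every returned problem lies within the Aufbau iteration's domain of
    applicability; the draw is still a pure function of the seed.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if not 0 <= 2 * n_occ_pairs <= 2 * dim:
        raise ValueError("infeasible occupation")
    complex_field = field == "complex"
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        H = _gapped_core(rng, dim, n_occ_pairs, complex_field)
        k = n_channels if n_channels is not None else dim
        Ms, Ws = [], []
        for _ in range(k):
            M = random_hermitian(rng, dim, complex_field)
            M /= np.linalg.norm(M)
            Ms.append([M])
            w = strength * rng.uniform(0.5, 1.5) / max(k, 1)
            Ws.append(np.array([[w]]))
        problem = ModelProblem(
            specs=[SymmetryBlockSpec(0, "a", dim, 2.0)],
            n_particles={0: 2.0 * n_occ_pairs},
            H=[H],
            channel_matrices=Ms,
            channel_weights=Ws,
            scalar_field=field,
            seed=seed,
        )
        check_rng = np.random.default_rng([seed, attempt, 10_000])
        problem.check_fock_consistency(check_rng)
        if not ensure_aufbau or _aufbau_consistent(problem, check_rng):
            return problem
    raise RuntimeError(
        f"no Aufbau-consistent instance found in {max_attempts} attempts"
    )


def make_two_species_problem(
    dims: Sequence[int],
    n_particles: Sequence[float],
    intra_strengths: Sequence[float],
    inter_strength: float,
    seed: int = 0,
    sign: int = -1,
    field: str = "real",
    n_channels: int | None = None,
    ensure_aufbau: bool = True,
    max_attempts: int = 50,
) -> ModelProblem:
    """Coupled two-species quadratic problem (electron-proton-like).

    Each channel carries a Hermitian matrix per species and a 2x2 symmetric
    positive-definite weight matrix; the off-diagonal coupling weight has
    the requested sign and its magnitude is capped below the geometric mean
    of the intra weights, which keeps every channel PSD and the energy
    bounded below (verified by sampling at construction).
    """
    if len(dims) != 2:
        raise ValueError("exactly two particle types expected")
    complex_field = field == "complex"
    f_max = [2.0, 1.0]
    n_occ = [
        int(np.ceil(n / fm)) for n, fm in zip(n_particles, f_max, strict=True)
    ]
    for attempt in range(max_attempts):
        rng = np.random.default_rng([seed, attempt])
        H = [
            _gapped_core(rng, d, min(k, d - 1) or 1, complex_field)
            for d, k in zip(dims, n_occ, strict=True)
        ]
        nch = n_channels if n_channels is not None else max(dims)
        Ms, Ws = [], []
        for _ in range(nch):
            M = []
            for d in dims:
                Mb = random_hermitian(rng, d, complex_field)
                M.append(Mb / np.linalg.norm(Mb))
            w0 = intra_strengths[0] * rng.uniform(0.5, 1.5) / nch
            w1 = intra_strengths[1] * rng.uniform(0.5, 1.5) / nch
            v = sign * inter_strength * rng.uniform(0.5, 1.0) / nch
            cap = 0.95 * math.sqrt(w0 * w1)
            v = float(np.clip(v, -cap, cap))
            Ms.append(M)
            Ws.append(np.array([[w0, v], [v, w1]]))
        specs = [
            SymmetryBlockSpec(0, "e", dims[0], f_max[0]),
            SymmetryBlockSpec(1, "p", dims[1], f_max[1]),
        ]
        problem = ModelProblem(
            specs=specs,
            n_particles={0: float(n_particles[0]), 1: float(n_particles[1])},
            H=H,
            channel_matrices=Ms,
            channel_weights=Ws,
            scalar_field=field,
            seed=seed,
        )
        check_rng = np.random.default_rng([seed, attempt, 10_000])
        problem.check_fock_consistency(check_rng)
        problem.check_bounded(check_rng, n_samples=50)
        if not ensure_aufbau or _aufbau_consistent(problem, check_rng):
            return problem
    raise RuntimeError(
        f"no Aufbau-consistent instance found in {max_attempts} attempts"
    )


class BruteForceResult(NamedTuple):
    E_min: float
    P_min: list[np.ndarray]
    grad_norm: float


def _aufbau_pattern(problem: ModelProblem) -> dict[int, list[np.ndarray]]:
    """Occupation patterns (descending) per type used on the search manifold."""
    out: dict[int, list[np.ndarray]] = {}
    for t in problem.types:
        idx = [b for b, s in enumerate(problem.specs) if s.particle_type == t]
        # fill against a flat spectrum: block order, deterministic
        dims = [problem.specs[b].dim for b in idx]
        fmax = [problem.specs[b].f_max for b in idx]
        energies = [np.arange(d, dtype=float) for d in dims]
        out[t] = aufbau_fill(energies, fmax, problem.n_particles[t])
    return out


def _project(
    M: np.ndarray, f_pattern: np.ndarray
) -> np.ndarray:
    """Closest density with the given (descending) occupation spectrum."""
    w, v = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    return (v * f_pattern) @ v.conj().T


def _descent(
    problem: ModelProblem,
    P: list[np.ndarray],
    patterns: dict[int, list[np.ndarray]],
    max_iter: int = 400,
) -> tuple[float, list[np.ndarray]]:
    """Monotone projected-gradient descent on the fixed-occupation manifold."""
    types = problem.types
    pat: list[np.ndarray] = []
    for b, spec in enumerate(problem.specs):
        idx = [
            i for i, s in enumerate(problem.specs)
            if s.particle_type == spec.particle_type
        ]
        pat.append(np.sort(patterns[spec.particle_type][idx.index(b)])[::-1])
    E = problem.energy_from_density(P)
    eta = 0.5
    for _ in range(max_iter):
        F = problem.fock_from_density(P)
        improved = False
        while eta > 1e-14:
            P_try = [
                _project(Pb - eta * Fb, pb)
                for Pb, Fb, pb in zip(P, F, pat, strict=True)
            ]
            E_try = problem.energy_from_density(P_try)
            if E_try < E - 1e-15 * max(1.0, abs(E)):
                P, E = P_try, E_try
                eta = min(eta * 1.5, 10.0)
                improved = True
                break
            eta *= 0.5
        if not improved:
            break
    return E, P


def _angle_scan_reference(
    problem: ModelProblem, step: float = 1e-4
) -> tuple[float, list[np.ndarray]]:
    """Dense scan over the occupied-subspace rotation for dim-2 rank-1 cases."""
    spec = problem.specs[0]
    f_occ = problem.n_particles[0]
    complex_field = problem.scalar_field == "complex"

    def density(theta: float, phi: float = 0.0) -> list[np.ndarray]:
        u = np.array([math.cos(theta), math.sin(theta)], dtype=complex)
        u[1] *= np.exp(1j * phi)
        if not complex_field:
            u = u.real
        return [f_occ * np.outer(u, u.conj())]

    if complex_field:
        thetas = np.arange(0.0, math.pi, 1e-2)
        phis = np.arange(0.0, 2 * math.pi, 1e-2)
        best = (math.inf, 0.0, 0.0)
        for th in thetas:
            for ph in phis:
                E = problem.energy_from_density(density(th, ph))
                if E < best[0]:
                    best = (E, th, ph)
        res = scipy.optimize.minimize(
            lambda x: problem.energy_from_density(density(x[0], x[1])),
            [best[1], best[2]],
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14},
        )
        return float(res.fun), density(res.x[0], res.x[1])
    thetas = np.arange(0.0, math.pi, step)
    energies = np.array(
        [problem.energy_from_density(density(t)) for t in thetas]
    )
    t0 = thetas[int(np.argmin(energies))]
    res = scipy.optimize.minimize_scalar(
        lambda t: problem.energy_from_density(density(t)),
        bracket=(t0 - step, t0, t0 + step),
        options={"xtol": 1e-14},
    )
    return float(res.fun), density(float(res.x))


def brute_force_reference(
    problem: ModelProblem,
    n_restarts: int = 100,
    seed: int = 12345,
) -> BruteForceResult:
    """Reference minimum over Aufbau-style densities, by independent search.

    Uses a dense rotation-angle scan with local refinement for single-block
    dim-2 rank-1 problems, and random-restart monotone projected-gradient
    descent on the fixed-occupation manifold otherwise (the angle-scan cases
    also run the descent and keep the better result).
    """
    rng = np.random.default_rng(seed)
    patterns = _aufbau_pattern(problem)
    complex_field = problem.scalar_field == "complex"

    best_E = math.inf
    best_P: list[np.ndarray] | None = None

    single_block_dim2 = (
        len(problem.specs) == 1
        and problem.specs[0].dim == 2
        and 0.0 < problem.n_particles[problem.types[0]] <= problem.specs[0].f_max
    )
    if single_block_dim2:
        best_E, best_P = _angle_scan_reference(problem)

    # deterministic start: Aufbau solution of the core Hamiltonian
    starts: list[list[np.ndarray]] = []
    core_start = []
    for b, spec in enumerate(problem.specs):
        w, v = np.linalg.eigh(problem.H[b])
        idx = [
            i for i, s in enumerate(problem.specs)
            if s.particle_type == spec.particle_type
        ]
        f = np.sort(patterns[spec.particle_type][idx.index(b)])[::-1]
        core_start.append((v * f) @ v.conj().T)
    starts.append(core_start)
    for _ in range(n_restarts):
        P = []
        for b, spec in enumerate(problem.specs):
            U = random_unitary(rng, spec.dim, complex_field)
            idx = [
                i for i, s in enumerate(problem.specs)
                if s.particle_type == spec.particle_type
            ]
            f = np.sort(patterns[spec.particle_type][idx.index(b)])[::-1]
            P.append((U * f) @ U.conj().T)
        starts.append(P)

    for P0 in starts:
        E, P = _descent(problem, P0, patterns)
        if E < best_E:
            best_E, best_P = E, P

    F = problem.fock_from_density(best_P)
    errs = [commutator_error(Fb, Pb) for Fb, Pb in zip(F, best_P, strict=True)]
    return BruteForceResult(
        E_min=float(best_E), P_min=best_P, grad_norm=error_norm(errs, "max")
    )
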