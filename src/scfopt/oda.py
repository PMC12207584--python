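"""Optimal damping: density-mixing line searches with cubic interpolation
and natural-orbital extraction.

A rejected Roothaan step from the best iterate is relaxed by searching the
energy along the convex mixture (1 - lam) P0 + lam P1, per particle type.
Endpoint energies and the analytic gradients dE/dlam = Tr F (P1 - P0)
afford a cubic fit whose interior minimum supplies the accepted mixture;
the mixed density is eigendecomposed into natural orbitals and occupations
before the single follow-up Fock evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Callable, Sequence

import numpy as np

from .core import BlockState, IterationEntry, SymmetryBlockSpec

__all__ = [
    "MixingState",
    "cubic_line_minimum",
    "mixing_direction",
    "oda_relax",
    "mixed_state",
]

logger = logging.getLogger("scfopt")

EntryFactory = Callable[[list[BlockState]], IterationEntry]


@dataclass
class MixingState:
    """Endpoint data of one density-mixing search."""

    P0: list[np.ndarray]
    F0: list[np.ndarray]
    E0: float
    P1: list[np.ndarray]
    F1: list[np.ndarray]
    E1: float
    lam: np.ndarray | None = None


def cubic_line_minimum(
    E0: float, dE0: float, E1: float, dE1: float
) -> float | None:
    """Interior minimum of the cubic through (E(0), E'(0), E(1), E'(1)).

    Returns the local minimum in (0, 1) with the lower fitted value when two
    exist, or ``None`` when the fit has no interior minimum (degenerate fits
    fall through to the quadratic/linear cases).
    """
    # E(x) = a x^3 + b x^2 + c x + d
    d = float(E0)
    c = float(dE0)
    a = dE1 + dE0 - 2.0 * (E1 - E0)
    b = 3.0 * (E1 - E0) - 2.0 * dE0 - dE1
    scale = max(abs(a), abs(b), abs(c), 1e-300)
    if abs(a) <= 1e-12 * scale:
        # quadratic (or lower) fit
        if b > 0.0:
            lam = -c / (2.0 * b)
            if 0.0 < lam < 1.0:
                return lam
        return None
    # stationary points of the cubic
    disc = b * b - 3.0 * a * c
    if disc < 0.0:
        return None
    sq = np.sqrt(disc)
    roots = [(-b - sq) / (3.0 * a), (-b + sq) / (3.0 * a)]
    minima = [
        r for r in roots if 0.0 < r < 1.0 and (6.0 * a * r + 2.0 * b) > 0.0
    ]
    if not minima:
        return None
    value = lambda x: a * x**3 + b * x**2 + c * x + d
    return min(minima, key=value)


def mixing_direction(gradients: Sequence[float]) -> np.ndarray | None:
    """Boundary-scaled trial mixing factors from the per-type gradients.

    s_i = max(0, -g_i), lam = s / max_i s_i; ``None`` signals that no type
    offers a descent direction (all gradients nonnegative)."""
    g = np.asarray(gradients, dtype=float)
    s = np.maximum(0.0, -g)
    if np.max(s) <= 0.0:
        return None
    return s / np.max(s)


def _per_type_gradients(
    F_ref: Sequence[np.ndarray],
    P0: Sequence[np.ndarray],
    P1: Sequence[np.ndarray],
    specs: Sequence[SymmetryBlockSpec],
    types: Sequence[int],
) -> np.ndarray:
    """g_t = Re sum_{blocks of t} Tr F_ref (P1 - P0)."""
    g = np.zeros(len(types))
    for b, spec in enumerate(specs):
        t = types.index(spec.particle_type)
        g[t] += float(np.trace(F_ref[b] @ (P1[b] - P0[b])).real)
    return g


def mixed_state(
    best: IterationEntry,
    candidate: IterationEntry,
    lam: np.ndarray,
    specs: Sequence[SymmetryBlockSpec],
    types: Sequence[int],
) -> list[BlockState]:
    """Natural-orbital state of the per-type mixture (1 - lam) P0 + lam P1.

    The mixed density of each block is eigendecomposed; eigenvalues become
    the occupations (clamped to [0, f_max] and rescaled per particle type to
    conserve the trace), and the orbitals are ordered by ascending
    expectation value against the best iterate's Fock matrix so downstream
    Aufbau logic sees a consistent energy ordering.
    """
    raw: list[tuple[np.ndarray, np.ndarray]] = []
    for b, spec in enumerate(specs):
        t = types.index(spec.particle_type)
        Pmix = (1.0 - lam[t]) * best.P[b] + lam[t] * candidate.P[b]
        w, v = np.linalg.eigh(Pmix)
        w = np.clip(w, 0.0, spec.f_max)
        raw.append((w, v))
    # rescale per type to conserve the particle count
    for t_idx, t in enumerate(types):
        target = sum(
            float(np.sum(best.states[b].f))
            for b, spec in enumerate(specs)
            if spec.particle_type == t
        )
        total = sum(
            float(np.sum(raw[b][0]))
            for b, spec in enumerate(specs)
            if spec.particle_type == t
        )
        if total > 0.0 and target > 0.0:
            scale = target / total
            for b, spec in enumerate(specs):
                if spec.particle_type == t:
                    raw[b] = (raw[b][0] * scale, raw[b][1])
    states: list[BlockState] = []
    for b, spec in enumerate(specs):
        w, v = raw[b]
        e_exp = np.real(np.einsum("ij,jk,ki->i", v.conj().T, best.F[b], v))
        order = np.argsort(e_exp, kind="stable")
        states.append(
            BlockState(C=v[:, order], E_orb=e_exp[order], f=w[order])
        )
    return states


def oda_relax(
    best: IterationEntry,
    candidate: IterationEntry,
    make_entry: EntryFactory,
    specs: Sequence[SymmetryBlockSpec],
    max_bisections: int = 5,
) -> IterationEntry:
    """Relax a rejected Roothaan step by an optimally damped density mixture.

    ``candidate`` must be the evaluated iterate built from the orbitals that
    diagonalize the best iterate's Fock matrices.  If it already lowers the
    energy it is accepted unchanged.  Otherwise the per-type trial mixing
    direction is built from the gradients, the trial point is evaluated
    (for a single particle type the trial point is the candidate itself),
    and a cubic fit along the segment supplies the accepted mixture; if the
    fit yields no interior minimum the mixing factor is bisected a few
    times, returning the best iterate found.

    ``make_entry`` evaluates the Fock functional at a list of block states
    and returns a complete history entry.
    """
    E0 = best.E_total
    if candidate.E_total < E0:
        return candidate
    types = sorted({s.particle_type for s in specs})
    g = _per_type_gradients(best.F, best.P, candidate.P, specs, types)
    lam = mixing_direction(g)
    if lam is None:
        logger.warning("no descent direction in the density mixture; keeping the Roothaan step")
        return candidate
    if len(types) == 1:
        trial = candidate
        lam = np.array([1.0])
    else:
        trial = make_entry(mixed_state(best, candidate, lam, specs, types))
        if trial.E_total < E0:
            return trial
    dE0 = float(lam @ g)
    g1 = _per_type_gradients(trial.F, best.P, candidate.P, specs, types)
    dE1 = float(lam @ g1)
    mu = cubic_line_minimum(E0, dE0, trial.E_total, dE1)
    if mu is not None:
        return make_entry(mixed_state(best, candidate, mu * lam, specs, types))
    # no interior minimum predicted: bisect toward the best iterate
    best_found = trial
    frac = 1.0
    for _ in range(max_bisections):
        frac /= 2.0
        probe = make_entry(mixed_state(best, candidate, frac * lam, specs, types))
        if probe.E_total < best_found.E_total:
            best_found = probe
        if probe.E_total < E0:
            return probe
    return best_found
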