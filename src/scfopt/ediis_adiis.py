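"""EDIIS and ADIIS proxy-energy objectives on the unit simplex, the
pairwise-line-search minimizer, and MESA candidate selection.

Both objectives are quadratic forms f(x) = 1/2 x^T A x + b.x + const with
symmetric A; they are minimized under x_i >= 0, sum x_i = 1 by repeated
exact line searches toward the simplex vertices (a Powell-style scheme).
The unconstrained square-variable reparametrization is deliberately not
used: it destroys convexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from ._linalg import block_diff_norm, block_inner

__all__ = [
    "SimplexQuadratic",
    "ediis_objective",
    "adiis_objective",
    "minimize_on_simplex",
    "mesa_select",
]

BlockSet = Sequence[np.ndarray]


@dataclass
class SimplexQuadratic:
    """f(x) = 1/2 x^T A x + b.x + const with A symmetrized on construction."""

    A: np.ndarray
    b: np.ndarray
    const: float = 0.0

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        self.A = (A + A.T) / 2.0
        self.b = np.asarray(self.b, dtype=float)
        if self.A.shape != (self.b.size, self.b.size):
            raise ValueError("A and b dimensions disagree")

    @property
    def m(self) -> int:
        return self.b.size

    def __call__(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        return float(0.5 * x @ self.A @ x + self.b @ x + self.const)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.A @ np.asarray(x, dtype=float) + self.b


def ediis_objective(
    energies: Sequence[float],
    F_history: Sequence[BlockSet],
    P_history: Sequence[BlockSet],
) -> SimplexQuadratic:
    """Energy-interpolation objective for the convex density combination.

    f(c) = sum_i c_i E_i - 1/4 c.X.c with
    X_ij = Re <F_i - F_j | P_i - P_j> accumulated over all blocks of all
    particle types.  The coefficient makes f(c) coincide exactly with the
    true energy E(sum_i c_i P_i) whenever the energy is a quadratic
    functional of the density (the Hartree-Fock form), for every simplex c.
    """
    m = len(energies)
    X = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            dF = [a - b for a, b in zip(F_history[i], F_history[j], strict=True)]
            dP = [a - b for a, b in zip(P_history[i], P_history[j], strict=True)]
            X[i, j] = X[j, i] = block_inner(dF, dP)
    return SimplexQuadratic(A=-X / 2.0, b=np.asarray(energies, dtype=float))


def adiis_objective(
    energies: Sequence[float],
    F_history: Sequence[BlockSet],
    P_history: Sequence[BlockSet],
    ref_index: int,
) -> SimplexQuadratic:
    """Augmented objective expanded around the reference iterate ``n``:

    f(c) = E_n + 2 sum_i c_i Re<P_i - P_n | F_n>
               + sum_ij c_i c_j Re<P_i - P_n | F_j - F_n>

    with inner products accumulated over particle types.  For quadratic
    (Hartree-Fock-form) energies this equals 2 E(sum c_i P_i) - E_n, so its
    simplex minimizer coincides with the energy-interpolation one.
    """
    m = len(energies)
    if not 0 <= ref_index < m:
        raise ValueError(f"reference index {ref_index} out of range")
    Fn = F_history[ref_index]
    Pn = P_history[ref_index]
    dP = [
        [a - b for a, b in zip(P_history[i], Pn, strict=True)] for i in range(m)
    ]
    dF = [
        [a - b for a, b in zip(F_history[i], Fn, strict=True)] for i in range(m)
    ]
    b = np.array([2.0 * block_inner(dP[i], Fn) for i in range(m)])
    M = np.empty((m, m))
    for i in range(m):
        for j in range(m):
            M[i, j] = block_inner(dP[i], dF[j])
    return SimplexQuadratic(A=M + M.T, b=b, const=float(energies[ref_index]))


def _start_points(m: int) -> list[np.ndarray]:
    pts = [np.eye(m)[k] for k in range(m)]
    pts.append(np.full(m, 1.0 / m))
    for k in range(m):
        x = np.full(m, 1.0 / (m + 2))
        x[k] = 3.0 / (m + 2)
        pts.append(x)
    return pts


def minimize_on_simplex(
    q: SimplexQuadratic,
    tol: float = 1e-12,
    max_sweeps: int | None = None,
) -> np.ndarray:
    """Minimize a quadratic form on the unit simplex by pairwise searches.

    Starting from the best of the vertices, the centroid and slightly
    offset points, the iterate is repeatedly moved along segments
    x <- (1 - lam) x + lam e_i toward each vertex, with the exact
    minimizing lam of the one-dimensional quadratic restriction clamped to
    (0, 1].  Sweeps stop when f no longer changes appreciably.
    """
    if not (np.all(np.isfinite(q.A)) and np.all(np.isfinite(q.b))):
        raise ValueError("non-finite entries in the simplex quadratic")
    m = q.m
    if m == 1:
        return np.array([1.0])
    if max_sweeps is None:
        max_sweeps = 10 * m

    def sweep_from(x0: np.ndarray) -> tuple[float, np.ndarray]:
        x = x0.copy()
        fx = q(x)
        for _ in range(max_sweeps):
            f_prev = fx
            for i in range(m):
                d = -x.copy()
                d[i] += 1.0  # e_i - x
                g = float(d @ q.gradient(x))
                den = float(d @ q.A @ d)
                if den > 0.0:
                    lam = min(max(-g / den, 0.0), 1.0)
                elif g + 0.5 * den < 0.0:
                    # concave (or flat) restriction: the endpoint is lower
                    lam = 1.0
                else:
                    lam = 0.0
                if lam > 0.0:
                    x = (1.0 - lam) * x + lam * np.eye(m)[i]
                    # guard against drift off the simplex
                    x = np.clip(x, 0.0, None)
                    x /= x.sum()
                    fx = q(x)
            if abs(f_prev - fx) < tol * max(1.0, abs(fx)):
                break
        return fx, x

    # the objective need not be convex; polish every start and keep the best
    results = [sweep_from(x0) for x0 in _start_points(m)]
    return min(results, key=lambda r: r[0])[1]


def mesa_select(
    c_ediis: np.ndarray,
    c_adiis: np.ndarray,
    P_history: Sequence[BlockSet],
    P_current: BlockSet,
) -> tuple[str, np.ndarray]:
    """Minimal error sampling: pick the candidate whose interpolated density
    changes the current density least in Frobenius norm (over all blocks).
    Ties go to ADIIS."""

    def change(c: np.ndarray) -> float:
        mixed = [
            sum(ci * Pi[b] for ci, Pi in zip(c, P_history, strict=True))
            for b in range(len(P_current))
        ]
        return block_diff_norm(P_current, mixed)

    if change(np.asarray(c_ediis)) < change(np.asarray(c_adiis)):
        return "ediis", np.asarray(c_ediis)
    return "adiis", np.asarray(c_adiis)
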