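"""Pulay DIIS: commutator error metric, error norms, and the constrained
weight solve with Hamilton-Pulay damping, smallest-diagonal normalization
and Chupin-style restart screening.

The weights minimize ||sum_i c_i e_i||^2 subject to sum_i c_i = 1 via the
bordered linear system

    [ B  -1 ] [ c      ]   [  0 ]
    [-1^T  0 ] [ lambda ] = [ -1 ]

with B_ij = Re <e_i, e_j> accumulated over all blocks and particle types.
Weights may be negative (extrapolation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from ._linalg import block_inner

__all__ = [
    "DIISSystem",
    "commutator_error",
    "error_norm",
    "diis_weights",
    "weights_from_overlaps",
]

logger = logging.getLogger("scfopt")


@dataclass
class DIISSystem:
    """Screened, normalized and damped DIIS error-overlap system."""

    B: np.ndarray
    kept_indices: list[int]
    damping: float = 0.02
    delta_diis: float = 1e-4


def commutator_error(F: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Orbital-gradient error matrix e = FP - PF (anti-Hermitian)."""
    if F.shape != P.shape:
        raise ValueError(f"dimension mismatch: F {F.shape} vs P {P.shape}")
    return F @ P - P @ F


def error_norm(errors: Sequence[np.ndarray], kind: str = "rms") -> float:
    """DIIS error norm over all blocks.

    ``rms`` divides by the total element count over all blocks, so a
    single-block problem reduces to the ordinary matrix rms; ``max`` is the
    largest absolute element anywhere.
    """
    if not errors:
        raise ValueError("at least one error block required")
    if kind == "rms":
        sq = sum(float(np.sum(np.abs(e) ** 2)) for e in errors)
        n = sum(e.size for e in errors)
        return float(np.sqrt(sq / n))
    if kind == "max":
        return max(float(np.max(np.abs(e))) for e in errors)
    raise ValueError(f"unknown error norm kind {kind!r}")


def weights_from_overlaps(
    B: np.ndarray,
    d: float = 0.02,
    delta_diis: float = 1e-4,
    latest: int | None = None,
    normalize: str = "smallest",
) -> np.ndarray:
    """Solve the constrained weight problem from a precomputed overlap matrix.

    Steps: screen out entries with ``delta_diis * B_ii > min_j B_jj`` (the
    latest entry is always retained), normalize B by its smallest kept
    diagonal (or the latest one when ``normalize='latest'``), multiply the
    diagonal by ``1 + d`` and solve the bordered system.  Screened-out
    entries receive weight 0; the weights of the kept set sum to one.
    """
    B = np.asarray(B, dtype=float)
    m = B.shape[0]
    if latest is None:
        latest = m - 1
    diag = np.diag(B)
    kept = [i for i in range(m) if delta_diis * diag[i] <= np.min(diag)]
    if latest not in kept:
        kept.append(latest)
        kept.sort()
    Bk = B[np.ix_(kept, kept)].copy()
    if normalize == "smallest":
        scale = float(np.min(np.diag(Bk)))
    elif normalize == "latest":
        scale = float(B[latest, latest])
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    if scale > 0.0:
        Bk /= scale
    k = len(kept)
    np.fill_diagonal(Bk, np.diag(Bk) * (1.0 + d))
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = Bk
    A[:k, k] = -1.0
    A[k, :k] = -1.0
    rhs = np.zeros(k + 1)
    rhs[k] = -1.0
    weights = np.zeros(m)
    try:
        sol = np.linalg.solve(A, rhs)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError("non-finite solution")
        weights[kept] = sol[:k]
    except np.linalg.LinAlgError:
        logger.warning("singular DIIS system; falling back to the latest iterate")
        weights[latest] = 1.0
    return weights


def build_overlaps(errors: Sequence[Sequence[np.ndarray]]) -> np.ndarray:
    """Gram matrix B_ij = Re sum_blocks Tr(e_i^H e_j) of the error sets."""
    m = len(errors)
    B = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            B[i, j] = B[j, i] = block_inner(errors[i], errors[j])
    return B


def diis_weights(
    errors: Sequence[Sequence[np.ndarray]],
    d: float = 0.02,
    delta_diis: float = 1e-4,
    latest: int | None = None,
    normalize: str = "smallest",
) -> np.ndarray:
    """DIIS weights for a history of per-block error-matrix sets."""
    if len(errors) == 0:
        raise ValueError("empty error history")
    B = build_overlaps(errors)
    return weights_from_overlaps(
        B, d=d, delta_diis=delta_diis, latest=latest, normalize=normalize
    )
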