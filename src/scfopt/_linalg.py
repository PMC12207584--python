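"""Small shared linear-algebra helpers.

All quantities live in an orthonormal orbital basis; per-block collections
are plain Python lists of ndarrays aligned with the block-spec list.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np

logger = logging.getLogger("scfopt")

#: relative Hermiticity/unitarity deviation that triggers a warning
HERMITICITY_WARN = 1e-10
#: relative deviation that is treated as an error
HERMITICITY_ERROR = 1e-6


def check_hermitian(M: np.ndarray, name: str = "matrix") -> None:
    """Validate that ``M`` is Hermitian relative to its own norm.

    Deviations above ``HERMITICITY_WARN`` log a warning; deviations above
    ``HERMITICITY_ERROR`` raise ``ValueError``.
    """
    scale = max(float(np.linalg.norm(M)), 1.0)
    dev = float(np.linalg.norm(M - M.conj().T)) / scale
    if dev > HERMITICITY_ERROR:
        raise ValueError(f"{name} is not Hermitian (relative deviation {dev:.3e})")
    if dev > HERMITICITY_WARN:
        logger.warning("%s deviates from Hermiticity by %.3e", name, dev)


def check_unitary(C: np.ndarray, name: str = "orbital matrix") -> None:
    """Validate ``C^H C = I`` relative to the matrix norm."""
    n = C.shape[1]
    scale = max(float(np.linalg.norm(C)), 1.0)
    dev = float(np.linalg.norm(C.conj().T @ C - np.eye(n))) / scale
    if dev > HERMITICITY_ERROR:
        raise ValueError(f"{name} is not unitary (relative deviation {dev:.3e})")
    if dev > HERMITICITY_WARN:
        logger.warning("%s deviates from unitarity by %.3e", name, dev)


def block_inner(a: Sequence[np.ndarray], b: Sequence[np.ndarray]) -> float:
    """Real trace inner product Re sum_b Tr(a_b^H b_b) accumulated over blocks."""
    return float(sum(np.vdot(x, y).real for x, y in zip(a, b, strict=True)))


def block_norm(a: Sequence[np.ndarray]) -> float:
    """Frobenius norm over all blocks, sqrt of the summed squared norms."""
    return float(np.sqrt(sum(float(np.linalg.norm(x)) ** 2 for x in a)))


def block_diff_norm(a: Sequence[np.ndarray], b: Sequence[np.ndarray]) -> float:
    """Frobenius norm of the blockwise difference ``a - b``."""
    return block_norm([x - y for x, y in zip(a, b, strict=True)])


def random_hermitian(rng: np.random.Generator, dim: int, complex_field: bool = False) -> np.ndarray:
    A = rng.standard_normal((dim, dim))
    if complex_field:
        A = A + 1j * rng.standard_normal((dim, dim))
    return (A + A.conj().T) / 2.0


def random_unitary(rng: np.random.Generator, dim: int, complex_field: bool = False) -> np.ndarray:
    A = rng.standard_normal((dim, dim))
    if complex_field:
        A = A + 1j * rng.standard_normal((dim, dim))
    Q, R = np.linalg.qr(A)
    # fix phases so the factorization is unique and Q well spread
    return Q * (np.diag(R) / np.abs(np.diag(R)))
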