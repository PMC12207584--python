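"""Construction of transformations X with X^H S X = I for reducing the
generalized Roothaan problem F C = S C E to the orthonormal-basis problem
the optimizer consumes.

Three routes are provided: symmetric orthogonalization (S^{-1/2}),
canonical orthogonalization with eigenvalue dropping for linearly
dependent bases, and a greedy pivoted-Cholesky preselection of a
well-conditioned basis subset before the conventional orthonormalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "Orthogonalizer",
    "symmetric_x",
    "canonical_x",
    "cholesky_pivot_select",
    "generalized_eigh",
]


@dataclass
class Orthogonalizer:
    X: np.ndarray
    method: str
    dropped: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.X.shape[1]


def symmetric_x(S: np.ndarray) -> Orthogonalizer:
    """X = S^{-1/2} via eigendecomposition; requires S positive definite."""
    w, v = scipy.linalg.eigh(S)
    if np.min(w) <= 0.0:
        raise np.linalg.LinAlgError(
            f"overlap matrix has a nonpositive eigenvalue ({np.min(w):.3e}); "
            "use canonical orthogonalization"
        )
    X = (v / np.sqrt(w)) @ v.conj().T
    return Orthogonalizer(X=X, method="symmetric")


def canonical_x(S: np.ndarray, drop_threshold: float = 1e-5) -> Orthogonalizer:
    """Columns u_i / sqrt(s_i) for eigenpairs with s_i > drop_threshold."""
    w, v = scipy.linalg.eigh(S)
    keep = w > drop_threshold
    if not np.any(keep):
        raise np.linalg.LinAlgError(
            "all overlap eigenvalues below the drop threshold"
        )
    dropped = [float(x) for x in w[~keep]]
    # largest eigenvalues first, matching the usual convention
    wk = w[keep][::-1]
    vk = v[:, keep][:, ::-1]
    return Orthogonalizer(X=vk / np.sqrt(wk), method="canonical", dropped=dropped)


def cholesky_pivot_select(
    S: np.ndarray, pivot_threshold: float = 1e-8
) -> list[int]:
    """Greedy pivoted Cholesky on S; returns the selected basis indices.

    Pivoting stops when the largest remaining diagonal residual falls below
    ``pivot_threshold`` times the largest initial diagonal (a relative,
    scale-invariant criterion).
    """
    S = np.asarray(S)
    n = S.shape[0]
    d = np.real(np.diag(S)).astype(float).copy()
    scale = float(np.max(d))
    if scale <= 0.0:
        return []
    L = np.zeros((n, n), dtype=S.dtype)
    selected: list[int] = []
    for k in range(n):
        p = int(np.argmax(d))
        if d[p] < pivot_threshold * scale:
            break
        selected.append(p)
        L[:, k] = (S[:, p] - L[:, :k] @ L[p, :k].conj()) / np.sqrt(d[p])
        d = d - np.abs(L[:, k]) ** 2
        d[selected] = -np.inf  # never re-pick a pivot
    return sorted(selected)


def generalized_eigh(
    F: np.ndarray, S: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Solve F C = S C E through the orthonormalizing transformation X.

    Returns ascending eigenvalues and coefficients C = X U where U
    diagonalizes X^H F X.
    """
    w, U = np.linalg.eigh(X.conj().T @ F @ X)
    return w, X @ U
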