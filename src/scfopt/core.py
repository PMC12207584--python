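"""Domain types and the lowest-energy-first iteration history stack.

The stack keeps the best iterate alive at position 0 under all push,
eviction and cleanup operations; the remaining iterates are ordered by
decreasing iteration index and the oldest nonminimal entry is evicted
when capacity is exceeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np

from ._linalg import block_diff_norm, check_hermitian, check_unitary

__all__ = [
    "SymmetryBlockSpec",
    "BlockState",
    "IterationEntry",
    "HistoryStack",
    "push_entry",
    "cleanup_history",
    "stagnation_check",
]


@dataclass(frozen=True)
class SymmetryBlockSpec:
    """Static description of one (particle type, symmetry) block."""

    particle_type: int
    block_label: str
    dim: int
    f_max: float

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError(f"block dimension must be >= 1, got {self.dim}")
        if not self.f_max > 0:
            raise ValueError(f"maximal occupation must be > 0, got {self.f_max}")


@dataclass
class BlockState:
    """Orbitals, orbital energies and occupations of one symmetry block."""

    C: np.ndarray
    E_orb: np.ndarray
    f: np.ndarray

    def validate(self, spec: SymmetryBlockSpec | None = None) -> None:
        check_unitary(self.C, "orbital coefficients")
        if spec is not None:
            if np.any(self.f < -1e-10) or np.any(self.f > spec.f_max + 1e-10):
                raise ValueError("occupations outside [0, f_max]")


@dataclass
class IterationEntry:
    """One history record: per-block states, Fock, density, error matrices."""

    states: list[BlockState]
    F: list[np.ndarray]
    P: list[np.ndarray]
    E_total: float
    err: list[np.ndarray]
    iteration_index: int

    def validate(self) -> None:
        if not math.isfinite(self.E_total):
            raise ValueError(f"non-finite total energy {self.E_total}")
        for i, (Fb, Pb) in enumerate(zip(self.F, self.P, strict=True)):
            check_hermitian(Fb, f"Fock matrix of block {i}")
            check_hermitian(Pb, f"density matrix of block {i}")


def push_entry(stack: "HistoryStack", entry: IterationEntry) -> "HistoryStack":
    """Push an iterate, keeping the minimum first; evict the oldest nonminimal."""
    stack.push(entry)
    return stack


def cleanup_history(stack: "HistoryStack", delta_history: float = 1e-4) -> "HistoryStack":
    """Drop faraway iterates whose density distance to the best exceeds the
    screened minimum: entry ``i`` survives iff
    ``delta_history * ||P_i - P_0||_F <= min_j ||P_j - P_0||_F`` where the
    minimum runs over the nonminimal entries and the norm is accumulated over
    all blocks.  The lowest-energy entry is always retained."""
    stack.cleanup(delta_history)
    return stack


def stagnation_check(recent_energies: Sequence[float], capacity: int) -> bool:
    """True iff the last ceil(capacity/2) energies each failed to lower the
    running minimum of all preceding energies in the list."""
    k = math.ceil(capacity / 2)
    n = len(recent_energies)
    if n < k + 1:
        return False
    e = np.asarray(recent_energies, dtype=float)
    for pos in range(n - k, n):
        if e[pos] < np.min(e[:pos]):
            return False
    return True


class HistoryStack:
    """Ordered iterate history: lowest energy first, then decreasing iteration."""

    def __init__(self, capacity: int = 10):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = int(capacity)
        self.entries: list[IterationEntry] = []

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def best(self) -> IterationEntry:
        return self.entries[0]

    @property
    def latest(self) -> IterationEntry:
        """The entry with the highest iteration index."""
        return max(self.entries, key=lambda e: e.iteration_index)

    def push(self, entry: IterationEntry) -> None:
        if not math.isfinite(entry.E_total):
            raise ValueError(
                f"rejecting iterate {entry.iteration_index}: "
                f"non-finite total energy {entry.E_total}"
            )
        if not self.entries:
            self.entries.append(entry)
            return
        if entry.E_total < self.entries[0].E_total:
            # new minimum: old minimum rejoins the ordinary iterates
            rest = self.entries
            self.entries = [entry] + sorted(
                rest, key=lambda e: -e.iteration_index
            )
        else:
            rest = self.entries[1:] + [entry]
            self.entries = [self.entries[0]] + sorted(
                rest, key=lambda e: -e.iteration_index
            )
        while len(self.entries) > self.capacity:
            # oldest nonminimal iterate sits at the end of the tail
            self.entries.pop()

    def cleanup(self, delta_history: float = 1e-4) -> None:
        if len(self.entries) < 2:
            return
        P0 = self.entries[0].P
        dists = [block_diff_norm(e.P, P0) for e in self.entries[1:]]
        dmin = min(dists)
        kept = [self.entries[0]]
        kept += [
            e
            for e, d in zip(self.entries[1:], dists, strict=True)
            if delta_history * d <= dmin
        ]
        self.entries = kept
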