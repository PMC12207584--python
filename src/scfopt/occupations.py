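"""Aufbau occupation assignment and density-matrix construction.

Occupations are real valued: Aufbau assigns the per-block maximal
occupation to orbitals in globally increasing energy order across all
blocks of a particle type, leaving at most one fractionally filled
orbital.  Degenerate levels (|de| < DEGENERACY_TOL) are broken
deterministically by (block index, orbital index).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .core import BlockState

__all__ = ["aufbau_fill", "build_density", "DEGENERACY_TOL"]

DEGENERACY_TOL = 1e-12


def _global_energy_order(
    energies: Sequence[np.ndarray], skip_lowest: Sequence[int] | None = None
) -> list[tuple[int, int]]:
    """(block, orbital) pairs in increasing energy, deterministic under ties."""
    items: list[tuple[float, int, int]] = []
    for b, eb in enumerate(energies):
        lo = 0 if skip_lowest is None else int(skip_lowest[b])
        for i in range(lo, len(eb)):
            items.append((float(eb[i]), b, i))
    items.sort(key=lambda t: t[0])
    # re-sort clusters of near-degenerate energies by (block, orbital)
    out: list[tuple[float, int, int]] = []
    i = 0
    while i < len(items):
        j = i
        while j + 1 < len(items) and items[j + 1][0] - items[i][0] < DEGENERACY_TOL:
            j += 1
        out.extend(sorted(items[i : j + 1], key=lambda t: (t[1], t[2])))
        i = j + 1
    return [(b, k) for _, b, k in out]


def aufbau_fill(
    orbital_energies: Sequence[np.ndarray],
    f_max: Sequence[float],
    n_particles: float,
    skip_lowest: Sequence[int] | None = None,
) -> list[np.ndarray]:
    """Distribute ``n_particles`` over the orbitals of all blocks of one
    particle type in increasing energy order.

    Parameters
    ----------
    orbital_energies:
        Per-block ascending orbital-energy vectors.
    f_max:
        Per-block maximal occupation per orbital.
    n_particles:
        Total particle count of this type (may be fractional).
    skip_lowest:
        Optional per-block number of lowest solutions to leave empty
        (negative-energy-sea style skipping); default none.

    Returns
    -------
    Per-block occupation vectors summing exactly to ``n_particles``.
    """
    if n_particles < 0:
        raise ValueError("particle count must be nonnegative")
    capacity = sum(
        (len(e) - (0 if skip_lowest is None else skip_lowest[b])) * f_max[b]
        for b, e in enumerate(orbital_energies)
    )
    if n_particles > capacity + 1e-12:
        raise ValueError(
            f"cannot place {n_particles} particles in capacity {capacity}"
        )
    occ = [np.zeros(len(e)) for e in orbital_energies]
    remaining = float(n_particles)
    for b, i in _global_energy_order(orbital_energies, skip_lowest):
        if remaining <= 0.0:
            break
        fill = min(f_max[b], remaining)
        occ[b][i] = fill
        remaining -= fill
    return occ


def build_density(state: BlockState) -> np.ndarray:
    """Density matrix P = sum_i f_i c_i c_i^H of one block."""
    return (state.C * state.f) @ state.C.conj().T


def density_from_orbitals(C: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Density matrix from raw coefficients and occupations."""
    return (C * np.asarray(f)) @ C.conj().T
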