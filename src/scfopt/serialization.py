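"""HDF5 persistence for restart: iteration histories and model problems.

History layout (one file per history)::

    /                     attrs: capacity
    /entry_000 .. NNN     attrs: E_total, iteration_index
        /block_0 .. B     datasets: C, E_orb, f, F, P, err
                          attrs: particle_type, block_label, dim, f_max

Entries are stored in stack order (lowest energy first, then decreasing
iteration index), so a reloaded stack reproduces the retention policy
state exactly.  Model problems store the core matrices, channel matrices
and channel weight matrices under ``/H``, ``/channels`` and ``/weights``.
"""

from __future__ import annotations

import h5py
import numpy as np

from .core import BlockState, HistoryStack, IterationEntry, SymmetryBlockSpec
from .model_problems import ModelProblem

__all__ = ["save_history", "load_history", "save_problem", "load_problem"]


def save_history(stack: HistoryStack, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["capacity"] = stack.capacity
        for i, entry in enumerate(stack.entries):
            g = fh.create_group(f"entry_{i:03d}")
            g.attrs["E_total"] = entry.E_total
            g.attrs["iteration_index"] = entry.iteration_index
            for b, st in enumerate(entry.states):
                gb = g.create_group(f"block_{b}")
                gb.create_dataset("C", data=st.C)
                gb.create_dataset("E_orb", data=st.E_orb)
                gb.create_dataset("f", data=st.f)
                gb.create_dataset("F", data=entry.F[b])
                gb.create_dataset("P", data=entry.P[b])
                gb.create_dataset("err", data=entry.err[b])


def load_history(path) -> HistoryStack:
    with h5py.File(path, "r") as fh:
        stack = HistoryStack(capacity=int(fh.attrs["capacity"]))
        names = sorted(k for k in fh.keys() if k.startswith("entry_"))
        entries = []
        for name in names:
            g = fh[name]
            blocks = sorted(g.keys(), key=lambda s: int(s.split("_")[1]))
            states, F, P, err = [], [], [], []
            for bname in blocks:
                gb = g[bname]
                states.append(
                    BlockState(
                        C=gb["C"][()], E_orb=gb["E_orb"][()], f=gb["f"][()]
                    )
                )
                F.append(gb["F"][()])
                P.append(gb["P"][()])
                err.append(gb["err"][()])
            entries.append(
                IterationEntry(
                    states=states,
                    F=F,
                    P=P,
                    E_total=float(g.attrs["E_total"]),
                    err=err,
                    iteration_index=int(g.attrs["iteration_index"]),
                )
            )
    # stored in stack order already; bypass push to preserve it verbatim
    stack.entries = entries
    return stack


def save_problem(problem: ModelProblem, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["scalar_field"] = problem.scalar_field
        fh.attrs["seed"] = problem.seed
        fh.attrs["n_types"] = len(problem.types)
        for t, n in problem.n_particles.items():
            fh.attrs[f"n_particles_{t}"] = n
        gs = fh.create_group("specs")
        for b, spec in enumerate(problem.specs):
            g = gs.create_group(f"block_{b}")
            g.attrs["particle_type"] = spec.particle_type
            g.attrs["block_label"] = spec.block_label
            g.attrs["dim"] = spec.dim
            g.attrs["f_max"] = spec.f_max
        gh = fh.create_group("H")
        for b, Hb in enumerate(problem.H):
            gh.create_dataset(f"block_{b}", data=Hb)
        gc = fh.create_group("channels")
        gw = fh.create_group("weights")
        for k, (M, W) in enumerate(
            zip(problem.channel_matrices, problem.channel_weights)
        ):
            g = gc.create_group(f"channel_{k:03d}")
            for b, Mb in enumerate(M):
                g.create_dataset(f"block_{b}", data=Mb)
            gw.create_dataset(f"channel_{k:03d}", data=W)


def load_problem(path) -> ModelProblem:
    with h5py.File(path, "r") as fh:
        nblocks = len(fh["specs"])
        specs = []
        for b in range(nblocks):
            g = fh["specs"][f"block_{b}"]
            specs.append(
                SymmetryBlockSpec(
                    particle_type=int(g.attrs["particle_type"]),
                    block_label=str(g.attrs["block_label"]),
                    dim=int(g.attrs["dim"]),
                    f_max=float(g.attrs["f_max"]),
                )
            )
        n_particles = {
            int(k.split("_")[-1]): float(v)
            for k, v in fh.attrs.items()
            if k.startswith("n_particles_")
        }
        H = [fh["H"][f"block_{b}"][()] for b in range(nblocks)]
        channels, weights = [], []
        for name in sorted(fh["channels"].keys()):
            g = fh["channels"][name]
            channels.append([g[f"block_{b}"][()] for b in range(nblocks)])
            weights.append(fh["weights"][name][()])
        return ModelProblem(
            specs=specs,
            n_particles=n_particles,
            H=H,
            channel_matrices=channels,
            channel_weights=weights,
            scalar_field=str(fh.attrs["scalar_field"]),
            seed=int(fh.attrs["seed"]),
        )
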