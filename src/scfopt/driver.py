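"""The SCF loop: Roothaan updates, hybrid DIIS-(E/A)DIIS weight mixing,
Fock extrapolation, strategy dispatch (ODA / hybrid / tit-for-tat), and
simultaneous vs stepwise multi-species solving.

The solver consumes a Fock evaluator, a callable mapping per-block orbital
coefficients and occupations to the total energy and per-block Fock
matrices, everything expressed in an orthonormal basis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from collections.abc import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    BlockState,
    HistoryStack,
    IterationEntry,
    SymmetryBlockSpec,
    stagnation_check,
)
from .diis import commutator_error, diis_weights, error_norm
from .ediis_adiis import (
    adiis_objective,
    ediis_objective,
    mesa_select,
    minimize_on_simplex,
)
from .occupations import aufbau_fill, build_density
from .oda import oda_relax

__all__ = [
    "SCFConfig",
    "ConvergenceTrace",
    "SCFResult",
    "FockEvaluator",
    "roothaan_update",
    "hybrid_weights",
    "extrapolate_fock",
    "solve_scf",
    "solve_stepwise",
]

logger = logging.getLogger("scfopt")

#: (C_blocks, f_blocks) -> (E_total, F_blocks)
FockEvaluator = Callable[
    [Sequence[np.ndarray], Sequence[np.ndarray]],
    tuple[float, Sequence[np.ndarray]],
]

STRATEGIES = ("roothaan", "diis", "hybrid", "full")


@dataclass
class SCFConfig:
    """Solver parameters; the defaults follow the reference algorithm."""

    history_capacity: int = 10
    diis_damping: float = 0.02
    delta_diis: float = 1e-4
    delta_history: float = 1e-4
    eps1: float = 1e-4
    eps2: float = 1e-1
    oda_threshold: float = 1.0
    error_norm_kind: str = "rms"
    convergence_threshold: float = 1e-7
    max_iterations: int = 200
    stepwise_macro_threshold: float = 1e-7
    strategy: str = "full"
    cleanup_every_iteration: bool = True
    adiis_reference: str = "latest"  # or "best"
    mesa_reference: str = "latest"  # or "best"
    diis_normalization: str = "smallest"  # or "latest"
    oda_step_cap: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.eps1 < self.eps2:
            raise ValueError("eps1 must be smaller than eps2")
        for name in (
            "delta_diis",
            "delta_history",
            "eps1",
            "eps2",
            "oda_threshold",
            "convergence_threshold",
            "stepwise_macro_threshold",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.error_norm_kind not in ("rms", "max"):
            raise ValueError("error_norm_kind must be 'rms' or 'max'")


class ConvergenceTrace:
    """Per-iteration record of energies, errors, strategy and weights."""

    columns = (
        "iteration",
        "energy",
        "best_energy",
        "rms_error",
        "max_error",
        "strategy",
        "f_int",
        "weights",
    )

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def record(
        self,
        entry: IterationEntry,
        strategy: str,
        f_int: float | None = None,
        weights: np.ndarray | None = None,
    ) -> None:
        best = entry.E_total
        if self.rows:
            best = min(best, self.rows[-1]["best_energy"])
        self.rows.append(
            {
                "iteration": entry.iteration_index,
                "energy": entry.E_total,
                "best_energy": best,
                "rms_error": error_norm(entry.err, "rms"),
                "max_error": error_norm(entry.err, "max"),
                "strategy": strategy,
                "f_int": f_int,
                "weights": None if weights is None else list(map(float, weights)),
            }
        )

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns)

    @property
    def best_energies(self) -> np.ndarray:
        return np.array([r["best_energy"] for r in self.rows])


@dataclass
class SCFResult:
    entry: IterationEntry
    trace: ConvergenceTrace
    converged: bool
    n_iterations: int
    history: HistoryStack


def roothaan_update(
    F: Sequence[np.ndarray],
    specs: Sequence[SymmetryBlockSpec],
    n_particles: Mapping[int, float],
) -> list[BlockState]:
    """Diagonalize each block's Fock matrix and refill occupations Aufbau-wise.

    Eigenvalues come out ascending; the occupations of each particle type are
    distributed across all of its blocks in globally increasing energy order.
    """
    eigs: list[np.ndarray] = []
    vecs: list[np.ndarray] = []
    for b, Fb in enumerate(F):
        try:
            w, v = np.linalg.eigh(Fb)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"eigendecomposition failed in block {b}") from exc
        eigs.append(w)
        vecs.append(v)
    occ: list[np.ndarray | None] = [None] * len(specs)
    for t in sorted({s.particle_type for s in specs}):
        idx = [b for b, s in enumerate(specs) if s.particle_type == t]
        fb = aufbau_fill(
            [eigs[b] for b in idx],
            [specs[b].f_max for b in idx],
            n_particles[t],
        )
        for b, f in zip(idx, fb, strict=True):
            occ[b] = f
    return [
        BlockState(C=vecs[b], E_orb=eigs[b], f=occ[b]) for b in range(len(specs))
    ]


def hybrid_weights(
    eps_diis: float,
    c_diis: np.ndarray,
    c_interp: np.ndarray,
    eps1: float = 1e-4,
    eps2: float = 1e-1,
) -> tuple[np.ndarray, float]:
    """Interpolate between the DIIS and EDIIS/ADIIS weights.

    The interpolation fraction is 1 (pure DIIS) for errors below ``eps1``,
    0 (pure interpolation) above ``eps2`` and linear in between.  Returns
    the mixed weights and the fraction used.
    """
    if eps_diis >= eps2:
        f_int = 0.0
    elif eps_diis <= eps1:
        f_int = 1.0
    else:
        f_int = 1.0 - (eps_diis - eps2) / (eps1 - eps2)
    c = f_int * np.asarray(c_diis) + (1.0 - f_int) * np.asarray(c_interp)
    return c, f_int


def extrapolate_fock(
    F_history: Sequence[Sequence[np.ndarray]], weights: Sequence[float]
) -> list[np.ndarray]:
    """Weighted combination Fbar = sum_i c_i F_i per block."""
    weights = np.asarray(weights, dtype=float)
    n_blocks = len(F_history[0])
    return [
        sum(c * Fi[b] for c, Fi in zip(weights, F_history, strict=True))
        for b in range(n_blocks)
    ]


def _particle_types(specs: Sequence[SymmetryBlockSpec]) -> list[int]:
    return sorted({s.particle_type for s in specs})


def _initial_states(
    specs: Sequence[SymmetryBlockSpec],
    n_particles: Mapping[int, float],
    guess: Sequence[BlockState] | tuple | None,
    guess_fock: Sequence[np.ndarray] | None,
) -> list[BlockState]:
    if (guess is None) == (guess_fock is None):
        raise ValueError("supply exactly one of guess or guess_fock")
    if guess_fock is not None:
        return roothaan_update(guess_fock, specs, n_particles)
    if guess and isinstance(guess[0], BlockState):
        return list(guess)
    C_blocks, f_blocks = guess
    return [
        BlockState(C=np.asarray(C), E_orb=np.zeros(spec.dim), f=np.asarray(f, dtype=float))
        for spec, C, f in zip(specs, C_blocks, f_blocks, strict=True)
    ]


def _make_entry_factory(
    evaluator: FockEvaluator, specs: Sequence[SymmetryBlockSpec]
):
    """Wrap the evaluator into a counting IterationEntry factory."""
    counter = {"n": 0}

    def make_entry(states: list[BlockState]) -> IterationEntry:
        C = [s.C for s in states]
        f = [s.f for s in states]
        E, F = evaluator(C, f)
        if not math.isfinite(float(E)):
            raise RuntimeError(
                f"Fock evaluator returned non-finite energy {E} "
                f"at evaluation {counter['n']}"
            )
        P = [build_density(s) for s in states]
        err = [commutator_error(Fb, Pb) for Fb, Pb in zip(F, P, strict=True)]
        entry = IterationEntry(
            states=states,
            F=list(F),
            P=P,
            E_total=float(E),
            err=err,
            iteration_index=counter["n"],
        )
        counter["n"] += 1
        return entry

    return make_entry, counter


def solve_scf(
    evaluator: FockEvaluator,
    specs: Sequence[SymmetryBlockSpec],
    n_particles: Mapping[int, float],
    guess: Sequence[BlockState] | tuple | None = None,
    guess_fock: Sequence[np.ndarray] | None = None,
    config: SCFConfig | None = None,
) -> SCFResult:
    """Drive the coupled Roothaan iteration to self-consistency.

    Each iteration evaluates the Fock functional, pushes the iterate onto
    the lowest-energy-first history, cleans the history, and either takes an
    optimally damped density step (when the max orbital gradient is large or
    the accelerated iterations have stagnated; stagnation forces
    ceil(N/2) consecutive damped evaluations) or extrapolates the Fock
    matrices with the hybrid DIIS / interpolation weights before the next
    Roothaan update.  Terminates when the configured error norm drops below
    the convergence threshold, returning the lowest-energy iterate.
    """
    cfg = config or SCFConfig()
    stack = HistoryStack(capacity=cfg.history_capacity)
    trace = ConvergenceTrace()
    make_entry, counter = _make_entry_factory(evaluator, specs)
    types = _particle_types(specs)

    states = _initial_states(specs, n_particles, guess, guess_fock)
    entry = make_entry(states)
    strategy_label, f_int_used, weights_used = "guess", None, None

    forced_oda = 0
    oda_run = 0
    accel_energies: list[float] = [entry.E_total]
    converged = False
    pushed: set[int] = set()

    while True:
        if entry.iteration_index not in pushed:
            stack.push(entry)
            pushed.add(entry.iteration_index)
            trace.record(entry, strategy_label, f_int_used, weights_used)
        eps = error_norm(entry.err, cfg.error_norm_kind)
        eps_max = error_norm(entry.err, "max")
        if eps < cfg.convergence_threshold:
            converged = True
            break
        if counter["n"] >= cfg.max_iterations:
            logger.warning(
                "SCF did not converge in %d Fock evaluations", counter["n"]
            )
            break
        if cfg.cleanup_every_iteration:
            stack.cleanup(cfg.delta_history)
        entries = stack.entries

        use_oda = cfg.strategy == "full" and (
            forced_oda > 0 or eps_max >= cfg.oda_threshold
        )
        if use_oda and oda_run >= cfg.oda_step_cap:
            logger.warning(
                "ODA step cap (%d) reached; falling back to acceleration",
                cfg.oda_step_cap,
            )
            use_oda = False
            forced_oda = 0

        if cfg.strategy == "roothaan":
            states = roothaan_update(entry.F, specs, n_particles)
            entry = make_entry(states)
            strategy_label, f_int_used, weights_used = "roothaan", None, None
            continue

        if use_oda:
            before = counter["n"]
            best = entries[0]
            cand_states = roothaan_update(best.F, specs, n_particles)
            cand = make_entry(cand_states)
            stack.push(cand)
            pushed.add(cand.iteration_index)
            trace.record(cand, "oda")
            relaxed = oda_relax(best, cand, make_entry, specs)
            consumed = counter["n"] - before
            oda_run += consumed
            forced_oda = max(0, forced_oda - consumed)
            entry = relaxed
            strategy_label, f_int_used, weights_used = "oda", None, None
            accel_energies = [stack.best.E_total]
            continue

        oda_run = 0
        # accelerated iteration: DIIS + optional interpolation
        latest_idx = int(
            np.argmax([e.iteration_index for e in entries])
        )
        errs = [e.err for e in entries]
        c_diis = diis_weights(
            errs,
            d=cfg.diis_damping,
            delta_diis=cfg.delta_diis,
            latest=latest_idx,
            normalize=cfg.diis_normalization,
        )
        if cfg.strategy == "diis":
            c, f_int = c_diis, 1.0
            label = "diis"
        else:
            E_hist = [e.E_total for e in entries]
            F_hist = [e.F for e in entries]
            P_hist = [e.P for e in entries]
            q_e = ediis_objective(E_hist, F_hist, P_hist)
            c_e = minimize_on_simplex(q_e)
            ref = latest_idx if cfg.adiis_reference == "latest" else 0
            q_a = adiis_objective(E_hist, F_hist, P_hist, ref_index=ref)
            c_a = minimize_on_simplex(q_a)
            P_cur = (
                entries[latest_idx].P
                if cfg.mesa_reference == "latest"
                else entries[0].P
            )
            label, c_int = mesa_select(c_e, c_a, P_hist, P_cur)
            c, f_int = hybrid_weights(eps, c_diis, c_int, cfg.eps1, cfg.eps2)
            if f_int >= 1.0:
                label = "diis"
            elif f_int > 0.0:
                label = "hybrid"
        Fbar = extrapolate_fock([e.F for e in entries], c)
        states = roothaan_update(Fbar, specs, n_particles)
        entry = make_entry(states)
        strategy_label, f_int_used, weights_used = label, f_int, c
        # stagnation bookkeeping over accelerated iterations
        accel_energies.append(entry.E_total)
        if cfg.strategy == "full" and stagnation_check(
            accel_energies, cfg.history_capacity
        ):
            forced_oda = math.ceil(cfg.history_capacity / 2)
            oda_run = 0
            logger.info(
                "stagnation detected at evaluation %d: forcing %d ODA evaluations",
                counter["n"],
                forced_oda,
            )

    # make sure the final iterate is recorded
    if entry.iteration_index not in pushed:
        stack.push(entry)
        trace.record(entry, strategy_label, f_int_used, weights_used)
    return SCFResult(
        entry=stack.best,
        trace=trace,
        converged=converged,
        n_iterations=counter["n"],
        history=stack,
    )


def solve_stepwise(
    evaluator: FockEvaluator,
    specs: Sequence[SymmetryBlockSpec],
    n_particles: Mapping[int, float],
    partition: Sequence[Sequence[int]],
    guess: Sequence[BlockState] | tuple | None = None,
    guess_fock: Sequence[np.ndarray] | None = None,
    config: SCFConfig | None = None,
    max_macro: int = 50,
) -> SCFResult:
    """Alternating (stepwise) multi-species solver.

    Each macroiteration solves the sub-SCF problem of every particle-type
    group in ``partition`` in turn while the other types' orbitals and
    occupations stay frozen, so the coupling field they generate is constant
    within the subproblem and refreshed at the group boundary.  When the
    total energy changes by less than the macro threshold between
    macroiterations, a final joint (simultaneous) solve finishes the job.
    """
    cfg = config or SCFConfig()
    states = _initial_states(specs, n_particles, guess, guess_fock)
    total_evals = 0
    E_prev = math.inf
    for macro in range(max_macro):
        for group in partition:
            group = set(group)
            idx = [b for b, s in enumerate(specs) if s.particle_type in group]
            frozen = {b: states[b] for b in range(len(specs)) if b not in idx}

            def sub_evaluator(C_sub, f_sub, _idx=idx, _frozen=frozen):
                C_all: list[np.ndarray] = [None] * len(specs)
                f_all: list[np.ndarray] = [None] * len(specs)
                for pos, b in enumerate(_idx):
                    C_all[b] = C_sub[pos]
                    f_all[b] = f_sub[pos]
                for b, st in _frozen.items():
                    C_all[b] = st.C
                    f_all[b] = st.f
                E, F = evaluator(C_all, f_all)
                return E, [F[b] for b in _idx]

            sub_specs = [specs[b] for b in idx]
            sub_n = {t: n_particles[t] for t in group}
            sub_guess = [states[b] for b in idx]
            res = solve_scf(
                sub_evaluator, sub_specs, sub_n, guess=sub_guess, config=cfg
            )
            total_evals += res.n_iterations
            for pos, b in enumerate(idx):
                states[b] = res.entry.states[pos]
        E_macro = res.entry.E_total
        if abs(E_macro - E_prev) < cfg.stepwise_macro_threshold:
            break
        E_prev = E_macro
    final = solve_scf(evaluator, specs, n_particles, guess=states, config=cfg)
    final.trace.rows = final.trace.rows  # joint trace only
    return SCFResult(
        entry=final.entry,
        trace=final.trace,
        converged=final.converged,
        n_iterations=total_evals + final.n_iterations,
        history=final.history,
    )
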