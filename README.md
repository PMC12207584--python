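# scfopt

Self-consistent-field (SCF) orbital optimization as a standalone Python
library: a driver that converges coupled Roothaan equations for an
arbitrary number of particle types and symmetry blocks, accelerated by

- **DIIS** — constrained least-squares Fock extrapolation with
  Hamilton–Pulay diagonal damping, smallest-diagonal normalization and
  restart screening of stale error vectors,
- **EDIIS / ADIIS** — proxy-energy interpolation objectives minimized on
  the unit simplex by exact pairwise line searches (no square-variable
  reparametrization, no external QP solver), with MESA selection between
  the two candidates,
- a **hybrid scheme** that interpolates linearly between the DIIS and
  EDIIS/ADIIS weights as a function of the DIIS error,
- the **optimal damping algorithm (ODA)** — per-particle-type convex
  density mixing with analytic gradients, a cubic line fit and
  natural-orbital extraction, triggered by large orbital gradients or by
  a stagnation (tit-for-tat) heuristic,
- a **lowest-energy-first history stack** that never evicts the best
  iterate, with density-distance history cleanup.

The solver only needs a *Fock evaluator*: a callable mapping per-block
orbital coefficients and occupations to the total energy and per-block
Fock matrices, everything in an orthonormal basis. Real and complex
orbitals are supported throughout. Helpers for reducing a generalized
eigenproblem to the orthonormal basis (symmetric/canonical
orthogonalization, pivoted-Cholesky basis reduction) are included.

Because no integral engine is bundled, the package ships a synthetic
model-problem generator: bounded-below quadratic (Hartree–Fock-form)
energy functionals over one or two particle types, with brute-force
reference minima (dense rotation-angle scans and random-restart projected
gradient descent) used as independent oracles by the test suite.

## Library quick start

```python
import scfopt

problem = scfopt.make_quadratic_problem(dim=6, n_occ_pairs=2, strength=1.0, seed=1)
result = scfopt.solve_scf(
    problem.evaluator,            # (C, f) -> (E, F) in the orthonormal basis
    problem.specs,                # SymmetryBlockSpec per block
    problem.n_particles,          # particle count per type
    guess_fock=problem.core_guess(),
    config=scfopt.SCFConfig(),    # defaults: N=10, d=0.02, eps1=1e-4, ...
)
print(result.converged, result.entry.E_total)
print(result.trace.to_dataframe())  # per-iteration energies/errors/strategy

ref = scfopt.brute_force_reference(problem)   # independent oracle
assert abs(result.entry.E_total - ref.E_min) < 1e-7
```

Two coupled species can be solved simultaneously (`solve_scf`) or
stepwise (`solve_stepwise`), where each macroiteration converges one
particle-type group at a time in the frozen field of the others and a
final joint solve finishes once the macroiteration energy change drops
below `stepwise_macro_threshold`.

## Command line

```sh
scfopt solve   --seed 1 --dim 4 --output trace.csv
scfopt suite   --seed 1 --n-problems 10 --output suite.csv
scfopt compare --seed 1 --strategies diis,full --output cmp.csv
```

`--config file.toml` accepts any `SCFConfig` field (e.g.
`history_capacity = 20`, `strategy = "hybrid"`). Traces and summaries are
written as CSV plus a JSON-lines mirror; outputs are byte-identical for a
fixed seed apart from the timestamp comment on the first line.

Strategy presets: `roothaan` (no acceleration), `diis` (pure DIIS),
`hybrid` (DIIS + EDIIS/ADIIS mixing), `full` (hybrid + ODA + stagnation
fallback; the default).

## HDF5 layouts

`scfopt.serialization` persists histories for restart (one group per
entry in stack order with `C`, `E_orb`, `f`, `F`, `P`, `err` datasets per
block and `E_total` / `iteration_index` attributes) and model problems
(`/H`, `/channels`, `/weights` groups plus block-spec attributes); see the
module docstring for the exact layout.
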