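import numpy as np
import pytest

from scfopt.ediis_adiis import (
    SimplexQuadratic,
    adiis_objective,
    ediis_objective,
    mesa_select,
    minimize_on_simplex,
)
from scfopt.model_problems import make_quadratic_problem


_GRID_CACHE: dict[tuple[int, int], np.ndarray] = {}


def simplex_grid(m: int, steps: int) -> np.ndarray:
    """All points with coordinates k/steps on the unit simplex (vectorized)."""
    key = (m, steps)
    if key not in _GRID_CACHE:
        axes = np.meshgrid(
            *[np.arange(steps + 1, dtype=np.int32)] * (m - 1), indexing="ij"
        )
        flat = np.stack([a.ravel() for a in axes], axis=1)
        flat = flat[flat.sum(axis=1) <= steps]
        last = steps - flat.sum(axis=1, keepdims=True)
        _GRID_CACHE[key] = np.hstack([flat, last]).astype(float) / steps
    return _GRID_CACHE[key]


def grid_minimum(q: SimplexQuadratic, steps: int = 200) -> float:
    X = simplex_grid(q.m, steps)
    vals = 0.5 * np.einsum("ni,ij,nj->n", X, q.A, X) + X @ q.b + q.const
    return float(np.min(vals))


def random_history(problem, m, seed):
    """History of m random feasible iterates of a model problem."""
    rng = np.random.default_rng(seed)
    E, F, P = [], [], []
    for _ in range(m):
        Pi = problem.random_feasible_density(rng)
        E.append(problem.energy_from_density(Pi))
        F.append(problem.fock_from_density(Pi))
        P.append(Pi)
    return E, F, P


class TestSimplexQuadratic:
    def test_symmetrized(self):
        q = SimplexQuadratic(A=np.array([[0.0, 2.0], [0.0, 0.0]]), b=np.zeros(2))
        assert np.allclose(q.A, [[0.0, 1.0], [1.0, 0.0]])

    def test_evaluate(self):
        q = SimplexQuadratic(A=2 * np.eye(2), b=np.array([1.0, 0.0]), const=3.0)
        assert q(np.array([0.5, 0.5])) == pytest.approx(0.25 + 0.25 + 0.5 + 3.0)


class TestEDIISObjective:
    def test_single_entry(self):
        p = make_quadratic_problem(3, 1, 1.0, seed=0)
        E, F, P = random_history(p, 1, 0)
        q = ediis_objective(E, F, P)
        assert q(np.array([1.0])) == pytest.approx(E[0])

    def test_identical_entries(self):
        p = make_quadratic_problem(3, 1, 1.0, seed=0)
        E, F, P = random_history(p, 1, 0)
        q = ediis_objective(E * 2, F * 2, P * 2)
        for c in ([0.3, 0.7], [1.0, 0.0], [0.5, 0.5]):
            assert q(np.array(c)) == pytest.approx(E[0])

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_on_quadratic_model(self, seed):
        """The interpolated objective equals the true mixed-density energy."""
        p = make_quadratic_problem(4, 2, 1.5, seed=seed)
        E, F, P = random_history(p, 4, seed)
        q = ediis_objective(E, F, P)
        rng = np.random.default_rng(seed + 99)
        for _ in range(20):
            c = rng.dirichlet(np.ones(4))
            mixed = [sum(ci * Pi[0] for ci, Pi in zip(c, P))]
            expected = p.energy_from_density(mixed)
            assert q(c) == pytest.approx(expected, rel=1e-10, abs=1e-12)


class TestADIISObjective:
    def test_indicator_of_reference(self):
        p = make_quadratic_problem(3, 1, 1.0, seed=1)
        E, F, P = random_history(p, 3, 1)
        q = adiis_objective(E, F, P, ref_index=1)
        c = np.array([0.0, 1.0, 0.0])
        assert q(c) == pytest.approx(E[1])

    def test_single_entry_constant(self):
        p = make_quadratic_problem(3, 1, 1.0, seed=1)
        E, F, P = random_history(p, 1, 1)
        q = adiis_objective(E, F, P, ref_index=0)
        assert q(np.array([1.0])) == pytest.approx(E[0])

    def test_bad_reference_raises(self):
        p = make_quadratic_problem(3, 1, 1.0, seed=1)
        E, F, P = random_history(p, 2, 1)
        with pytest.raises(ValueError):
            adiis_objective(E, F, P, ref_index=5)

    @pytest.mark.parametrize("seed", range(4))
    def test_argmin_agrees_with_ediis_on_quadratic_model(self, seed):
        p = make_quadratic_problem(4, 2, 1.5, seed=seed)
        E, F, P = random_history(p, 4, seed)
        q_e = ediis_objective(E, F, P)
        q_a = adiis_objective(E, F, P, ref_index=len(E) - 1)
        c_e = minimize_on_simplex(q_e)
        c_a = minimize_on_simplex(q_a)
        # same minimizing mixture => same interpolated energy
        assert q_e(c_a) == pytest.approx(q_e(c_e), abs=1e-8)


class TestMinimizeOnSimplex:
    def test_isotropic_m2(self):
        q = SimplexQuadratic(A=2 * np.eye(2), b=np.zeros(2))
        c = minimize_on_simplex(q)
        assert np.allclose(c, [0.5, 0.5], atol=1e-8)
        assert q(c) == pytest.approx(0.5)

    def test_linear_vertex(self):
        q = SimplexQuadratic(A=np.zeros((2, 2)), b=np.array([-2.0, 0.0]))
        c = minimize_on_simplex(q)
        assert np.allclose(c, [1.0, 0.0], atol=1e-10)

    def test_isotropic_m3(self):
        q = SimplexQuadratic(A=2 * np.eye(3), b=np.zeros(3))
        c = minimize_on_simplex(q)
        assert np.allclose(c, np.full(3, 1 / 3), atol=1e-8)

    def test_m1(self):
        q = SimplexQuadratic(A=np.zeros((1, 1)), b=np.array([2.0]))
        assert np.allclose(minimize_on_simplex(q), [1.0])

    def test_non_finite_raises(self):
        q = SimplexQuadratic(A=np.full((2, 2), np.nan), b=np.zeros(2))
        with pytest.raises(ValueError):
            minimize_on_simplex(q)

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_against_grid_oracle(self, m):
        rng = np.random.default_rng(m)
        for _ in range(10):
            A = rng.standard_normal((m, m))
            q = SimplexQuadratic(A=A + A.T, b=rng.standard_normal(m))
            c = minimize_on_simplex(q)
            assert np.all(c >= -1e-12) and np.isclose(c.sum(), 1.0)
            assert q(c) <= grid_minimum(q, 200) + 1e-6

    def test_descent_and_feasibility(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 6))
            A = rng.standard_normal((m, m))
            q = SimplexQuadratic(A=A + A.T, b=rng.standard_normal(m))
            starts = [np.eye(m)[k] for k in range(m)] + [np.full(m, 1 / m)]
            c = minimize_on_simplex(q)
            assert q(c) <= min(q(s) for s in starts) + 1e-12
            assert np.all(c >= -1e-12)
            assert np.isclose(c.sum(), 1.0, atol=1e-12)


class TestMESASelect:
    def _history(self, seed, m=3):
        p = make_quadratic_problem(3, 1, 1.0, seed=seed)
        return p, random_history(p, m, seed)

    def test_identical_candidates(self):
        p, (E, F, P) = self._history(0)
        c = np.array([0.2, 0.3, 0.5])
        label, w = mesa_select(c, c, P, P[-1])
        assert np.allclose(w, c)

    def test_indicator_of_current_wins(self):
        p, (E, F, P) = self._history(1)
        c_adiis = np.array([0.0, 0.0, 1.0])  # exactly the current density
        c_ediis = np.array([1.0, 0.0, 0.0])
        label, w = mesa_select(c_ediis, c_adiis, P, P[-1])
        assert label == "adiis"
        assert np.allclose(w, c_adiis)

    def test_matches_direct_comparison(self, rng):
        p, (E, F, P) = self._history(2)
        for _ in range(10):
            c_e = rng.dirichlet(np.ones(3))
            c_a = rng.dirichlet(np.ones(3))

            def dist(c):
                mixed = [sum(ci * Pi[0] for ci, Pi in zip(c, P))]
                return np.linalg.norm(P[-1][0] - mixed[0])

            label, w = mesa_select(c_e, c_a, P, P[-1])
            expected = "ediis" if dist(c_e) < dist(c_a) else "adiis"
            assert label == expected
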