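"""Real-coded GA engine and the two estimation modes."""

import numpy as np
import pytest

from mlago.kinetics import generate_quasi_data
from mlago.optimizer import (
    MlagoProblem,
    RcgaSettings,
    SearchSpace,
    conventional_estimate,
    mlago_estimate,
    rcga_run,
    repeated_trials,
    stochastic_ranking,
)
from mlago.synthetic import ToyPathwaySpec, make_toy_pathway
from tests.conftest import TOY_TIMEPOINTS

FAST = RcgaSettings(stagnation_generations=100)


class TestSearchSpace:
    def test_default_bounds_span_minus5_to_3(self):
        s = SearchSpace.default(3)
        np.testing.assert_allclose(s.log_lower, -5.0)
        np.testing.assert_allclose(s.log_upper, 3.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            SearchSpace([1.0], [1.0])


class TestStochasticRanking:
    def test_all_feasible_sorts_by_objective(self):
        rng = np.random.default_rng(0)
        obj = np.array([3.0, 1.0, 2.0])
        viol = np.zeros(3)
        order = stochastic_ranking(obj, viol, pf=0.45, rng=rng)
        assert list(obj[order]) == [1.0, 2.0, 3.0]

    def test_pf_zero_is_feasibility_driven(self):
        rng = np.random.default_rng(0)
        obj = np.array([0.0, 1.0])
        viol = np.array([5.0, 0.0])
        order = stochastic_ranking(obj, viol, pf=0.0, rng=rng)
        assert order[0] == 1  # feasible point first despite worse objective


class TestRcgaRun:
    def test_sphere_convergence(self):
        space = SearchSpace.default(5)
        res = rcga_run(lambda p: float(np.sum(np.log10(p) ** 2)), None, space, 20000, seed=1)
        assert res.best_objective < 1e-3

    def test_constrained_toy_analytic_optimum(self):
        """min q1 s.t. q1 >= 0.5 has optimum exactly at the boundary."""
        space = SearchSpace.default(1)
        res = rcga_run(
            lambda p: float(np.log10(p[0])),
            lambda p: max(0.0, 0.5 - np.log10(p[0])),
            space, 20000, seed=3,
        )
        assert res.feasible
        assert abs(np.log10(res.best_p[0]) - 0.5) < 2e-3

    def test_same_seed_identical_traces(self):
        space = SearchSpace.default(3)
        obj = lambda p: float(np.sum((np.log10(p) - 1.0) ** 2))
        r1 = rcga_run(obj, None, space, 3000, seed=7, settings=FAST)
        r2 = rcga_run(obj, None, space, 3000, seed=7, settings=FAST)
        assert r1.trace == r2.trace
        np.testing.assert_array_equal(r1.best_p, r2.best_p)

    def test_budget_one_generation_returns_best_of_initial_population(self):
        space = SearchSpace.default(2)
        obj = lambda p: float(np.sum(np.log10(p) ** 2))
        res = rcga_run(obj, None, space, 50, seed=0, settings=RcgaSettings(population_size=50))
        assert res.n_evaluations == 50
        # equals the best initial sample under the same seed
        rng = np.random.default_rng(0)
        pop = rng.uniform(-5, 3, size=(50, 2))
        best = min(float(np.sum(q**2)) for q in pop)
        assert res.best_objective == pytest.approx(best)

    def test_budget_too_small_raises(self):
        with pytest.raises(ValueError):
            rcga_run(lambda p: 0.0, None, SearchSpace.default(2), 10, seed=0)

    def test_bounds_respected(self):
        space = SearchSpace(np.array([0.01]), np.array([10.0]))
        res = rcga_run(lambda p: float(-np.log10(p[0])), None, space, 2000, seed=1, settings=FAST)
        assert 0.01 <= res.best_p[0] <= 10.0
        # unconstrained max of -q is at the upper bound
        assert np.log10(res.best_p[0]) == pytest.approx(1.0, abs=1e-6)

    def test_trace_monotone_among_feasible(self):
        space = SearchSpace.default(2)
        res = rcga_run(
            lambda p: float(np.sum(np.log10(p) ** 2)),
            lambda p: max(0.0, 1.0 - np.log10(p[0])),
            space, 5000, seed=5, settings=FAST,
        )
        feas_obj = [o for _, o, _ in res.trace if np.isfinite(o)]
        assert all(a >= b for a, b in zip(feas_obj, feas_obj[1:]))


@pytest.fixture(scope="module")
def two_km_problem():
    model, p_true = make_toy_pathway(ToyPathwaySpec(n_reactions=2, seed=4))
    data = generate_quasi_data(model, p_true, TOY_TIMEPOINTS)
    return model, p_true, data


class TestEstimationModes:
    def test_conventional_recovers_good_fit(self, two_km_problem):
        model, p_true, data = two_km_problem
        res = conventional_estimate(
            model, data, model.km_names, p_true.copy(), budget=6000, seed=2, ae=0.02
        )
        assert res.best_bof <= 0.02
        assert res.feasible

    def test_mlago_with_true_reference_recovers_truth(self, two_km_problem):
        model, p_true, data = two_km_problem
        idx = model.parameter_index(model.km_names)
        q_true = np.log10(p_true[idx])
        problem = MlagoProblem(
            model=model, data=data, searched_names=model.km_names,
            reference=q_true, p_fixed=p_true.copy(), budget=6000, seed=1,
        )
        res = mlago_estimate(problem)
        assert res.feasible and res.best_bof <= 0.02
        assert res.best_rmse_to_reference < 0.05
        np.testing.assert_allclose(np.log10(res.best_p), q_true, atol=0.1)

    def test_mlago_infeasible_reference_projects_to_boundary(self, two_km_problem):
        """With the reference outside the feasible set, BOF sits at ~AE."""
        model, p_true, data = two_km_problem
        idx = model.parameter_index(model.km_names)
        ref = np.log10(p_true[idx]) + 1.0
        problem = MlagoProblem(
            model=model, data=data, searched_names=model.km_names,
            reference=ref, p_fixed=p_true.copy(), budget=8000, seed=1,
        )
        res = mlago_estimate(problem)
        assert res.feasible
        assert 0 < res.best_rmse_to_reference < 1.0  # pulled toward truth but constrained
        assert res.best_bof <= 0.02

    def test_invalid_problem_configs_rejected(self, two_km_problem):
        model, p_true, data = two_km_problem
        with pytest.raises(ValueError):
            MlagoProblem(model=model, data=data, searched_names=model.km_names,
                         reference=np.array([0.0, 0.0]), p_fixed=p_true, ae=-1.0)
        with pytest.raises(ValueError):
            MlagoProblem(model=model, data=data, searched_names=model.km_names,
                         reference=np.array([0.0]), p_fixed=p_true)
        with pytest.raises(ValueError):
            MlagoProblem(model=model, data=data, searched_names=model.km_names,
                         reference=np.array([np.inf, 0.0]), p_fixed=p_true)

    def test_rmse_mask_excludes_cosearched_parameters(self, two_km_problem):
        """Vmax co-searched but excluded from the objective RMSE."""
        model, p_true, data = two_km_problem
        searched = ["Vmax1", "Vmax2", "Km1", "Km2"]
        idx = model.parameter_index(["Km1", "Km2"])
        q_true = np.log10(p_true[idx])
        problem = MlagoProblem(
            model=model, data=data, searched_names=searched,
            reference=q_true, p_fixed=p_true.copy(),
            rmse_mask=np.array([False, False, True, True]),
            budget=8000, seed=3,
        )
        res = mlago_estimate(problem)
        assert res.feasible
        # objective only over the Km subset
        from mlago.predictor import rmse
        assert res.best_rmse_to_reference == pytest.approx(rmse(np.log10(res.best_p[2:]), q_true))


class TestRepeatedTrials:
    def test_determinism_and_feasibility_rate(self, two_km_problem):
        model, p_true, data = two_km_problem
        idx = model.parameter_index(model.km_names)
        q_true = np.log10(p_true[idx])

        def estimate(seed):
            return mlago_estimate(MlagoProblem(
                model=model, data=data, searched_names=model.km_names,
                reference=q_true, p_fixed=p_true.copy(), budget=4000, seed=seed,
            ))

        s1 = repeated_trials(estimate, n_trials=2, base_seed=10)
        s2 = repeated_trials(estimate, n_trials=2, base_seed=10)
        assert s1.feasibility_rate == s2.feasibility_rate == 1.0
        assert s1.rmse_mean == s2.rmse_mean
        np.testing.assert_array_equal(s1.per_parameter_sd, s2.per_parameter_sd)

    def test_requires_two_trials(self, two_km_problem):
        with pytest.raises(ValueError):
            repeated_trials(lambda s: None, n_trials=1)
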