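"""Derivative-free optimizers and the subject-fitting pipeline."""

import numpy as np
import pytest

from glottifit import (
    FitConfig,
    FitVariables,
    SearchSpace,
    StandardParameters,
    SyntheticSpec,
    bee_colony,
    fit_subject,
    generate_model_subject,
    initial_grid_search,
    nelder_mead,
    particle_swarm,
    subject_parameters,
)
from glottifit.errors import DomainError, SearchFailureError

SPACE = SearchSpace()
MINIMUM = np.array([1.0, 2.0, 20.0])


def quadratic(x):
    return (x[0] - 1.0) ** 2 + (x[1] - 2.0) ** 2 + ((x[2] - 20.0) / 10.0) ** 2


class TestInitialGridSearch:
    def test_on_grid_minimum_is_found(self):
        target = np.array([2.0, 2.0, 20.0])
        obj = lambda x: float(np.sum((np.asarray(x) - target) ** 2))
        best, value = initial_grid_search(obj, SPACE)[0]
        assert np.allclose(best, target)
        assert value == 0.0

    def test_nearest_grid_point_matches_exhaustive_oracle(self):
        target = np.array([2.2, 1.9, 18.0])
        obj = lambda x: float(np.sum((np.asarray(x) - target) ** 2))
        ranked = initial_grid_search(obj, SPACE)
        # brute-force oracle over the same grid
        import itertools
        pts = [np.array(p) for p in itertools.product(*SPACE.grid_axes())]
        oracle = min(pts, key=obj)
        assert np.allclose(ranked[0][0], oracle)

    def test_all_points_inside_bounds(self):
        ranked = initial_grid_search(lambda x: float(np.sum(x)), SPACE)
        for p, _ in ranked:
            assert SPACE.contains(p)

    def test_all_non_finite_raises(self):
        with pytest.raises(SearchFailureError):
            initial_grid_search(lambda x: float("nan"), SPACE)


class TestNelderMead:
    def test_reaches_quadratic_minimum(self):
        res = nelder_mead(quadratic, [3.0, 3.0, 40.0], SPACE, budget=2000)
        assert np.allclose(res.x, MINIMUM, atol=1e-4)

    def test_start_at_minimum_is_fixed_point(self):
        res = nelder_mead(quadratic, MINIMUM, SPACE, budget=2000)
        assert np.allclose(res.x, MINIMUM, atol=1e-4)

    def test_respects_bounds(self):
        # minimum outside the box: the result must stay inside
        obj = lambda x: float(np.sum((np.asarray(x) - [-5.0, -5.0, 0.0]) ** 2))
        res = nelder_mead(obj, [1.0, 1.0, 10.0], SPACE, budget=2000)
        assert SPACE.contains(res.x)

    def test_rejects_start_outside_bounds(self):
        with pytest.raises(DomainError):
            nelder_mead(quadratic, [10.0, 1.0, 20.0], SPACE)


class TestParticleSwarm:
    def test_reaches_quadratic_minimum(self):
        res = particle_swarm(quadratic, SPACE, seed=1, budget=2000)
        assert np.allclose(res.x, MINIMUM, atol=1e-3)

    def test_different_seeds_same_minimum(self):
        a = particle_swarm(quadratic, SPACE, seed=1, budget=3000)
        b = particle_swarm(quadratic, SPACE, seed=2, budget=3000)
        assert np.allclose(a.x, b.x, atol=1e-3)

    def test_seeded_reproducibility_is_bitwise(self):
        a = particle_swarm(quadratic, SPACE, seed=7, budget=600)
        b = particle_swarm(quadratic, SPACE, seed=7, budget=600)
        assert np.array_equal(a.x, b.x)
        assert a.value == b.value
        assert a.n_evaluations == b.n_evaluations

    def test_grid_injection_accelerates(self):
        res = particle_swarm(quadratic, SPACE, seed=3, budget=300,
                             init_points=[MINIMUM + 0.01])
        assert quadratic(res.x) <= quadratic(MINIMUM + 0.01) + 1e-12


class TestBeeColony:
    def test_reaches_quadratic_minimum(self):
        res = bee_colony(quadratic, SPACE, seed=1, budget=2000)
        assert np.allclose(res.x, MINIMUM, atol=1e-3)

    def test_seeded_reproducibility_is_bitwise(self):
        a = bee_colony(quadratic, SPACE, seed=5, budget=600)
        b = bee_colony(quadratic, SPACE, seed=5, budget=600)
        assert np.array_equal(a.x, b.x)

    def test_scouts_fire_on_flat_objective(self):
        # no candidate ever improves, so every source is eventually
        # abandoned and re-scouted
        res = bee_colony(lambda x: 1.0, SPACE, seed=2, budget=4000,
                         n_sources=10, limit=5)
        assert res.n_scouts >= 10

    def test_respects_bounds(self):
        res = bee_colony(quadratic, SPACE, seed=1, budget=500)
        assert SPACE.contains(res.x)


class TestBudgetMonotonicity:
    @pytest.mark.parametrize("algo", ["nm", "pso", "sbc"])
    def test_doubling_budget_never_hurts(self, algo):
        def run(budget):
            if algo == "nm":
                return nelder_mead(quadratic, [4.0, 4.0, 45.0], SPACE, budget=budget)
            if algo == "pso":
                return particle_swarm(quadratic, SPACE, seed=11, budget=budget)
            return bee_colony(quadratic, SPACE, seed=11, budget=budget)
        assert run(1200).value <= run(600).value + 1e-15


@pytest.fixture(scope="module")
def tiny_fit():
    """Structural fit with a minimal search space and budget."""
    std = StandardParameters()
    pair, _ = generate_model_subject(
        SyntheticSpec(fit=FitVariables(1.2, 1.1, 15.0)), std)
    space = SearchSpace(ql_bounds=(0.8, 2.0), qr_bounds=(0.8, 2.0),
                        ps_bounds=(8.0, 20.0), q_step=0.6, ps_step=6.0)
    config = FitConfig(budget=60, refine=False)
    return fit_subject(pair, std, space, config, seed=0)


class TestFitSubject:
    def test_full_algorithm_cost_cross_product(self, tiny_fit):
        combos = {(r.algorithm, r.cost) for r in tiny_fit.records}
        assert len(tiny_fit.records) == 9
        assert combos == {(a, c) for a in ("nm", "pso", "sbc")
                          for c in ("gamma1", "gamma2", "gamma3")}

    def test_best_is_minimum_gamma(self, tiny_fit):
        assert tiny_fit.best.gamma == min(r.gamma for r in tiny_fit.records)

    def test_parameters_within_bounds(self, tiny_fit):
        for r in tiny_fit.records:
            assert 0.8 <= r.params.Ql <= 2.0
            assert 0.8 <= r.params.Qr <= 2.0
            assert 8.0 <= r.params.Ps <= 20.0

    def test_evaluation_counts_within_budget(self, tiny_fit):
        for r in tiny_fit.records:
            assert r.n_evaluations <= 60 + 10  # NM may finish its last iteration

    def test_deterministic_given_seed(self, tiny_fit):
        std = StandardParameters()
        pair, _ = generate_model_subject(
            SyntheticSpec(fit=FitVariables(1.2, 1.1, 15.0)), std)
        space = SearchSpace(ql_bounds=(0.8, 2.0), qr_bounds=(0.8, 2.0),
                            ps_bounds=(8.0, 20.0), q_step=0.6, ps_step=6.0)
        config = FitConfig(budget=60, refine=False)
        again = fit_subject(pair, std, space, config, seed=0)
        assert again.best.params == tiny_fit.best.params
        assert again.best.gamma == tiny_fit.best.gamma


class TestSelfFit:
    def test_noiseless_self_fit_recovers_parameters(self):
        """End-to-end: a noiseless model-generated subject is recovered."""
        std = StandardParameters().with_fold_length(1.0)
        truth = FitVariables(1.2, 1.1, 15.0)
        pair, _ = generate_model_subject(SyntheticSpec(fit=truth), std)
        config = FitConfig(budget=300, algorithms=("nm",), costs=("gamma2",))
        res = fit_subject(pair, std, config=config, seed=0)
        assert res.best.gamma <= 0.05
        assert res.best.params.Ql == pytest.approx(truth.Ql, rel=0.05)
        assert res.best.params.Qr == pytest.approx(truth.Qr, rel=0.05)
        assert res.success.success
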