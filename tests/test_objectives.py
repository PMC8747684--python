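"""Regularizers and the three treatment objectives, cross-checked against
brute-force enumeration oracles."""

import math
from itertools import product

import numpy as np
import pytest

from combopt import (
    ObjectiveSpec,
    Regularizer,
    SequentialPlan,
    TableModel,
    TreatmentSpace,
    TreatmentVector,
    evaluate_objective,
    population_objective,
    regularize,
    sequential_objective,
    single_cell_objective,
)
from combopt.sweep import dense_grid_optimum, enumerate_grid
from combopt.synthetic import brute_force_best_plan, enumerate_table_plans


class TestRegularizers:
    @pytest.mark.parametrize("kind", list(Regularizer))
    def test_vanish_at_origin(self, kind):
        assert regularize(np.zeros(7), kind) == 0.0

    def test_direct_evaluations(self):
        assert regularize([100, 200, 0, 0, 0, 0, 0], "l1") == pytest.approx(300)
        assert regularize([3, 4, 0, 0, 0, 0, 0], "l2") == pytest.approx(25)
        e = math.e - 1
        assert regularize([e, e, 0, 0, 0, 0, 0], "ln") == pytest.approx(2.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            regularize([-1.0, 0.0], "l1")

    @pytest.mark.parametrize("kind", list(Regularizer))
    def test_strictly_increasing_in_every_coordinate(self, kind, rng):
        tau = rng.uniform(0, 1000, 5)
        base = regularize(tau, kind)
        for i in range(5):
            bumped = tau.copy()
            bumped[i] += 10.0
            assert regularize(bumped, kind) > base


class TestSingleCell:
    def test_lambda_zero_equals_viability(self, single_hill):
        spec = ObjectiveSpec(lambda_penalty=0.0, aggregation="single")
        tau = TreatmentVector([150.0, 300.0])
        assert single_cell_objective(tau, single_hill, spec) == pytest.approx(
            single_hill.evaluate(tau.doses)
        )

    def test_zero_dose_is_one_for_any_lambda(self, single_hill):
        spec = ObjectiveSpec(lambda_penalty=0.3, aggregation="single")
        assert single_cell_objective(np.zeros(2), single_hill, spec) == 1.0

    def test_affine_increasing_in_lambda(self, single_hill):
        tau = np.array([400.0, 100.0])
        space = TreatmentSpace(d=2)
        lams = [0.0, 1e-4, 1e-3, 1e-2]
        vals = [
            single_cell_objective(
                tau, single_hill,
                ObjectiveSpec(lambda_penalty=l, aggregation="single"), space,
            )
            for l in lams
        ]
        slopes = np.diff(vals) / np.diff(lams)
        assert np.all(np.diff(vals) >= 0)
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-9)  # affine
        assert slopes[0] == pytest.approx(regularize(tau, "l1"))

    def test_grid_argmin_matches_plain_loop_oracle(self, single_hill):
        """Vectorized dense-grid optimum equals a scalar-loop enumeration."""
        space = TreatmentSpace(d=2, alpha=2000.0)
        spec = ObjectiveSpec(
            lambda_penalty=1e-4, aggregation="single", reg_coords="normalized"
        )
        pts = enumerate_grid(space, 100.0)
        best_obj, best_tau = math.inf, None
        for tau in pts:  # independent scalar path
            obj = single_hill.evaluate(tau) + 1e-4 * (tau.sum() / space.alpha)
            if obj < best_obj:
                best_obj, best_tau = obj, tau
        res = dense_grid_optimum([single_hill], spec, space, 100.0)
        assert res.best_objective == pytest.approx(best_obj, abs=1e-12)
        np.testing.assert_allclose(res.best_treatment, best_tau)


class TestPopulation:
    def test_identical_models_max_equals_single(self, single_hill):
        spec_m = ObjectiveSpec(lambda_penalty=1e-4, aggregation="max")
        spec_s = ObjectiveSpec(lambda_penalty=1e-4, aggregation="single")
        tau = np.array([200.0, 900.0])
        space = TreatmentSpace(d=2)
        assert population_objective(
            tau, [single_hill, single_hill], spec_m, space
        ) == pytest.approx(single_cell_objective(tau, single_hill, spec_s, space))

    def test_max_and_mean_aggregation(self):
        m1 = TableModelLike(0.3)
        m2 = TableModelLike(0.7)
        tau = np.zeros(2) + 100.0
        space = TreatmentSpace(d=2)
        spec = ObjectiveSpec(lambda_penalty=0.0, aggregation="max")
        assert population_objective(tau, [m1, m2], spec, space) == pytest.approx(0.7)
        wspec = ObjectiveSpec(
            lambda_penalty=0.0, aggregation="weighted", weights=(0.5, 0.5)
        )
        assert population_objective(tau, [m1, m2], wspec, space) == pytest.approx(0.5)

    def test_weighted_never_exceeds_max(self, panel2d, rng):
        space = TreatmentSpace(d=2)
        wspec = ObjectiveSpec(lambda_penalty=0.0, aggregation="weighted", weights=(0.3, 0.7))
        mspec = ObjectiveSpec(lambda_penalty=0.0, aggregation="max")
        taus = rng.uniform(0, 4000, size=(50, 2))
        w = evaluate_objective(taus, panel2d, wspec, space)
        m = evaluate_objective(taus, panel2d, mspec, space)
        assert np.all(w <= m + 1e-12)

    def test_weights_models_mismatch(self, panel2d):
        spec = ObjectiveSpec(lambda_penalty=0.0, aggregation="weighted", weights=(1.0,))
        with pytest.raises(ValueError):
            population_objective(np.zeros(2), panel2d, spec)

    def test_empty_models_rejected(self):
        spec = ObjectiveSpec(aggregation="max")
        with pytest.raises(ValueError):
            population_objective(np.zeros(2), [], spec)


class TableModelLike:
    """Constant-viability stub for aggregation arithmetic."""

    def __init__(self, v):
        self.v = v
        self.label = f"const{v}"

    def evaluate(self, tau):
        return self.v if np.any(np.asarray(tau) > 0) else 1.0

    def evaluate_many(self, taus):
        taus = np.atleast_2d(taus)
        return np.where(taus.sum(axis=1) > 0, self.v, 1.0)


class TestSequential:
    def test_single_step_reduces_to_population(self, panel2d):
        space = TreatmentSpace(d=2)
        spec = ObjectiveSpec(lambda_penalty=1e-4, aggregation="max", n_steps=1)
        tau = TreatmentVector([500.0, 800.0])
        plan = SequentialPlan([tau])
        assert sequential_objective(plan, panel2d, spec, space) == pytest.approx(
            population_objective(tau, panel2d, spec, space)
        )

    def test_all_zero_plan(self, panel2d):
        space = TreatmentSpace(d=2, n_steps=2)
        spec = ObjectiveSpec(lambda_penalty=0.5, aggregation="max", n_steps=2)
        plan = SequentialPlan([TreatmentVector([0.0, 0.0])] * 2)
        assert sequential_objective(plan, panel2d, spec, space) == pytest.approx(1.0)

    def test_fig1_enumeration(self, fig1):
        """All 9 ordered pairs: best sequential 0.32 beats best repeated 0.36."""
        scores = enumerate_table_plans(fig1.models, 2)
        assert len(scores) == 9
        seq_best = min(v.max() for v in scores.values())
        ti_best = min(
            v.max() for p, v in scores.items() if p[0] == p[1]
        )
        assert seq_best == pytest.approx(0.32)
        assert ti_best == pytest.approx(0.36)

    @pytest.mark.parametrize("seed", range(5))
    def test_sequential_dominates_time_invariant_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        models = [
            TableModel(
                table={t: float(rng.uniform(0.05, 1.0)) for t in "ABCD"},
                label=f"c{i}",
            )
            for i in range(3)
        ]
        _, _, seq = brute_force_best_plan(models, 2)
        _, _, ti = brute_force_best_plan(models, 2, time_invariant=True)
        assert seq <= ti + 1e-12


def test_spec_validation():
    with pytest.raises(ValueError):
        ObjectiveSpec(lambda_penalty=-1)
    with pytest.raises(ValueError):
        ObjectiveSpec(aggregation="median")
    with pytest.raises(ValueError):
        ObjectiveSpec(aggregation="weighted")  # weights missing
    with pytest.raises(ValueError):
        ObjectiveSpec(aggregation="weighted", weights=(0.5, 0.2))
    with pytest.raises(ValueError):
        ObjectiveSpec(aggregation="max", weights=(1.0,))
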