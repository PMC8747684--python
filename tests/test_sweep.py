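"""Lambda sweeps, Pareto fronts, exhaustive baselines, and solution PCA."""

import numpy as np
import pytest

from combopt import (
    CmaesConfig,
    LambdaGrid,
    ObjectiveSpec,
    ParetoPoint,
    TreatmentSpace,
    best_single_drug,
    best_two_drug_ratio,
    lambda_sweep,
    pareto_front,
    treatment_pca,
)
from combopt.cmaes import TreatmentProblem
from combopt.objectives import evaluate_objective
from combopt.sweep import dense_grid_optimum, enumerate_grid


class TestLambdaGrid:
    def test_default_grid_has_25_values(self):
        grid = LambdaGrid()
        lams = grid.lambdas()
        assert lams.size == 25
        assert lams[0] == pytest.approx(1e-7)
        assert lams[-1] == pytest.approx(1e-1)

    def test_sequential_step_yields_121_values(self):
        assert LambdaGrid(-7, -1, 0.05).lambdas().size == 121

    def test_degenerate_grid_single_value(self):
        assert LambdaGrid(-3, -3, 0.25).lambdas().size == 1

    def test_validation(self):
        with pytest.raises(ValueError):
            LambdaGrid(-1, -7, 0.25)
        with pytest.raises(ValueError):
            LambdaGrid(-7, -1, 0)


class TestParetoFront:
    def test_single_point_is_its_own_front(self):
        pts = [ParetoPoint(100.0, 0.5, 1e-4)]
        assert pareto_front(pts) == pts

    def test_dominated_point_discarded(self):
        pts = [
            ParetoPoint(100.0, 0.5, 1e-3),
            ParetoPoint(200.0, 0.4, 1e-4),
            ParetoPoint(300.0, 0.45, 1e-5),
        ]
        front = pareto_front(pts)
        assert [(p.total_dose, p.proliferation) for p in front] == [
            (100.0, 0.5), (200.0, 0.4),
        ]

    def test_front_equals_all_pairs_check(self, rng):
        pts = [
            ParetoPoint(float(d), float(p), 0.0)
            for d, p in zip(rng.uniform(0, 8000, 40), rng.uniform(0, 1, 40))
        ]
        front = pareto_front(pts)
        coords = [(p.total_dose, p.proliferation) for p in pts]
        # quadratic-time oracle
        expected = {
            (d, p)
            for d, p in coords
            if not any(
                (d2 <= d and p2 <= p and (d2 < d or p2 < p)) for d2, p2 in coords
            )
        }
        assert {(p.total_dose, p.proliferation) for p in front} == expected

    def test_empty_sweep_rejected(self):
        with pytest.raises(ValueError):
            pareto_front([])


class TestBaselines:
    def test_single_drug_matches_plain_enumeration(self, panel2d, space2):
        spec = ObjectiveSpec(lambda_penalty=1e-4, regularizer="l1", aggregation="max")
        res = best_single_drug(panel2d, spec, space2, dose_step_nM=50.0)
        # independent loop over every drug/dose
        best = (np.inf, None)
        for i in range(2):
            for dose in np.arange(0.0, space2.alpha + 25.0, 50.0):
                tau = np.zeros(2)
                tau[i] = dose
                v = max(m.evaluate(tau) for m in panel2d)
                obj = v + 1e-4 * dose
                if obj < best[0]:
                    best = (obj, tau)
        assert res.best_objective == pytest.approx(best[0], abs=1e-12)
        np.testing.assert_allclose(res.best_treatment, best[1])

    def test_grid_sizes(self, panel2d, space2):
        # d * (alpha/step + 1) single-drug points at the documented defaults
        assert 7 * (8000 // 1 + 1) == 56_007
        spec = ObjectiveSpec(lambda_penalty=0.0, aggregation="max")
        res = best_single_drug(panel2d, spec, space2, dose_step_nM=400.0)
        assert res.config["method"] == "grid_single_drug"

    def test_large_lambda_gives_zero_dose(self, panel2d, space2):
        spec = ObjectiveSpec(lambda_penalty=1e-1, regularizer="l1", aggregation="max")
        res = best_single_drug(panel2d, spec, space2, dose_step_nM=50.0)
        assert res.total_dose == 0.0
        assert res.best_objective == pytest.approx(1.0)

    def test_monotone_model_lambda_zero_fills_the_cap(self, space2):
        from combopt.response import HillBlissProfile

        m = HillBlissProfile(ic50=[200.0, 5000.0], emax=[0.95, 0.3], hill=[1.0, 1.0])
        spec = ObjectiveSpec(lambda_penalty=0.0, aggregation="single")
        res = best_single_drug([m], spec, space2, dose_step_nM=50.0)
        assert res.total_dose == pytest.approx(space2.alpha)
        assert res.best_treatment[0] == pytest.approx(space2.alpha)  # most potent drug

    def test_pair_search_beats_its_endpoints(self, panel2d, space2):
        spec = ObjectiveSpec(lambda_penalty=1e-4, regularizer="l1", aggregation="max")
        pair = best_two_drug_ratio(panel2d, spec, space2, (0, 1), dose_step_nM=50.0)
        # ratio 0 / 1 recover single-drug treatments of each pair member
        for drug in (0, 1):
            doses = np.arange(0.0, space2.alpha + 25.0, 50.0)
            taus = np.zeros((doses.size, 2))
            taus[:, drug] = doses
            objs = evaluate_objective(taus, panel2d, spec, space2)
            assert pair.best_objective <= objs.min() + 1e-12

    def test_pair_matches_plain_enumeration(self, panel2d, space2):
        spec = ObjectiveSpec(lambda_penalty=1e-4, regularizer="l2", aggregation="max")
        res = best_two_drug_ratio(
            panel2d, spec, space2, (0, 1), ratio_step=0.25, dose_step_nM=400.0
        )
        best = np.inf
        for r in np.linspace(0, 1, 5):
            for total in np.arange(0.0, space2.alpha + 200.0, 400.0):
                tau = np.array([r * total, (1 - r) * total])
                v = max(m.evaluate(tau) for m in panel2d)
                best = min(best, v + 1e-4 * float((tau**2).sum()))
        assert res.best_objective == pytest.approx(best, abs=1e-9)

    def test_permuted_evaluation_order_same_optimum(self, panel2d, space2):
        spec = ObjectiveSpec(lambda_penalty=1e-4, regularizer="l1", aggregation="max")
        a = best_single_drug(panel2d, spec, space2, dose_step_nM=50.0)
        # drug order permuted: swap columns of the models' parameters
        swapped = [
            type(m)(
                ic50=m.ic50[::-1].copy(), emax=m.emax[::-1].copy(),
                hill=m.hill[::-1].copy(), label=m.label,
            )
            for m in panel2d
        ]
        b = best_single_drug(swapped, spec, space2, dose_step_nM=50.0)
        assert a.best_objective == pytest.approx(b.best_objective, abs=1e-12)

    def test_invalid_pair_rejected(self, panel2d, space2):
        spec = ObjectiveSpec(lambda_penalty=0.0, aggregation="max")
        with pytest.raises(ValueError):
            best_two_drug_ratio(panel2d, spec, space2, (0, 0))


class TestLambdaPathOracle:
    def test_dose_monotone_and_proliferation_monotone_under_l1(self, panel2d, space2):
        """On the exact per-lambda grid optima (brute force), total dose is
        non-increasing and proliferation non-decreasing as lambda grows."""
        grid_pts = enumerate_grid(space2, 100.0)
        doses, prolifs = [], []
        for lam in LambdaGrid(-7, -1, 0.5).lambdas():
            spec = ObjectiveSpec(
                lambda_penalty=float(lam), regularizer="l1", aggregation="max"
            )
            res = dense_grid_optimum(panel2d, spec, space2, 100.0, grid=grid_pts)
            doses.append(res.total_dose)
            prolifs.append(float(res.per_line_viability.max()))
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(doses, doses[1:]))
        assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(prolifs, prolifs[1:]))


@pytest.fixture(scope="module")
def sweep_result(panel2d, space2):
    spec = ObjectiveSpec(lambda_penalty=0.0, regularizer="l1", aggregation="max")
    prob = TreatmentProblem(panel2d, spec, space2)
    grid = LambdaGrid(-6, -2, 1.0)
    return lambda_sweep(prob, grid, CmaesConfig(seed=20, iterations=60), n_seeds=1)


class TestSweep:
    def test_entries_sorted_and_complete(self, sweep_result):
        lams = [e.lam for e in sweep_result.entries]
        assert lams == sorted(lams)
        assert len(lams) == 5

    def test_proliferation_strips_penalty(self, sweep_result):
        for e in sweep_result.entries:
            assert 0 < e.proliferation <= 1.0
            assert e.result.best_objective >= e.proliferation - 1e-9

    def test_frame_round_trip(self, sweep_result):
        df = sweep_result.to_frame()
        assert list(df["lambda"]) == [e.lam for e in sweep_result.entries]
        assert "total_dose_nM" in df.columns

    def test_warm_start_runs(self, panel2d, space2):
        spec = ObjectiveSpec(lambda_penalty=0.0, regularizer="l1", aggregation="max")
        prob = TreatmentProblem(panel2d, spec, space2)
        sw = lambda_sweep(
            prob, LambdaGrid(-5, -3, 1.0),
            CmaesConfig(seed=21, iterations=40), warm_start=True,
        )
        assert len(sw.entries) == 3

    def test_cmaes_matches_grid_oracle_per_lambda(self, panel2d, space2):
        """Optimizer optima track the dense-grid optima within 1% objective."""
        grid_pts = enumerate_grid(space2, 50.0)
        spec = ObjectiveSpec(lambda_penalty=0.0, regularizer="l1", aggregation="max")
        prob = TreatmentProblem(panel2d, spec, space2)
        for lam in LambdaGrid(-5, -2, 1.0).lambdas():
            sub = prob.with_lambda(float(lam))
            from combopt.cmaes import optimize_problem

            res = optimize_problem(sub, CmaesConfig(seed=22, iterations=100))
            oracle = dense_grid_optimum(
                panel2d, sub.objective_spec, space2, 50.0, grid=grid_pts
            )
            assert res.best_objective <= oracle.best_objective * 1.01 + 1e-12


class TestPca:
    def test_identical_treatments_flagged_degenerate(self):
        groups = {1e-4: [np.array([100.0, 200.0])] * 5}
        rep = treatment_pca(groups)
        assert rep.groups[0].degenerate
        assert np.all(rep.groups[0].explained_variance_ratio == 0)

    def test_rank_two_data_explained_by_two_components(self, rng):
        base = rng.uniform(0, 100, 5)
        u, v = rng.normal(size=5), rng.normal(size=5)
        pts = [base + rng.normal() * u + rng.normal() * v for _ in range(12)]
        rep = treatment_pca({1e-3: pts})
        evr = rep.groups[0].explained_variance_ratio
        assert evr[:2].sum() == pytest.approx(1.0, abs=1e-9)

    def test_ratios_nonneg_nonincreasing_sum_le_one(self, rng):
        pts = list(rng.uniform(0, 8000, size=(10, 7)))
        rep = treatment_pca({1e-2: pts})
        evr = rep.groups[0].explained_variance_ratio
        assert np.all(evr >= 0)
        assert np.all(np.diff(evr) <= 1e-12)
        assert evr.sum() <= 1 + 1e-9

    def test_small_group_skipped_with_warning(self, rng):
        groups = {1e-4: [rng.uniform(0, 10, 3)], 1e-3: list(rng.uniform(0, 10, (4, 3)))}
        with pytest.warns(UserWarning):
            rep = treatment_pca(groups)
        assert [g.lam for g in rep.groups] == [1e-3]
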