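"""Penalty sweeps, Pareto fronts, exhaustive baselines, and solution PCA.

A single penalty weight lambda is rarely defensible a priori, so treatments
are optimized over a log-spaced lambda grid (default exponents -7..-1 in
0.25 steps; 0.05 for sequential plans).  Each sweep point records the
optimized treatment's total dose and its *unpenalized* proliferation metric;
the non-dominated subset of those (dose, proliferation) pairs is the Pareto
front offered to the treatment-selection process.

Two exhaustive reference searches mirror conventional practice: the best
single-drug treatment (every drug, every 1 nM dose up to the cap) and the
best fixed-pair mixture (RAF+MEK inhibitor doses split at 5% ratio steps).
Per-lambda PCA over repeated warm-start runs quantifies solution variance —
near-interchangeable drugs induce continua of equivalent optima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product as _iterproduct
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from sklearn.decomposition import PCA

from combopt.cmaes import (
    CmaesConfig,
    OptimizationResult,
    TreatmentProblem,
    optimize_problem,
    run_restarts,
)
from combopt.domain import TreatmentSpace
from combopt.objectives import ObjectiveSpec, evaluate_objective, proliferation_metric
from combopt.response import ResponseModel


@dataclass(frozen=True)
class LambdaGrid:
    """Log grid of penalty weights: 10**(lo), ..., 10**(hi) at exponent_step."""

    exponent_lo: float = -7.0
    exponent_hi: float = -1.0
    exponent_step: float = 0.25

    def __post_init__(self):
        if self.exponent_lo > self.exponent_hi:
            raise ValueError("exponent_lo must be <= exponent_hi")
        if self.exponent_step <= 0:
            raise ValueError("exponent_step must be positive")

    def exponents(self) -> NDArray[np.float64]:
        n = int(round((self.exponent_hi - self.exponent_lo) / self.exponent_step)) + 1
        return self.exponent_lo + self.exponent_step * np.arange(n)

    def lambdas(self) -> NDArray[np.float64]:
        return 10.0 ** self.exponents()


@dataclass(frozen=True)
class SweepEntry:
    lam: float
    result: OptimizationResult
    total_dose: float
    proliferation: float


@dataclass
class SweepResult:
    """Lambda-indexed optimized treatments with their Pareto coordinates."""

    entries: list[SweepEntry]
    regularizer: str
    aggregation: str
    space: TreatmentSpace

    def __post_init__(self):
        self.entries = sorted(self.entries, key=lambda e: e.lam)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            row = {"lambda": e.lam}
            doses = e.result.best_treatment.reshape(self.space.n_steps, self.space.d)
            for s in range(self.space.n_steps):
                for i, name in enumerate(self.space.drug_names):
                    key = f"{name}_nM" if self.space.n_steps == 1 else f"step{s+1}_{name}_nM"
                    row[key] = doses[s, i]
            row["total_dose_nM"] = e.total_dose
            row["proliferation"] = e.proliferation
            row["objective"] = e.result.best_objective
            rows.append(row)
        if not rows:
            cols = ["lambda"]
            for s in range(self.space.n_steps):
                for name in self.space.drug_names:
                    cols.append(
                        f"{name}_nM" if self.space.n_steps == 1 else f"step{s+1}_{name}_nM"
                    )
            cols += ["total_dose_nM", "proliferation", "objective"]
            return pd.DataFrame(columns=cols)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ParetoPoint:
    """One non-dominated (total dose, proliferation) treatment."""

    total_dose: float
    proliferation: float
    lam: float
    seed: int | None = None


@dataclass
class GroupPca:
    lam: float
    loadings: NDArray[np.float64]
    explained_variance_ratio: NDArray[np.float64]
    projections: NDArray[np.float64]
    degenerate: bool = False


@dataclass
class PcaReport:
    """Per-lambda principal components of repeated optimization outcomes."""

    groups: list[GroupPca] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for i, r in enumerate(g.explained_variance_ratio):
                rows.append(
                    {
                        "lambda": g.lam,
                        "component": i + 1,
                        "explained_variance_ratio": r,
                        "degenerate": g.degenerate,
                    }
                )
        return pd.DataFrame(rows)


def _entry_from_result(
    res: OptimizationResult, lam: float, spec: ObjectiveSpec
) -> SweepEntry:
    prolif = proliferation_metric(res.per_line_viability, spec)
    return SweepEntry(
        lam=lam, result=res, total_dose=res.total_dose, proliferation=prolif
    )


def lambda_sweep(
    problem: TreatmentProblem,
    grid: LambdaGrid,
    cfg: CmaesConfig | None = None,
    warm_start: bool = False,
    n_seeds: int = 3,
) -> SweepResult:
    """Optimize at every lambda on the grid.

    Cold mode runs independent best-of-``n_seeds`` restarts per lambda from
    the even-split initial mean.  Warm mode runs one chain over ascending
    lambda, initializing each step's search mean at the previous optimum
    (the protocol used to probe solution variance).
    """
    cfg = cfg or CmaesConfig()
    entries: list[SweepEntry] = []
    prev_opt_norm: NDArray[np.float64] | None = None
    for lam in grid.lambdas():
        sub = problem.with_lambda(float(lam))
        try:
            if warm_start:
                run_cfg = cfg if prev_opt_norm is None else cfg.replace(
                    initial_mean=prev_opt_norm
                )
                res = optimize_problem(sub, run_cfg)
                prev_opt_norm = res.best_treatment / problem.space.alpha
            else:
                res = run_restarts(sub, cfg, n_seeds=n_seeds)
        except Exception as exc:
            raise RuntimeError(f"sweep failed at lambda={lam:g}") from exc
        entries.append(_entry_from_result(res, float(lam), sub.objective_spec))
    return SweepResult(
        entries=entries,
        regularizer=problem.objective_spec.regularizer.value,
        aggregation=problem.objective_spec.aggregation,
        space=problem.space,
    )


def _nondominated(points: list[tuple[float, float]]) -> list[int]:
    """Indices of the non-dominated subset minimizing both coordinates."""
    keep = []
    for i, (d_i, p_i) in enumerate(points):
        dominated = any(
            (d_j <= d_i and p_j <= p_i and (d_j < d_i or p_j < p_i))
            for j, (d_j, p_j) in enumerate(points)
            if j != i
        )
        if not dominated:
            keep.append(i)
    return keep


def pareto_front(sweep: SweepResult | Sequence[ParetoPoint]) -> list[ParetoPoint]:
    """Maximal non-dominated subset in (total dose, proliferation), both
    minimized, sorted by dose.  Duplicate coordinates are kept once."""
    if isinstance(sweep, SweepResult):
        pts = [
            ParetoPoint(e.total_dose, e.proliferation, e.lam, e.result.seed)
            for e in sweep.entries
        ]
    else:
        pts = list(sweep)
    if not pts:
        raise ValueError("empty sweep")
    idx = _nondominated([(p.total_dose, p.proliferation) for p in pts])
    seen = set()
    front = []
    for i in sorted(idx, key=lambda i: (pts[i].total_dose, pts[i].proliferation)):
        key = (pts[i].total_dose, pts[i].proliferation)
        if key not in seen:
            seen.add(key)
            front.append(pts[i])
    return front


def _grid_result(
    tau_nM: NDArray[np.float64], objective: float, models, spec, space, method: str
) -> OptimizationResult:
    vs = np.array([m.evaluate(tau_nM) for m in models])
    return OptimizationResult(
        best_treatment=tau_nM,
        best_objective=float(objective),
        total_dose=float(tau_nM.sum()),
        per_line_viability=vs,
        trace=[],
        seed=None,
        config={"method": method, "d": space.d, "alpha_nM": space.alpha},
    )


def best_single_drug(
    models: Sequence[ResponseModel],
    spec: ObjectiveSpec,
    space: TreatmentSpace,
    dose_step_nM: float = 1.0,
) -> OptimizationResult:
    """Exhaustive best single-drug treatment: every drug at every dose from
    0 to the cap in ``dose_step_nM`` steps.  Ties break toward lower dose,
    then lower drug index."""
    if spec.n_steps != 1:
        raise ValueError("single-drug baseline is defined for single-step specs")
    doses = np.arange(0.0, space.alpha + dose_step_nM / 2, dose_step_nM)
    best: tuple[float, float, int] | None = None  # (objective, dose, drug)
    best_tau = None
    for i in range(space.d):
        taus = np.zeros((doses.size, space.d))
        taus[:, i] = doses
        objs = evaluate_objective(taus, models, spec, space)
        j = int(np.argmin(objs))  # first minimum: lowest dose for this drug
        cand = (float(objs[j]), float(doses[j]), i)
        if best is None or cand < best:
            best = cand
            best_tau = taus[j]
    return _grid_result(best_tau, best[0], models, spec, space, "grid_single_drug")


def best_two_drug_ratio(
    models: Sequence[ResponseModel],
    spec: ObjectiveSpec,
    space: TreatmentSpace,
    drug_pair: tuple[int, int] = (0, 1),
    ratio_step: float = 0.05,
    dose_step_nM: float = 1.0,
) -> OptimizationResult:
    """Exhaustive best fixed-pair mixture: total doses 0..cap at
    ``dose_step_nM`` steps, split between the pair at ratios 0..100% in
    ``ratio_step`` steps.  Ties break toward lower total dose, then lower
    ratio."""
    i, j = drug_pair
    if i == j or not (0 <= i < space.d and 0 <= j < space.d):
        raise ValueError("drug_pair indices must be distinct and valid")
    if spec.n_steps != 1:
        raise ValueError("pair baseline is defined for single-step specs")
    totals = np.arange(0.0, space.alpha + dose_step_nM / 2, dose_step_nM)
    n_ratios = int(round(1.0 / ratio_step)) + 1
    ratios = np.linspace(0.0, 1.0, n_ratios)
    best: tuple[float, float, float] | None = None  # (objective, total, ratio)
    best_tau = None
    for r in ratios:
        taus = np.zeros((totals.size, space.d))
        taus[:, i] = r * totals
        taus[:, j] = (1.0 - r) * totals
        objs = evaluate_objective(taus, models, spec, space)
        k = int(np.argmin(objs))
        cand = (float(objs[k]), float(totals[k]), float(r))
        if best is None or cand < best:
            best = cand
            best_tau = taus[k]
    return _grid_result(best_tau, best[0], models, spec, space, "grid_two_drug_ratio")


def enumerate_grid(space: TreatmentSpace, dose_step_nM: float) -> NDArray[np.float64]:
    """All feasible single-step dose grid points (rows, nM).  Intended for
    low-dimensional brute-force oracles; the point count grows like the d-th
    power of the axis resolution."""
    axis = np.arange(0.0, space.alpha + dose_step_nM / 2, dose_step_nM)
    pts = np.array(list(_iterproduct(axis, repeat=space.d)))
    return pts[pts.sum(axis=1) <= space.alpha + 1e-9]


def dense_grid_optimum(
    models: Sequence[ResponseModel],
    spec: ObjectiveSpec,
    space: TreatmentSpace,
    dose_step_nM: float,
    grid: NDArray[np.float64] | None = None,
) -> OptimizationResult:
    """Brute-force single-step optimum over the full feasible dose grid
    (independent oracle for the stochastic optimizer on small problems).
    Ties break toward lower total dose."""
    pts = enumerate_grid(space, dose_step_nM) if grid is None else grid
    objs = evaluate_objective(pts, models, spec, space)
    order = np.lexsort((pts.sum(axis=1), objs))
    k = order[0]
    return _grid_result(pts[k], objs[k], models, spec, space, "grid_dense")


def treatment_pca(groups: dict[float, Sequence[NDArray[np.float64]]]) -> PcaReport:
    """Separate PCA per lambda group of discovered treatments (nM).

    Groups of fewer than two treatments are skipped with a warning; a group
    with (numerically) zero total variance is flagged degenerate and its
    ratios are reported as zeros.
    """
    report = PcaReport()
    for lam in sorted(groups):
        mat = np.atleast_2d(np.asarray(groups[lam], dtype=float))
        if mat.shape[0] < 2:
            warnings.warn(f"lambda={lam:g}: fewer than 2 treatments, skipping PCA")
            continue
        total_var = np.var(mat, axis=0, ddof=1).sum()
        n_comp = min(mat.shape[0] - 1, mat.shape[1])
        if total_var < 1e-24:
            report.groups.append(
                GroupPca(
                    lam=lam,
                    loadings=np.zeros((n_comp, mat.shape[1])),
                    explained_variance_ratio=np.zeros(n_comp),
                    projections=np.zeros((mat.shape[0], n_comp)),
                    degenerate=True,
                )
            )
            continue
        pca = PCA(n_components=n_comp)
        proj = pca.fit_transform(mat)
        report.groups.append(
            GroupPca(
                lam=lam,
                loadings=pca.components_,
                explained_variance_ratio=pca.explained_variance_ratio_,
                projections=proj,
            )
        )
    return report
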