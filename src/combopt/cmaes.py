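"""Constrained CMA-ES for treatment optimization.

Covariance Matrix Adaptation Evolution Strategy in the standard textbook
formulation (log-rank elite weights, cumulative step-size control, rank-one
plus rank-mu covariance adaptation), with one modification: solution
candidates are drawn from the search Gaussian *truncated to the feasible
treatment polytope* via the exact-HMC sampler, so every evaluated candidate
is feasible by construction and no per-candidate rejection loop is needed.
Truncated samples feed the updates unmodified — truncation is a drop-in
replacement for resampling until feasible, which induces the same candidate
distribution.

The optimizer works in normalized coordinates (doses / cap), where the
default initial step size sigma0 = 0.25 is meaningful; results are reported
in nM.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.typing import NDArray

from combopt.domain import LinearConstraintSet, TreatmentSpace, build_constraints
from combopt.objectives import ObjectiveSpec, make_flat_objective, per_line_viability
from combopt.response import ResponseModel
from combopt.sampling import (
    SamplerConfig,
    TruncatedGaussianSpec,
    find_interior_point,
    sample_truncated,
)

#: relative eigenvalue floor used when repairing a drifting covariance
_EIG_FLOOR = 1e-12


def default_population(dim: int) -> int:
    """Candidates per iteration: 4 + floor(3 ln D) (9 at D=7, 11 at D=14)."""
    return 4 + int(math.floor(3 * math.log(dim)))


def default_n_elites(population: int) -> int:
    """Elites per iteration: floor(population / 2) (4 of 9, 5 of 11)."""
    return population // 2


@dataclass(frozen=True)
class CmaesConfig:
    """Optimizer settings.

    population / n_elites default to the dimension-dependent textbook values;
    sigma0 is the initial step size in normalized coordinates; initial_mean
    (normalized, flat) defaults to the even split of the cap across drugs in
    every step.
    """

    population: int | None = None
    n_elites: int | None = None
    sigma0: float = 0.25
    iterations: int = 400
    seed: int | None = None
    initial_mean: NDArray[np.float64] | None = None

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.population is not None and self.population < 2:
            raise ValueError("population must be >= 2")
        if (
            self.population is not None
            and self.n_elites is not None
            and not (1 <= self.n_elites < self.population)
        ):
            raise ValueError("need 1 <= n_elites < population")

    def resolve(self, dim: int) -> tuple[int, int, NDArray[np.float64]]:
        pop = self.population if self.population is not None else default_population(dim)
        mu = self.n_elites if self.n_elites is not None else default_n_elites(pop)
        if not 1 <= mu < pop:
            raise ValueError("need 1 <= n_elites < population")
        if self.initial_mean is not None:
            mean = np.asarray(self.initial_mean, dtype=float).reshape(-1)
            if mean.size != dim:
                raise ValueError("initial_mean has wrong dimension")
        else:
            mean = None
        return pop, mu, mean

    def replace(self, **kw) -> "CmaesConfig":
        cur = dict(
            population=self.population,
            n_elites=self.n_elites,
            sigma0=self.sigma0,
            iterations=self.iterations,
            seed=self.seed,
            initial_mean=self.initial_mean,
        )
        cur.update(kw)
        return CmaesConfig(**cur)


@dataclass
class CmaesState:
    """Search-distribution state: mean, step size, covariance, evolution paths."""

    mean: NDArray[np.float64]
    sigma: float
    C: NDArray[np.float64]
    p_sigma: NDArray[np.float64]
    p_c: NDArray[np.float64]
    iteration: int = 0
    best_x: NDArray[np.float64] | None = None
    best_f: float = math.inf


@dataclass
class OptimizationResult:
    """Outcome of one optimization (or exhaustive baseline) run.

    best_treatment is the flat dose vector in nM (d * n_steps entries);
    trace records (iteration, best_objective_so_far, sigma, mean_dose_nM).
    """

    best_treatment: NDArray[np.float64]
    best_objective: float
    total_dose: float
    per_line_viability: NDArray[np.float64] | None
    trace: list[tuple[int, float, float, float]]
    seed: int | None
    config: dict

    def to_dict(self) -> dict:
        return {
            "best_treatment_nM": [float(v) for v in self.best_treatment],
            "best_objective": float(self.best_objective),
            "total_dose_nM": float(self.total_dose),
            "per_line_viability": None
            if self.per_line_viability is None
            else [float(v) for v in self.per_line_viability],
            "seed": self.seed,
            "config": self.config,
        }


@dataclass(frozen=True)
class TreatmentProblem:
    """A fully specified optimization problem: response models, objective
    spec, treatment space, and sampler tuning."""

    models: Sequence[ResponseModel]
    objective_spec: ObjectiveSpec
    space: TreatmentSpace
    sampler: SamplerConfig = field(default_factory=SamplerConfig)

    def flat_objective(self) -> Callable[[NDArray[np.float64]], float]:
        return make_flat_objective(self.models, self.objective_spec, self.space)

    def with_lambda(self, lam: float) -> "TreatmentProblem":
        return TreatmentProblem(
            self.models, self.objective_spec.with_lambda(lam), self.space, self.sampler
        )


def _repair_covariance(C: NDArray[np.float64]) -> NDArray[np.float64]:
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    floor = max(w.max(), _EIG_FLOOR) * _EIG_FLOOR
    if w.min() < floor:
        w = np.maximum(w, floor)
        C = (V * w) @ V.T
        C = 0.5 * (C + C.T)
    return C


def optimize(
    objective: Callable[[NDArray[np.float64]], float],
    space: TreatmentSpace,
    cfg: CmaesConfig | None = None,
    sampler: SamplerConfig | None = None,
    models: Sequence[ResponseModel] | None = None,
) -> OptimizationResult:
    """Minimize ``objective`` (defined on flat normalized coordinates) over
    the feasible polytope of ``space`` with constrained CMA-ES.

    Runs exactly ``cfg.iterations`` iterations.  Each iteration draws
    ``population`` feasible candidates from N(mean, sigma^2 C) truncated to
    the domain, ranks them, and applies the standard mean, step-size and
    covariance updates using the top ``n_elites``.  Returns the best feasible
    point ever evaluated (in nM), with the per-iteration best-so-far trace.

    ``models``, if given, are used to report the unpenalized per-line
    viabilities at the optimum.
    """
    cfg = cfg or CmaesConfig()
    sampler = sampler or SamplerConfig()
    D = space.dim
    pop, mu, mean0 = cfg.resolve(D)
    cons = build_constraints(space, normalized=True)
    rng = np.random.default_rng(cfg.seed)

    # textbook constants (log-rank weights over the elites, zero otherwise)
    ws = np.log((pop + 1) / 2) - np.log(np.arange(1, mu + 1))
    ws = ws / ws.sum()
    mu_eff = 1.0 / float((ws**2).sum())
    c_sigma = (mu_eff + 2) / (D + mu_eff + 5)
    d_sigma = 1 + 2 * max(0.0, math.sqrt((mu_eff - 1) / (D + 1)) - 1) + c_sigma
    c_c = (4 + mu_eff / D) / (D + 4 + 2 * mu_eff / D)
    c_1 = 2 / ((D + 1.3) ** 2 + mu_eff)
    c_mu = min(1 - c_1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((D + 2) ** 2 + mu_eff))
    chi_n = math.sqrt(D) * (1 - 1 / (4 * D) + 1 / (21 * D * D))

    mean = mean0 if mean0 is not None else space.even_split(normalized=True)
    state = CmaesState(
        mean=mean.copy(),
        sigma=cfg.sigma0,
        C=np.eye(D),
        p_sigma=np.zeros(D),
        p_c=np.zeros(D),
    )
    chain_start = find_interior_point(cons)
    trace: list[tuple[int, float, float, float]] = []

    for k in range(1, cfg.iterations + 1):
        state.C = _repair_covariance(state.C)
        tg = TruncatedGaussianSpec(state.mean, state.sigma**2 * state.C, cons)
        xs = sample_truncated(tg, pop, sampler, start=chain_start, rng=rng)
        chain_start = xs[-1]
        fs = np.array([objective(x) for x in xs])
        if not np.all(np.isfinite(fs)):
            bad = xs[~np.isfinite(fs)][0]
            raise RuntimeError(
                "non-finite objective value during optimization; state dump: "
                + json.dumps(
                    {
                        "iteration": k,
                        "candidate": bad.tolist(),
                        "mean": state.mean.tolist(),
                        "sigma": state.sigma,
                    }
                )
            )
        order = np.argsort(fs, kind="stable")
        if fs[order[0]] < state.best_f:
            state.best_f = float(fs[order[0]])
            state.best_x = xs[order[0]].copy()

        deltas = (xs - state.mean) / state.sigma
        delta_w = ws @ deltas[order[:mu]]
        state.mean = state.mean + state.sigma * delta_w

        # step-size control (whitening via eigendecomposition of C)
        evals, evecs = np.linalg.eigh(state.C)
        evals = np.maximum(evals, _EIG_FLOOR * evals.max())
        C_inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
        state.p_sigma = (1 - c_sigma) * state.p_sigma + math.sqrt(
            c_sigma * (2 - c_sigma) * mu_eff
        ) * (C_inv_sqrt @ delta_w)
        state.sigma *= math.exp(
            (c_sigma / d_sigma) * (np.linalg.norm(state.p_sigma) / chi_n - 1)
        )

        # covariance adaptation (rank-one + rank-mu)
        h_sigma = float(
            np.linalg.norm(state.p_sigma) / math.sqrt(1 - (1 - c_sigma) ** (2 * k))
            < (1.4 + 2 / (D + 1)) * chi_n
        )
        state.p_c = (1 - c_c) * state.p_c + h_sigma * math.sqrt(
            c_c * (2 - c_c) * mu_eff
        ) * delta_w
        elite_deltas = deltas[order[:mu]]
        rank_mu = (elite_deltas.T * ws) @ elite_deltas
        state.C = (
            (1 - c_1 - c_mu) * state.C
            + c_1
            * (
                np.outer(state.p_c, state.p_c)
                + (1 - h_sigma) * c_c * (2 - c_c) * state.C
            )
            + c_mu * rank_mu
        )
        state.iteration = k
        mean_dose_nM = float(np.sum(state.mean) * space.alpha / space.n_steps)
        trace.append((k, state.best_f, float(state.sigma), mean_dose_nM))

    best_nM = state.best_x * space.alpha
    plv = None
    if models is not None:
        plv = per_line_viability(models, space, state.best_x)
    return OptimizationResult(
        best_treatment=best_nM,
        best_objective=state.best_f,
        total_dose=float(best_nM.sum()),
        per_line_viability=plv,
        trace=trace,
        seed=cfg.seed,
        config={
            "population": pop,
            "n_elites": mu,
            "sigma0": cfg.sigma0,
            "iterations": cfg.iterations,
            "d": space.d,
            "n_steps": space.n_steps,
            "alpha_nM": space.alpha,
        },
    )


def optimize_problem(
    problem: TreatmentProblem, cfg: CmaesConfig | None = None
) -> OptimizationResult:
    """Run :func:`optimize` on a :class:`TreatmentProblem`."""
    return optimize(
        problem.flat_objective(),
        problem.space,
        cfg,
        problem.sampler,
        models=problem.models,
    )


def run_restarts(
    problem: TreatmentProblem,
    cfg: CmaesConfig | None = None,
    n_seeds: int = 3,
) -> OptimizationResult:
    """Best-of-n restarts: run the optimizer with seeds seed+0..seed+n-1 and
    return the result with the lowest objective.  All per-seed results are
    attached as ``result.restarts``."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    cfg = cfg or CmaesConfig()
    base = cfg.seed if cfg.seed is not None else 0
    results: list[OptimizationResult] = []
    errors: list[Exception] = []
    for i in range(n_seeds):
        try:
            results.append(optimize_problem(problem, cfg.replace(seed=base + i)))
        except Exception as exc:  # propagate only if every seed fails
            errors.append(exc)
    if not results:
        raise RuntimeError(f"all {n_seeds} restarts failed") from errors[0]
    best = min(results, key=lambda r: r.best_objective)
    best.restarts = results  # type: ignore[attr-defined]
    return best
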