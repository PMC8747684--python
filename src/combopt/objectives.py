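"""Regularized treatment-optimization objectives.

Three regularizers serve as idealized adverse-effect surrogates,

    R_L1(tau) = sum_i |tau_i|        (total dose)
    R_L2(tau) = sum_i tau_i^2        (sum of squares; favors balanced mixes)
    R_ln(tau) = sum_i ln(1 + tau_i)  (favors few drugs at high dose)

and three problem classes share the form  proliferation + lambda * penalty:

* single cell line:       V_c(tau) + lambda R(tau)
* population (max):       max_c V_c(tau) + lambda R(tau)
* population (weighted):  sum_c w_c V_c(tau) + lambda R(tau)
* sequential plan:        agg_c prod_i V_c(tau_i) + lambda sum_i R(tau_i)

All are minimized.  By default the regularizer is evaluated in raw nM
coordinates: with an 8000 nM cap this pins the useful lambda range to
roughly [1e-7, 1e-1] — at 1e-7 the L1 penalty of a full-cap dose is ~1e-3
(dose freely, most aggressive treatments), at 1e-1 it is ~800 (administer
nothing).  Evaluating in normalized coordinates tau/alpha is available as a
config switch (``reg_coords="normalized"``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray

from combopt.domain import SequentialPlan, TreatmentSpace, TreatmentVector
from combopt.response import ResponseModel, plan_viability, viability


class Regularizer(str, enum.Enum):
    L1 = "l1"
    L2 = "l2"
    LN = "ln"


@dataclass(frozen=True)
class ObjectiveSpec:
    """What to minimize: penalty weight, regularizer, aggregation, plan length.

    ``aggregation`` is 'single' (one cell line), 'max' (worst line of a
    population) or 'weighted' (weights over lines, summing to 1; uniform
    weights give the average-proliferation objective).  ``reg_coords``
    selects the coordinate convention the regularizer sees.
    """

    lambda_penalty: float = 0.0
    regularizer: Regularizer = Regularizer.L1
    aggregation: str = "single"
    weights: tuple[float, ...] | None = None
    n_steps: int = 1
    reg_coords: str = "nM"

    def __post_init__(self):
        object.__setattr__(self, "regularizer", Regularizer(self.regularizer))
        if self.lambda_penalty < 0:
            raise ValueError("lambda_penalty must be >= 0")
        if self.aggregation not in ("single", "max", "weighted"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.reg_coords not in ("normalized", "nM"):
            raise ValueError(f"unknown reg_coords {self.reg_coords!r}")
        if (self.weights is not None) != (self.aggregation == "weighted"):
            raise ValueError("weights present iff aggregation == 'weighted'")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must be nonnegative and sum to 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def with_lambda(self, lam: float) -> "ObjectiveSpec":
        return ObjectiveSpec(
            lambda_penalty=lam,
            regularizer=self.regularizer,
            aggregation=self.aggregation,
            weights=self.weights,
            n_steps=self.n_steps,
            reg_coords=self.reg_coords,
        )


def regularize(tau: ArrayLike, kind: Regularizer | str) -> float:
    """Evaluate one regularizer; units follow the coordinates passed in."""
    return float(regularize_many(np.atleast_2d(np.asarray(tau, float)), kind)[0])


def regularize_many(taus: NDArray[np.float64], kind: Regularizer | str) -> NDArray[np.float64]:
    """Vectorized regularizer over an (n, d) treatment matrix."""
    kind = Regularizer(kind)
    taus = np.atleast_2d(np.asarray(taus, dtype=float))
    if np.any(taus < 0):
        raise ValueError("regularizers are defined for nonnegative doses")
    if kind is Regularizer.L1:
        return taus.sum(axis=1)
    if kind is Regularizer.L2:
        return (taus**2).sum(axis=1)
    return np.log1p(taus).sum(axis=1)


def _as_doses(tau) -> NDArray[np.float64]:
    if isinstance(tau, TreatmentVector):
        return tau.doses
    return np.asarray(tau, dtype=float).reshape(-1)


def _reg_input(tau_nM: NDArray[np.float64], spec: ObjectiveSpec, space: TreatmentSpace):
    return tau_nM / space.alpha if spec.reg_coords == "normalized" else tau_nM


def _aggregate(vs: NDArray[np.float64], spec: ObjectiveSpec) -> NDArray[np.float64]:
    """Aggregate per-line viabilities (n_lines, ...) over axis 0."""
    if spec.aggregation == "weighted":
        w = np.asarray(spec.weights, dtype=float)
        return np.tensordot(w, vs, axes=(0, 0))
    if spec.aggregation == "max":
        return vs.max(axis=0)
    return vs[0]


def single_cell_objective(
    tau, model: ResponseModel, spec: ObjectiveSpec, space: TreatmentSpace | None = None
) -> float:
    """V_c(tau) + lambda R(tau) for one cell line; tau in nM."""
    if spec.aggregation != "single" or spec.n_steps != 1:
        raise ValueError("spec must have aggregation='single' and n_steps=1")
    return population_objective(tau, [model], spec, space)


def population_objective(
    tau,
    models: Sequence[ResponseModel],
    spec: ObjectiveSpec,
    space: TreatmentSpace | None = None,
) -> float:
    """Aggregated single-step objective over a population; tau in nM."""
    if not models:
        raise ValueError("models must be non-empty")
    if spec.aggregation == "weighted" and len(spec.weights) != len(models):
        raise ValueError("weights and models length mismatch")
    doses = _as_doses(tau)
    if space is None:
        space = TreatmentSpace(d=doses.size)
    vs = np.array([viability(m, doses) for m in models])
    agg = float(_aggregate(vs, spec))
    reg = regularize(_reg_input(doses, spec, space), spec.regularizer)
    return agg + spec.lambda_penalty * reg


def sequential_objective(
    plan: SequentialPlan,
    models: Sequence[ResponseModel],
    spec: ObjectiveSpec,
    space: TreatmentSpace | None = None,
) -> float:
    """agg_c prod_i V_c(tau_i) + lambda sum_i R(tau_i); plan in nM."""
    if not models:
        raise ValueError("models must be non-empty")
    if plan.n_steps != spec.n_steps:
        raise ValueError(f"plan has {plan.n_steps} steps, spec expects {spec.n_steps}")
    if space is None:
        space = TreatmentSpace(d=plan.d, n_steps=plan.n_steps)
    prods = np.array([plan_viability(m, plan) for m in models])
    agg = float(_aggregate(prods, spec))
    reg = sum(
        regularize(_reg_input(s.doses, spec, space), spec.regularizer)
        for s in plan.steps
    )
    return agg + spec.lambda_penalty * reg


def evaluate_objective(
    taus_nM: ArrayLike,
    models: Sequence[ResponseModel],
    spec: ObjectiveSpec,
    space: TreatmentSpace,
) -> NDArray[np.float64]:
    """Vectorized single-step objective over an (n, d) dose matrix in nM.

    The workhorse of the exhaustive grid baselines: a dense dose grid is one
    matrix evaluation per cell line.
    """
    taus = np.atleast_2d(np.asarray(taus_nM, dtype=float))
    vs = np.stack([m.evaluate_many(taus) for m in models])  # (n_lines, n)
    agg = _aggregate(vs, spec)
    reg = regularize_many(_reg_input(taus, spec, space), spec.regularizer)
    return agg + spec.lambda_penalty * reg


def proliferation_metric(
    vs_per_line: NDArray[np.float64], spec: ObjectiveSpec
) -> float:
    """The unpenalized proliferation coordinate recorded for sweeps/Pareto:
    V_c for 'single', max_c V_c for 'max', the weighted mean for 'weighted'."""
    return float(_aggregate(np.asarray(vs_per_line, dtype=float), spec))


def make_flat_objective(
    models: Sequence[ResponseModel],
    spec: ObjectiveSpec,
    space: TreatmentSpace,
) -> Callable[[NDArray[np.float64]], float]:
    """Objective on flat *normalized* coordinates of length d * n_steps, as
    consumed by the optimizer.  Handles both single-step and sequential specs.
    """
    if spec.n_steps != space.n_steps:
        raise ValueError("spec.n_steps must match space.n_steps")
    if spec.aggregation == "single" and len(models) != 1:
        raise ValueError("'single' aggregation expects exactly one model")
    if spec.aggregation == "weighted" and len(spec.weights) != len(models):
        raise ValueError("weights and models length mismatch")

    def objective(x: NDArray[np.float64]) -> float:
        steps_nM = np.asarray(x, dtype=float).reshape(space.n_steps, space.d) * space.alpha
        vs = np.stack([m.evaluate_many(steps_nM) for m in models])  # (lines, steps)
        prods = vs.prod(axis=1)
        agg = float(_aggregate(prods, spec))
        reg = float(
            regularize_many(_reg_input(steps_nM, spec, space), spec.regularizer).sum()
        )
        return agg + spec.lambda_penalty * reg

    return objective


def per_line_viability(
    models: Sequence[ResponseModel], space: TreatmentSpace, x_norm: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Per-line plan viability (product over steps) at flat normalized x."""
    steps_nM = np.asarray(x_norm, dtype=float).reshape(space.n_steps, space.d) * space.alpha
    vs = np.stack([m.evaluate_many(steps_nM) for m in models])
    return vs.prod(axis=1)
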