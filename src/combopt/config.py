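"""Run configuration: schema, validation, defaults, seed fan-out.

A run is fully described by one YAML/JSON document.  Defaults reproduce the
study settings: 7 drugs, 8000 nM per-step cap, lambda exponents -7..-1 in
0.25 steps (0.05 for sequential runs), 400 CMA-ES iterations, sigma0 = 0.25,
3 restart seeds.  Exactly one response-model source must be given: a panel
CSV, a discrete viability-table CSV, or a generator spec.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, PrivateAttr, model_validator

from combopt.cmaes import CmaesConfig, TreatmentProblem
from combopt.domain import TreatmentSpace
from combopt.objectives import ObjectiveSpec, Regularizer
from combopt.response import load_panel_csv, load_table_csv
from combopt.sampling import SamplerConfig
from combopt.sweep import LambdaGrid
from combopt.synthetic import PanelSpec, generate_panel


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SpaceConfig(_Strict):
    d: int = 7
    alpha_nM: float = 8000.0
    n_steps: int = 1
    drug_names: list[str] | None = None

    def build(self) -> TreatmentSpace:
        return TreatmentSpace(
            d=self.d,
            alpha=self.alpha_nM,
            n_steps=self.n_steps,
            drug_names=self.drug_names or [],
        )


class GeneratorConfig(_Strict):
    n_lines: int = 12
    seed: int | None = None  # defaults to the global seed
    ic50_log_range: tuple[float, float] = (10.0, 5000.0)
    emax_range: tuple[float, float] = (0.6, 1.0)
    hill_range: tuple[float, float] = (0.8, 2.0)
    fraction_resistant: float = 0.0
    interchangeable_pairs: list[tuple[int, int]] = Field(default_factory=list)
    pair_jitter: float = 0.0
    interaction_density: float = 0.0
    gamma_range: tuple[float, float] = (0.0, 1.0)

    def build(self, d: int, fallback_seed: int) -> PanelSpec:
        return PanelSpec(
            n_lines=self.n_lines,
            d=d,
            seed=self.seed if self.seed is not None else fallback_seed,
            ic50_log_range=self.ic50_log_range,
            emax_range=self.emax_range,
            hill_range=self.hill_range,
            fraction_resistant=self.fraction_resistant,
            interchangeable_pairs=tuple(map(tuple, self.interchangeable_pairs)),
            pair_jitter=self.pair_jitter,
            interaction_density=self.interaction_density,
            gamma_range=self.gamma_range,
        )


class ResponseConfig(_Strict):
    panel_file: str | None = None
    table_file: str | None = None
    generate: GeneratorConfig | None = None

    @model_validator(mode="after")
    def _one_source(self):
        n = sum(x is not None for x in (self.panel_file, self.table_file, self.generate))
        if n != 1:
            raise ValueError(
                "exactly one response-model source required: "
                "panel_file | table_file | generate"
            )
        return self


class ObjectiveConfig(_Strict):
    lambda_penalty: float = Field(default=1e-4, alias="lambda")
    regularizer: str = "l1"
    aggregation: str = "max"
    weights: list[float] | None = None
    reg_coords: str = "nM"
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    def build(self, n_steps: int) -> ObjectiveSpec:
        return ObjectiveSpec(
            lambda_penalty=self.lambda_penalty,
            regularizer=Regularizer(self.regularizer),
            aggregation=self.aggregation,
            weights=None if self.weights is None else tuple(self.weights),
            n_steps=n_steps,
            reg_coords=self.reg_coords,
        )


class OptimizerConfig(_Strict):
    iterations: int = 400
    sigma0: float = 0.25
    population: int | None = None
    n_elites: int | None = None
    n_seeds: int = 3

    @model_validator(mode="after")
    def _elites_lt_population(self):
        if (
            self.population is not None
            and self.n_elites is not None
            and self.n_elites >= self.population
        ):
            raise ValueError("n_elites must be < population")
        return self

    def build(self, seed: int) -> CmaesConfig:
        return CmaesConfig(
            population=self.population,
            n_elites=self.n_elites,
            sigma0=self.sigma0,
            iterations=self.iterations,
            seed=seed,
        )


class SamplerBlockConfig(_Strict):
    method: str = "hmc"
    travel_time: float = math.pi / 2
    burn_in: int = 50
    thin: int = 1

    def build(self) -> SamplerConfig:
        return SamplerConfig(
            method=self.method,
            travel_time=self.travel_time,
            burn_in=self.burn_in,
            thin=self.thin,
        )


class SweepConfig(_Strict):
    exponent_lo: float = -7.0
    exponent_hi: float = -1.0
    exponent_step: float | None = None  # 0.25, or 0.05 for sequential runs
    warm_start: bool = False

    def build(self, n_steps: int) -> LambdaGrid:
        step = self.exponent_step
        if step is None:
            step = 0.05 if n_steps > 1 else 0.25
        return LambdaGrid(self.exponent_lo, self.exponent_hi, step)


class RunConfig(_Strict):
    """Validated top-level configuration; see module docstring."""

    space: SpaceConfig = Field(default_factory=SpaceConfig)
    response: ResponseConfig
    objective: ObjectiveConfig = Field(default_factory=ObjectiveConfig)
    optimizer: OptimizerConfig = Field(default_factory=OptimizerConfig)
    sampler: SamplerBlockConfig = Field(default_factory=SamplerBlockConfig)
    sweep: SweepConfig = Field(default_factory=SweepConfig)
    output_dir: str = "results"
    seed: int = 0

    # directory the config file was loaded from; resolves relative paths
    _base_dir: Path = PrivateAttr(default=Path("."))

    def resolve_path(self, p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else self._base_dir / path

    def load_models(self):
        r = self.response
        if r.panel_file is not None:
            return load_panel_csv(self.resolve_path(r.panel_file))
        if r.table_file is not None:
            return load_table_csv(self.resolve_path(r.table_file))
        return generate_panel(r.generate.build(self.space.d, self.seed))

    def build_problem(self) -> TreatmentProblem:
        space = self.space.build()
        return TreatmentProblem(
            models=self.load_models(),
            objective_spec=self.objective.build(space.n_steps),
            space=space,
            sampler=self.sampler.build(),
        )

    def to_dict(self) -> dict:
        return self.model_dump(by_alias=True, mode="json")

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def derive_seed(global_seed: int, stream: int) -> int:
    """Deterministic per-stream seed fan-out (counter-based); stays < 2^31
    and is stable under adding new streams."""
    ss = np.random.SeedSequence((int(global_seed), int(stream)))
    return int(ss.generate_state(1, dtype="uint32")[0] % (2**31))


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected and violations are reported with their field
    paths; referenced model files must exist at load time.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    cfg = RunConfig.model_validate(raw)
    cfg._base_dir = path.parent
    for f in (cfg.response.panel_file, cfg.response.table_file):
        if f is not None and not cfg.resolve_path(f).exists():
            raise FileNotFoundError(f"referenced model file not found: {f}")
    return cfg
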