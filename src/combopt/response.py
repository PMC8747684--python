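"""Cell-line viability models and sequential-plan composition.

A response model predicts, for one cell line c, the relative proliferation
V_c(tau) in (0, 1]: the ratio of treated to untreated cell count after a
fixed treatment duration, with V_c(0) = 1 by normalization.  The package is
model-agnostic — any callable satisfying this contract plugs into the
optimizer — and ships two concrete families:

* :class:`HillBlissProfile` — a parametric multi-drug surrogate combining
  per-drug Hill dose-response curves under Bliss independence, with optional
  pairwise interaction modifiers for synergy/antagonism.
* :class:`TableModel` — a finite table of named discrete treatments with
  per-cell-line viabilities, for worked toy examples and brute-force
  enumeration.

Sequential plans compose multiplicatively: under exponential clonal growth
with drug-dependent rates, the relative cell count after steps tau_1..tau_n
is the product of per-step viabilities.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from combopt.domain import SequentialPlan, TreatmentVector

#: Viability floor guarding log/division; far below any realistic readout.
V_FLOOR = 1e-300


class ResponseModel(abc.ABC):
    """Contract: tau (nonneg, length d) -> relative proliferation in (0, 1+eps].

    ``evaluate`` must accept any nonnegative dose vector (feasibility is the
    optimizer's concern, not the model's) and satisfy V(0) = 1 exactly.
    Subclasses may additionally vectorize over an (n, d) treatment matrix via
    ``evaluate_many``.
    """

    label: str = ""

    @abc.abstractmethod
    def evaluate(self, tau: ArrayLike) -> float:
        ...

    def evaluate_many(self, taus: ArrayLike) -> NDArray[np.float64]:
        arr = np.atleast_2d(np.asarray(taus, dtype=float))
        return np.array([self.evaluate(row) for row in arr])

    def _check_contract(self, d: int) -> None:
        v0 = self.evaluate(np.zeros(d))
        if abs(v0 - 1.0) > 1e-12:
            raise ValueError(f"model {self.label!r} violates V(0)=1: got {v0}")


@dataclass
class HillBlissProfile(ResponseModel):
    """Multi-drug viability surrogate: per-drug Hill curves x Bliss product.

    Each drug i contributes an independent fractional effect
    ``E_i * u_i`` where ``u_i = tau_i^h_i / (ic50_i^h_i + tau_i^h_i)`` is the
    Hill occupancy, so the Bliss-independent combination viability is

        V(tau) = prod_i (1 - E_i u_i) * prod_{(i,j)} s_ij(tau),

    with an optional bounded pairwise modifier
    ``s_ij = exp(-gamma_ij * u_i * u_j)`` (gamma >= 0 gives synergy; s_ij = 1
    whenever either dose is zero, so single-drug behavior is untouched).

    Parameters
    ----------
    ic50 : per-drug half-maximal concentrations, nM (> 0).
    emax : per-drug maximal fractional effects in [0, 1].
    hill : per-drug Hill slopes (> 0).
    interactions : map (i, j) -> gamma_ij >= 0.
    label : cell-line identifier.
    """

    ic50: NDArray[np.float64]
    emax: NDArray[np.float64]
    hill: NDArray[np.float64]
    interactions: dict[tuple[int, int], float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        self.ic50 = np.asarray(self.ic50, dtype=float).reshape(-1)
        self.emax = np.asarray(self.emax, dtype=float).reshape(-1)
        self.hill = np.asarray(self.hill, dtype=float).reshape(-1)
        d = self.ic50.size
        if not (self.emax.size == d and self.hill.size == d):
            raise ValueError("ic50, emax, hill must have equal length")
        if np.any(self.ic50 <= 0) or np.any(self.hill <= 0):
            raise ValueError("ic50 and hill must be positive")
        if np.any(self.emax < 0) or np.any(self.emax > 1):
            raise ValueError("emax must lie in [0, 1]")
        for (i, j), g in self.interactions.items():
            if not (0 <= i < d and 0 <= j < d and i != j):
                raise ValueError(f"bad interaction pair {(i, j)}")
            if g < 0:
                raise ValueError("interaction exponents must be >= 0")
        self._check_contract(d)

    @property
    def d(self) -> int:
        return self.ic50.size

    def _occupancy(self, taus: NDArray[np.float64]) -> NDArray[np.float64]:
        # tau^h / (ic50^h + tau^h), numerically safe at tau = 0
        with np.errstate(divide="ignore"):
            ratio = np.where(taus > 0, (taus / self.ic50) ** self.hill, 0.0)
        return ratio / (1.0 + ratio)

    def evaluate_many(self, taus: ArrayLike) -> NDArray[np.float64]:
        arr = np.atleast_2d(np.asarray(taus, dtype=float))
        if arr.shape[1] != self.d:
            raise ValueError(f"expected {self.d} doses, got {arr.shape[1]}")
        if np.any(arr < 0):
            raise ValueError("negative dose")
        u = self._occupancy(arr)
        v = np.prod(1.0 - self.emax * u, axis=1)
        if self.interactions:
            log_s = np.zeros(arr.shape[0])
            for (i, j), g in self.interactions.items():
                log_s -= g * u[:, i] * u[:, j]
            v = v * np.exp(log_s)
        return np.maximum(v, V_FLOOR)

    def evaluate(self, tau: ArrayLike) -> float:
        tau = np.asarray(tau, dtype=float).reshape(-1)
        return float(self.evaluate_many(tau[None, :])[0])


@dataclass
class TableModel(ResponseModel):
    """Viability table over a finite set of named discrete treatments.

    ``table`` maps treatment name -> viability in (0, 1] for one cell line.
    A zero-dose pseudo-treatment is implicit: ``evaluate(None)`` and the
    reserved name ``"none"`` both return 1.
    """

    table: dict[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        for name, v in self.table.items():
            if not (0 < v <= 1):
                raise ValueError(f"table entry {name!r} = {v} outside (0, 1]")

    @property
    def treatments(self) -> list[str]:
        return sorted(self.table)

    def evaluate(self, tau) -> float:
        if tau is None or tau == "none":
            return 1.0
        try:
            return self.table[tau]
        except KeyError:
            raise KeyError(f"unknown treatment {tau!r}") from None


@dataclass(frozen=True)
class GrowthParams:
    """Exponential-growth bookkeeping for one treatment step.

    eta0 is the untreated growth rate per hour; duration_h the step length T
    (default 72 h, the assay horizon the response models are normalized to).
    """

    eta0: float = 0.02
    duration_h: float = 72.0

    def __post_init__(self):
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")


def viability(model: ResponseModel, tau) -> float:
    """Relative proliferation V_c(tau) for a single treatment."""
    if isinstance(tau, TreatmentVector):
        tau = tau.doses
    return model.evaluate(tau)


def growth_rate_from_viability(V: float, gp: GrowthParams) -> float:
    """Invert V = exp(eta(tau) T) / exp(eta(0) T) for the treated rate:
    eta(tau) = eta0 + ln(V) / T."""
    if V <= 0:
        raise ValueError("viability must be positive")
    return gp.eta0 + float(np.log(V)) / gp.duration_h


def viability_from_growth_rate(eta: float, gp: GrowthParams) -> float:
    """Forward map eta(tau) -> V = exp((eta - eta0) T); inverse of
    :func:`growth_rate_from_viability`."""
    return float(np.exp((eta - gp.eta0) * gp.duration_h))


def plan_viability(model: ResponseModel, plan) -> float:
    """Relative cell count after a sequential plan: the product of per-step
    viabilities.  Accepts a SequentialPlan (continuous models) or a sequence
    of treatment names (TableModel).

    Under exponential growth with drug-dependent rates this equals
    N_{n,tau,c} / N_{n,0,c} with both populations starting at equal counts;
    models are memoryless across steps, so all sequential structure is this
    multiplicative bookkeeping.
    """
    if isinstance(plan, SequentialPlan):
        steps = [s.doses for s in plan.steps]
    else:
        steps = list(plan)
    out = 1.0
    for s in steps:
        out *= viability(model, s) if not isinstance(s, str) else model.evaluate(s)
    return out


# ---------------------------------------------------------------------------
# serialization

def panel_to_frame(panel: list[HillBlissProfile]) -> pd.DataFrame:
    """One row per cell line: label, ic50_i / emax_i / hill_i columns, and an
    ``interactions`` column encoding ``i-j:gamma`` pairs separated by ';'."""
    rows = []
    for m in panel:
        row: dict = {"label": m.label}
        for i in range(m.d):
            row[f"ic50_{i}"] = m.ic50[i]
            row[f"emax_{i}"] = m.emax[i]
            row[f"hill_{i}"] = m.hill[i]
        row["interactions"] = ";".join(
            f"{i}-{j}:{g:.10g}" for (i, j), g in sorted(m.interactions.items())
        )
        rows.append(row)
    return pd.DataFrame(rows)


def panel_from_frame(df: pd.DataFrame) -> list[HillBlissProfile]:
    d = sum(1 for c in df.columns if c.startswith("ic50_"))
    panel = []
    for _, row in df.iterrows():
        inter: dict[tuple[int, int], float] = {}
        raw = row.get("interactions", "")
        if isinstance(raw, str) and raw:
            for item in raw.split(";"):
                pair, g = item.split(":")
                i, j = pair.split("-")
                inter[(int(i), int(j))] = float(g)
        panel.append(
            HillBlissProfile(
                ic50=np.array([row[f"ic50_{i}"] for i in range(d)], dtype=float),
                emax=np.array([row[f"emax_{i}"] for i in range(d)], dtype=float),
                hill=np.array([row[f"hill_{i}"] for i in range(d)], dtype=float),
                interactions=inter,
                label=str(row["label"]),
            )
        )
    return panel


def save_panel_csv(panel: list[HillBlissProfile], path) -> None:
    panel_to_frame(panel).to_csv(path, index=False)


def load_panel_csv(path) -> list[HillBlissProfile]:
    return panel_from_frame(pd.read_csv(path, keep_default_na=False))


def save_table_csv(models: list[TableModel], path) -> None:
    """Treatments x cell lines matrix."""
    treatments = sorted({t for m in models for t in m.table})
    df = pd.DataFrame(
        {m.label: [m.table[t] for t in treatments] for m in models},
        index=pd.Index(treatments, name="treatment"),
    )
    df.to_csv(path)


def load_table_csv(path) -> list[TableModel]:
    df = pd.read_csv(path, index_col=0)
    return [
        TableModel(table=dict(zip(df.index, df[col].astype(float))), label=str(col))
        for col in df.columns
    ]
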