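"""Synthetic cell-line panels and worked toy fixtures.

Everything the pipeline consumes can be generated here, seeded and offline:
heterogeneous panels of Hill/Bliss viability profiles standing in for
calibrated pathway-model cell lines, including

* *hard-to-treat* lines (low maximal effect across all drugs) that dominate
  a population's max-proliferation objective,
* *interchangeable* drug pairs sharing a primary target with similar
  affinity (e.g. two RAF inhibitors), which make the optimum non-unique and
  reproduce the solution-variance phenomenon, and
* a two-line / three-treatment discrete toy on which the advantage of
  sequential over time-invariant plans is exactly enumerable.

Panel defaults mirror realistic tissue panel sizes (12 colorectal,
19 melanoma, 10 pancreatic, 20 breast).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as _iterproduct

import numpy as np

from combopt.response import HillBlissProfile, TableModel

TISSUE_PANEL_SIZES = {"colorectal": 12, "melanoma": 19, "pancreatic": 10, "breast": 20}


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a reproducible synthetic cell-line panel.

    ic50s are drawn log-uniformly (nM), maximal effects and Hill slopes
    uniformly, per line and drug.  ``fraction_resistant`` lines get their
    emax capped into ``resistant_emax_range`` across all drugs (hard to
    treat).  ``interchangeable_pairs`` lists drug index pairs whose
    dose-response parameters are shared (up to ``pair_jitter`` relative
    jitter; 0 makes them exactly interchangeable).  Random pairwise
    interactions are added with probability ``interaction_density`` and
    synergy exponents drawn from ``gamma_range``.
    """

    n_lines: int = 12
    d: int = 7
    seed: int = 0
    ic50_log_range: tuple[float, float] = (10.0, 5000.0)
    emax_range: tuple[float, float] = (0.6, 1.0)
    hill_range: tuple[float, float] = (0.8, 2.0)
    fraction_resistant: float = 0.0
    resistant_emax_range: tuple[float, float] = (0.10, 0.35)
    interchangeable_pairs: tuple[tuple[int, int], ...] = ()
    pair_jitter: float = 0.0
    interaction_density: float = 0.0
    gamma_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.n_lines < 1 or self.d < 1:
            raise ValueError("n_lines and d must be >= 1")
        for lo, hi in (
            self.ic50_log_range,
            self.emax_range,
            self.hill_range,
            self.resistant_emax_range,
            self.gamma_range,
        ):
            if lo > hi:
                raise ValueError("ranges must be ordered (lo <= hi)")
        if not (0 <= self.fraction_resistant <= 1):
            raise ValueError("fraction_resistant must lie in [0, 1]")
        if not (0 <= self.interaction_density <= 1):
            raise ValueError("interaction_density must lie in [0, 1]")
        for i, j in self.interchangeable_pairs:
            if not (0 <= i < self.d and 0 <= j < self.d) or i == j:
                raise ValueError(f"bad interchangeable pair {(i, j)}")


def generate_panel(spec: PanelSpec) -> list[HillBlissProfile]:
    """Draw a seeded panel of HillBlissProfile cell lines per the spec.

    Resistant lines are the last ``round(fraction_resistant * n_lines)``
    lines (labelled with an ``-r`` suffix).  For every interchangeable pair
    (i, j), drug j's parameters are copied from drug i (with at most
    ``pair_jitter`` relative perturbation), and any pairwise interaction
    exponents involving i and j are mirrored so swapping the two drugs'
    doses leaves the viability surface unchanged when jitter is zero.
    """
    rng = np.random.default_rng(spec.seed)
    n_resistant = int(round(spec.fraction_resistant * spec.n_lines))
    panel: list[HillBlissProfile] = []
    for c in range(spec.n_lines):
        lo, hi = np.log(spec.ic50_log_range[0]), np.log(spec.ic50_log_range[1])
        ic50 = np.exp(rng.uniform(lo, hi, spec.d))
        emax = rng.uniform(*spec.emax_range, spec.d)
        hill = rng.uniform(*spec.hill_range, spec.d)
        resistant = c >= spec.n_lines - n_resistant
        if resistant:
            emax = rng.uniform(*spec.resistant_emax_range, spec.d)

        interactions: dict[tuple[int, int], float] = {}
        if spec.interaction_density > 0:
            for i in range(spec.d):
                for j in range(i + 1, spec.d):
                    if rng.random() < spec.interaction_density:
                        interactions[(i, j)] = float(rng.uniform(*spec.gamma_range))

        for i, j in spec.interchangeable_pairs:
            jit = 1.0 + spec.pair_jitter * rng.uniform(-1, 1, 3)
            ic50[j] = ic50[i] * jit[0]
            emax[j] = min(emax[i] * jit[1], 1.0)
            hill[j] = hill[i] * jit[2]
            # mirror third-party interactions so i and j are symmetric
            for k in range(spec.d):
                if k in (i, j):
                    continue
                g_ik = interactions.get((min(i, k), max(i, k)))
                g_jk = interactions.get((min(j, k), max(j, k)))
                g = g_ik if g_ik is not None else g_jk
                if g is None:
                    continue
                interactions[(min(i, k), max(i, k))] = g
                interactions[(min(j, k), max(j, k))] = g

        label = f"line{c + 1:02d}" + ("-r" if resistant else "")
        panel.append(
            HillBlissProfile(
                ic50=ic50, emax=emax, hill=hill, interactions=interactions, label=label
            )
        )
    return panel


@dataclass
class Fig1Toy:
    """Two cell lines, three named treatments, two treatment steps.

    A minimal discrete instance on which sequential plans strictly beat
    time-invariant ones: the table is constructed so exhaustive enumeration
    of all ordered two-step plans gives a best time-invariant
    max-proliferation of 0.36 (plan A,A — per-line products 0.36/0.36) while
    the best sequential plan B,C reaches per-line products 0.32/0.27
    (max 0.32).  The table itself is a consistent reconstruction of such an
    instance, not a measured dataset.
    """

    models: list[TableModel]
    best_time_invariant_plan: tuple[str, ...] = ("A", "A")
    best_time_invariant_products: tuple[float, ...] = (0.36, 0.36)
    best_sequential_plan: tuple[str, ...] = ("B", "C")
    best_sequential_products: tuple[float, ...] = (0.32, 0.27)

    @property
    def best_time_invariant_max(self) -> float:
        return max(self.best_time_invariant_products)

    @property
    def best_sequential_max(self) -> float:
        return max(self.best_sequential_products)


def make_fig1_toy() -> Fig1Toy:
    """The canonical sequential-vs-time-invariant toy instance."""
    line1 = TableModel(table={"A": 0.6, "B": 0.8, "C": 0.4}, label="cell line 1")
    line2 = TableModel(table={"A": 0.6, "B": 0.3, "C": 0.9}, label="cell line 2")
    return Fig1Toy(models=[line1, line2])


def enumerate_table_plans(
    models: list[TableModel], n_steps: int, time_invariant: bool = False
) -> dict[tuple[str, ...], np.ndarray]:
    """Brute-force map plan -> per-line viability products over all ordered
    n-step plans (or only repeated-treatment plans if time_invariant)."""
    names = models[0].treatments
    if time_invariant:
        plans = [(t,) * n_steps for t in names]
    else:
        plans = list(_iterproduct(names, repeat=n_steps))
    out = {}
    for plan in plans:
        out[plan] = np.array(
            [np.prod([m.evaluate(t) for t in plan]) for m in models]
        )
    return out


def brute_force_best_plan(
    models: list[TableModel], n_steps: int, time_invariant: bool = False
) -> tuple[tuple[str, ...], np.ndarray, float]:
    """Exhaustively minimize the max per-line product; returns
    (plan, per-line products, max product)."""
    scores = enumerate_table_plans(models, n_steps, time_invariant)
    best = min(scores, key=lambda p: (scores[p].max(), p))
    return best, scores[best], float(scores[best].max())
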