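"""Treat a heterogeneous cell-line population: minimize the worst line.

A 6-line synthetic panel includes two hard-to-treat (resistant) lines.  The
max-aggregated objective min_tau max_c V_c(tau) + lambda*R(tau) forces the
combination to target the resistant lines; the optimized combination is
compared against the exhaustive single-drug and fixed-pair baselines at the
same lambda.
"""

import numpy as np

from combopt import (
    CmaesConfig,
    ObjectiveSpec,
    PanelSpec,
    TreatmentSpace,
    best_single_drug,
    best_two_drug_ratio,
    generate_panel,
    run_restarts,
)
from combopt.cmaes import TreatmentProblem

space = TreatmentSpace(d=7)
panel = generate_panel(PanelSpec(n_lines=6, d=7, seed=5, fraction_resistant=0.34))
spec = ObjectiveSpec(lambda_penalty=1e-5, regularizer="l1", aggregation="max")
problem = TreatmentProblem(panel, spec, space)

res = run_restarts(problem, CmaesConfig(seed=1, iterations=150), n_seeds=2)
single = best_single_drug(panel, spec, space, dose_step_nM=50.0)
pair = best_two_drug_ratio(panel, spec, space, (0, 1), dose_step_nM=50.0)

print("objective = max-line viability + 1e-5 * total dose (nM)\n")
for name, r in [("CMA-ES combination", res), ("best single drug", single),
                ("best PLX-4720/PD0325901 mix", pair)]:
    worst = r.per_line_viability.max()
    print(f"{name:28s} objective {r.best_objective:.4f}  worst-line V {worst:.4f}  "
          f"dose {r.total_dose:7.1f} nM")

print("\noptimized combination (nM per drug):")
for drug, dose in zip(space.drug_names, res.best_treatment):
    if dose > 1:
        print(f"  {drug:12s} {dose:8.1f}")
print("\nresistant lines keep every treatment's worst-line V well above the "
      "sensitive-only level; the combination spreads dose across targets "
      "the baselines cannot reach simultaneously.")
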