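"""Sampling candidates inside the dose-capped domain: why exact HMC.

The feasible region {tau >= 0, sum tau <= cap} occupies a 1/d! fraction of
its bounding box, so rejection sampling collapses as drugs (or treatment
steps) are added.  The exact-HMC sampler reflects harmonic trajectories off
the constraint walls and emits feasible samples at constant cost.  Here both
samplers target the same truncated Gaussian and their moments agree.
"""

import math
import time

import numpy as np

from combopt import (
    SamplerConfig,
    TreatmentSpace,
    TruncatedGaussianSpec,
    build_constraints,
    feasible_volume_fraction,
    sample_truncated,
)

print("feasible fraction of the dose cube (Monte Carlo vs 1/d!):")
for d in (2, 3, 5, 7):
    est = feasible_volume_fraction(d, 200_000, seed=d)
    print(f"  d={d}: {est:.3e}   1/d! = {1 / math.factorial(d):.3e}")

d = 3
cons = build_constraints(TreatmentSpace(d=d, alpha=1.0), normalized=False)
spec = TruncatedGaussianSpec(np.full(d, 0.3), 0.25 * np.eye(d), cons)

t0 = time.perf_counter()
h = sample_truncated(spec, 2000, SamplerConfig(seed=1))
t_hmc = time.perf_counter() - t0
t0 = time.perf_counter()
r = sample_truncated(spec, 2000, SamplerConfig(method="rejection", seed=2))
t_rej = time.perf_counter() - t0

print(f"\ntruncated Gaussian on the d={d} capped box, 2000 samples each:")
print(f"  hmc       mean {h.mean(axis=0).round(4)}  ({t_hmc:.2f} s)")
print(f"  rejection mean {r.mean(axis=0).round(4)}  ({t_rej:.2f} s)")
print("  (the two distributions agree; for a two-step 7-drug plan the "
      "rejection sampler would need ~(7!)^2 = 2.5e7 trials per accepted "
      "candidate, while the hmc cost per sample does not change)")
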