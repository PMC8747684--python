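# combopt

In-silico **combination-treatment optimization** over dose-capped multi-drug
spaces: find drug cocktails — and sequences of cocktails — that minimize
predicted cancer-cell proliferation while keeping total drug burden low.

The package is aimed at computational biologists who have (or can simulate)
a per-cell-line dose-response predictor and want to search the combination
space it spans: single cell lines, heterogeneous populations of lines, and
multi-step sequential treatment plans.

## The optimization problems

A treatment is a vector τ ∈ ℝ₊^d of per-drug concentrations (nM) restricted
to the domain **T = {τ ≥ 0 : ‖τ‖₁ ≤ α}** with α = 8000 nM by default. For
each cell line *c* a response model predicts the relative proliferation
V_c(τ) ∈ (0, 1], the treated-to-untreated cell-count ratio after a 72 h
step, with V_c(0) = 1. Three regularizers stand in for adverse effects:

    R_L1(τ) = Σᵢ τᵢ      R_L2(τ) = Σᵢ τᵢ²      R_ln(τ) = Σᵢ ln(1 + τᵢ)

and three problem classes are minimized over T (or its n-step power Tⁿ):

| problem | objective |
|---|---|
| single cell line | V_c(τ) + λ·R(τ) |
| population, worst line | max_c V_c(τ) + λ·R(τ) |
| sequential plan | max_c Πᵢ V_c(τᵢ) + λ·Σᵢ R(τᵢ) |

(a weighted-average aggregation replaces the max when the clonal
composition is known). The product form of plan viability follows from
exponential growth with drug-dependent rates: V_c(τᵢ) = e^{η(τᵢ)T}/e^{η(0)T}
per step, so relative cell counts multiply across steps.

The solver is **CMA-ES** with one structural change: solution candidates are
drawn from the search Gaussian *truncated to the feasible polytope* using an
exact Hamiltonian Monte Carlo sampler (harmonic trajectories reflecting off
the constraint walls, hit times solved analytically). Naive
sample-and-reject collapses here because T occupies only a 1/d! fraction of
its bounding box — about 2×10⁻⁴ at d = 7, and (1/7!)² ≈ 4×10⁻⁸ for two-step
plans; the exact sampler's cost per candidate is independent of that
fraction.

Because the defensible penalty weight λ is unknown a priori, treatments are
optimized along a log-spaced λ grid (10⁻⁷…10⁻¹) and reported as a **Pareto
front** in (total dose, proliferation). Exhaustive single-drug and
fixed-pair (RAF+MEK inhibitor mixture) searches provide reference
baselines, and per-λ PCA over repeated warm-start runs quantifies solution
variance — drugs with interchangeable targets make the optimum a continuum.

Response models are pluggable. Shipped surrogates: a per-drug Hill /
Bliss-independence profile with optional pairwise interaction modifiers
(`HillBlissProfile`), and a discrete viability table (`TableModel`); the
`synthetic` module generates seeded heterogeneous panels with resistant
lines and interchangeable drug pairs.

## Worked example

`python examples/02_sequential_plan_toy.py` — why sequences of different
cocktails can beat repeating the best single cocktail:

```
all ordered 2-step plans (per-line viability products, worst line):
  B->C: (0.32, 0.27)  max 0.32
  C->B: (0.32, 0.27)  max 0.32
  A->A: (0.36, 0.36)  max 0.36
  ...
best time-invariant plan: max proliferation 0.36
best sequential plan ('B', 'C'): per-line products (0.32, 0.27)
sequential advantage: 0.36 -> 0.32 for the worst line
```

Treatment A is a compromise that suppresses both lines to 0.6 per step
(0.36 after two steps). Alternating the specialized treatments B and C —
each strong against one line — leaves *both* lines lower (0.32 and 0.27)
than the best time-invariant plan leaves either.

`python examples/01_single_line_pareto.py` sweeps λ for one synthetic line:

```
    lambda  total dose (nM)  proliferation V
   1.0e-07           3944.2           0.0003
   1.0e-05            718.7           0.0047
   1.0e-03            138.9           0.0695
   1.0e-01              0.5           0.9983
```

At λ = 10⁻⁷ the penalty is negligible and the optimizer doses aggressively;
at λ = 10⁻¹ any dose costs more than the proliferation it buys and the
optimizer administers essentially nothing. The intermediate rows are the
Pareto-efficient menu.

The other examples demonstrate the truncated sampler vs its rejection
oracle (`03`), population treatment with hard-to-treat lines against the
exhaustive baselines (`04`), and the interchangeable-drug variance analysis
(`05`).

A thin CLI wraps the same functions for scripted runs:
`combopt optimize|sweep|baseline-single|baseline-pair|pca|simulate-panel
-c config.yaml` (see `combopt --help`; `--fast` gives a coarse smoke
profile).

## Layout

- `src/combopt/domain.py` — treatment vectors, the capped domain T and Tⁿ,
  linear-inequality representation, simplex-volume estimate
- `src/combopt/response.py` — response-model contract, Hill/Bliss surrogate,
  viability tables, growth-rate algebra, plan composition
- `src/combopt/objectives.py` — regularizers and the three objectives
- `src/combopt/sampling.py` — exact-HMC truncated-Gaussian sampler +
  rejection oracle
- `src/combopt/cmaes.py` — constrained CMA-ES, restarts
- `src/combopt/sweep.py` — λ sweeps, Pareto fronts, exhaustive baselines,
  per-λ PCA
- `src/combopt/synthetic.py` — seeded panels, resistant lines,
  interchangeable pairs, the sequential toy
- `src/combopt/config.py`, `io.py`, `cli.py` — run configs, serialization,
  CLI
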