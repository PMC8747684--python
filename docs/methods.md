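# Methods

This note records the models, algorithms, numerical choices and limitations
behind `combopt`, in the order a user meets them.

## Treatment domain and coordinates

A single-step treatment is τ ∈ ℝ₊^d (nM per drug, d = 7 by default). The
feasible set is T = {τ ≥ 0 : ‖τ‖₁ ≤ α} with α = 8000 nM, a cap chosen to
match the concentration range over which typical dose-response predictors
are calibrated; sequential plans live in Tⁿ with the cap applied per step.
Feasibility is encoded as D + n inequalities A·x ≤ b (D = d·n nonnegativity
rows plus one sum row per step). The sum constraint is non-strict, so the
even-split point (α/d per drug), which lies exactly on the cap, is
admissible and serves as the optimizer's initial mean.

All search happens in normalized coordinates x = τ/α. This makes each step
an O(1)-sized region so that a single dimensionless step size (σ₀ = 0.25)
is meaningful; an 8000 nM-scale parameterization would demand per-problem
step-size tuning. Results are always reported in nM. Feasibility tolerance
is 10⁻⁹ in normalized units.

Regularizers, by contrast, are evaluated in **nM** by default. This is what
gives the λ grid its intended semantics: with R_L1 in nM, λ = 10⁻⁷ makes
the penalty of a full-cap dose ≈ 8·10⁻⁴ (negligible next to a viability
gain of order 1, so the optimizer doses aggressively), while λ = 10⁻¹ makes
it ≈ 800 (no treatment is ever worth administering). Evaluated in
normalized units the penalty could never exceed ≈ 0.1·n and the
"administer nothing" regime would not exist on the grid; that convention
remains available as `reg_coords="normalized"` for problems posed on other
scales.

## Response models

The optimizer only needs a map τ → V_c(τ) ∈ (0, 1] per cell line c with
V_c(0) = 1 (relative proliferation: treated/untreated cell count after one
72 h step). Any predictor honoring this contract plugs in — including an
external mechanistic simulator. Two concrete families ship with the
package:

**HillBlissProfile** — a parametric surrogate:
V(τ) = Πᵢ (1 − Eᵢ uᵢ) · Π₍ᵢⱼ₎ exp(−γᵢⱼ uᵢ uⱼ), with Hill occupancy
uᵢ = τᵢ^hᵢ/(IC50ᵢ^hᵢ + τᵢ^hᵢ). The product over drugs is Bliss
independence — the standard null model for combining independent
single-drug effects — and the exponential pairwise modifier adds bounded
synergy (γ > 0) without affecting single-drug behavior (it is 1 whenever
either dose is zero). With all γ ≥ 0, V is non-increasing in every dose and
strictly positive. Parameters per drug: IC50 (nM, > 0), maximal fractional
effect E ∈ [0, 1], Hill slope h > 0. This surrogate is a first-class model
in its own right (it is how the test panels are built); it makes no claim
to reproduce any particular mechanistic simulator's surface.

**TableModel** — a finite map from named discrete treatments to per-line
viabilities in (0, 1], used for exactly enumerable toy instances.

**Sequential composition.** Under exponential growth with drug-dependent
rates, V_c(τ) = e^{η_c(τ)T}/e^{η_c(0)T} per step (T = 72 h), so the
relative cell count after a plan is the product of per-step viabilities,
assuming treated and untreated populations start equal. The growth-rate
algebra (η(τ) = η₀ + ln V/T and its inverse) is exposed for bookkeeping and
tested as an exact round trip. Models are memoryless across steps — there
is no cellular-level carry-over — so all sequential structure is this
multiplicative population bookkeeping; the per-step viabilities of earlier
steps effectively re-weight the lines for later steps, which is exactly why
specialized step-varying plans can beat time-invariant ones.

## Truncated-Gaussian sampling (exact HMC)

Candidates must come from N(μ, σ²C) restricted to the polytope. Rejection
sampling degrades with the feasible fraction, which for T is 1/d! of the
bounding box (≈ 2·10⁻⁴ at d = 7, squared for two-step plans). The workhorse
is the exact Hamiltonian Monte Carlo method for Gaussians under linear
constraints: after whitening by the Cholesky factor the target is standard
normal, Hamiltonian trajectories are exact harmonic oscillations
x(t) = x₀cos t + v₀sin t, and the first wall hit solves
u·cos(t − φ) = c per constraint in closed form. The velocity reflects about
the wall normal and the trajectory continues until a fixed travel time
elapses; the end position is an exact sample. Cost per sample is
independent of the feasible volume.

Tuning (the method's literature gives the travel-time heuristic; the rest
is ours, validated by oracle equivalence): travel time π/2 per move — a
quarter period, the standard decorrelating choice; 50 burn-in moves per
call, thinning 1. A 10⁻¹² guard excludes immediate re-hits of the wall just
reflected from; reflections are capped defensively at 10⁵ per trajectory
(typical counts are below ten). Chain starts must be strictly feasible:
the default start is the polytope's Chebyshev center (computed by linear
programming), and a boundary start is pulled toward it until strictly
inside. When the Gaussian mean is infeasible — common late in constrained
CMA-ES runs, where the mean presses against the cap — the chain simply
starts at the last feasible sample; the dynamics remain exact.

The plain rejection sampler is retained as the independent distributional
oracle: marginal Kolmogorov–Smirnov comparisons and moment checks against
it at D ≤ 3 (n = 2000, α = 0.01), including infeasible-mean settings, are
part of the test suite, as is per-bounce energy conservation to 10⁻⁸.

## Constrained CMA-ES

The implementation follows the standard textbook formulation exactly:
population m = 4 + ⌊3 ln D⌋ (9 at D = 7, 11 at D = 14), μ = ⌊m/2⌋ elites
(4 and 5), log-rank elite weights normalized to sum 1, cumulative step-size
control against the expected χ-norm, rank-one plus rank-μ covariance
adaptation with the usual learning rates (c_σ, d_σ, c_c, c₁, c_μ derived
from μ_eff and D). No re-derivation or variant tuning was attempted.

The single modification is candidate generation: draws come from the
truncated Gaussian above, and the truncated samples feed the updates
unmodified. No importance reweighting is applied — truncation is the exact
drop-in replacement for resample-until-feasible, which induces the same
candidate distribution, and every evaluated candidate is feasible by
construction.

Defaults: σ₀ = 0.25 (normalized coordinates), 400 iterations, even-split
initial mean, 3 restart seeds (seed+0, +1, +2, sharing the initial mean)
with the best-objective result reported. 400 iterations is deliberate
overkill for most problems — convergence typically occurs well before
100 — but logarithmic regularization at large λ produces a difficult,
high-variance surface where the full budget matters; no early stopping is
used. Numerical hygiene: the covariance is re-symmetrized and its
eigenvalues floored at 10⁻¹² of the largest before each Cholesky; a
non-finite objective value aborts with a state dump. With a fixed seed the
entire run is bitwise reproducible.

## Sweeps, baselines, variance analysis

**λ grid**: exponents −7…−1, step 0.25 (0.05 for sequential runs; the
warm-start variance study uses 0.25). Cold sweeps run independent restarts
per λ from the even-split mean; warm sweeps ascend λ initializing each
search at the previous optimum. Each sweep point records total dose and
the *unpenalized* proliferation metric matching the aggregation (V_c,
max_c V_c, or Σ w_c V_c); the Pareto front is the non-dominated subset in
(dose, proliferation), verified in tests against an all-pairs oracle.

**Baselines** are exact exhaustive searches: every drug at 0…α nM in 1 nM
steps (56,007 evaluations at defaults), and the fixed two-drug mixture at
21 ratio steps × the same dose axis. Ties break toward lower dose, then
lower drug index / ratio; there is no canonical tie order for such grids,
so determinism was the criterion. Tests run these at 50 nM steps;
exactness properties are resolution-independent.

**PCA**: discovered treatments (nM) from repeated warm-start sweeps are
grouped by λ; each group with ≥ 2 members gets its own PCA (sample
covariance, 1/(n−1)); groups with zero variance are flagged degenerate
rather than producing 0/0 ratios. Only single-step treatments are grouped.

## Synthetic panels

`generate_panel` draws seeded heterogeneous panels: log-uniform IC50s in
10–5000 nM (spanning "well below" to "near the cap" of the 8000 nM dosing
range), uniform Emax in 0.6–1.0 and Hill slopes in 0.8–2.0 (typical ranges
for targeted agents on sensitive lines). *Resistant* lines get Emax capped
to 0.10–0.35 across all drugs, making them bind a population's
max-proliferation objective the way hard-to-treat lines do in real panels.
*Interchangeable pairs* share dose-response parameters (default exactly;
a relative jitter of up to 1% is available) with interaction exponents
mirrored so swapping the pair's doses leaves the surface invariant — the
mechanism by which two inhibitors of the same target make the optimum a
continuum. Default panel sizes mirror realistic tissue panels (12
colorectal, 19 melanoma, 10 pancreatic, 20 breast).

The two-line/three-treatment sequential toy is constructed so exhaustive
enumeration gives a best time-invariant two-step max-proliferation of 0.36
and a best sequential plan with per-line products (0.32, 0.27). It is a
consistent reconstruction of such an instance — other tables produce the
same optima — not a measured dataset.

What the synthetic panels do **not** emulate: expression-individualized
mechanistic response surfaces, transcriptional-feedback adaptive
resistance, non-steady-state transients between treatment steps, or
pharmacokinetics. Passing tests therefore demonstrate the correctness of
the optimization machinery on viability surfaces with realistic shape and
heterogeneity, not predictions for any real cell line.

## Problem sizes in tests and the acceptance script

Brute-force oracles bound what can be enumerated: grid comparisons use
2–3 drugs at 50 nM steps, sampler oracles use D ≤ 3 at n = 2000, the
convergence study uses 20 random positive-definite quadratics at D = 7 with
the full 400 iterations, and the sweep check covers the full 25-value λ
grid on a 2-drug panel. These sizes make every check exact or
statistically calibrated while keeping a full run in minutes on one CPU.

## Known limitations

- No importance correction for truncation in the CMA-ES updates; near a
  tight cap the adapted covariance is that of the truncated, not the free,
  Gaussian. This matches the resampling semantics it replaces.
- The per-candidate HMC chain is re-burned every iteration (50 moves);
  persistent chains would be cheaper but couple iterations.
- Quadratic constraints (supported by the exact-HMC method in general) are
  not implemented; the domain here is polyhedral.
- `best_single_drug` at 1 nM resolution is exact but slow in Python for
  many lines; the vectorized evaluation makes the default 7 × 8001 grid
  cheap, but dense d-drug enumeration is exponential and restricted to
  oracles.
- Drug-specific penalty weights and synergy-aware penalties are out of
  scope; the regularizers penalize total burden only.
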