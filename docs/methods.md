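# Methods

This note documents the statistical model behind `tfnbs`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that were genuinely open.

## Data model and preprocessing

A cohort is a set of per-subject symmetric nonnegative connectivity matrices
over a common parcellation, plus covariates (group, age, sex, batch,
optional subgroup labels). Edges are the upper-triangle entries; an edge
enters the analysis only if it is nonzero in at least `min_prevalence` of
subjects (default 1.0, i.e. present in everyone). Zero weights are treated
as structurally absent connections, not censored measurements — this keeps
the per-edge GLM well-posed without imputation. With the default filter no
zeros survive, so the natural-log transform needs no offset; an explicit
offset for exact zeros is available for lower prevalence thresholds.

All modeling happens on the log scale. Tractography-derived edge weights are
positive, right-skewed, and roughly log-normal; harmonization and the GLM
both assume additive structure, which holds far better for log weights.
Back-transformation (`exp`) is for display only.

## Batch harmonization

Scanner software epochs (or any protocol change) act on edge values with a
per-edge additive (location) and multiplicative (noise scale) effect. The
model, for subject *g* in batch *b*:

    y_ge = α_e + x_g'β_e + γ_be + δ_be ε_ge,   ε_ge ~ N(0, σ_e²)

Fitting (the parametric empirical-Bayes / ComBat scheme):

1. Per-edge least squares of `y` on the preserved design (group, age, sex)
   plus batch indicators, with batch effects constrained to a size-weighted
   zero sum; the weighted batch intercept is the grand intercept α̂.
2. Standardize: `z = (y − α̂ − x'β̂)/σ̂` with σ̂² the pooled (MLE) residual
   variance.
3. Naive per-batch estimates: γ̂ (mean of z in the batch) and δ̂² (MLE
   variance of z in the batch).
4. Hyperpriors across edges by moment matching: γ ~ N(γ̄, τ²); δ² ~
   inverse-gamma(λ, θ) with λ, θ from the mean and variance of the δ̂².
5. Iterate the conditional posterior means γ\*, δ\*² to convergence
   (absolute change < `tol`, default 1e−4, `max_iter` 100 — conventional
   for EB fixed-point iterations, which here converge in a handful of
   steps). `max_iter=0` returns the naive estimates.

Harmonized values re-add the preserved effects:
`ŷ = σ̂·(z − γ\*)/δ\* + α̂ + x'β̂`.

Numerical decisions:

- **MLE (1/n) batch variances.** With the MLE denominator a single-batch fit
  is an exact no-op (γ\* = 0, δ\*² = 1, output ≡ input to machine
  precision), which is the behavior a user toggling harmonization on
  single-site data should see. The n−1 convention used by some reference
  implementations breaks this identity by O(1/n); the test suite's
  cross-check against Bioconductor `sva::ComBat` therefore asserts
  agreement at ~O(1/n_batch) tolerance rather than machine precision.
- **Degenerate priors.** When the across-edge spread of δ̂² (or γ̂) is ~0 —
  e.g. the single-batch case, where δ̂² = 1 exactly for every edge — the
  inverse-gamma moment match is undefined; the posterior then keeps the
  naive estimate (point-mass prior). Without this guard the fit would
  divide by zero on its own identity case.
- Only the parametric EB path is implemented; arbitrary batch counts are
  supported, but there is no hierarchical multi-site model.

## Edge-wise GLM

Each edge gets an OLS fit on intercept + treatment-coded group indicator +
nuisance covariates (age centered at the retained-sample mean — stabilizes
the intercept, irrelevant to the contrast — and sex 0/1). The contrast
*t*-statistic uses the residual dof `n − rank(X)`. The implementation is
direct linear algebra vectorized across edges (a 162-node connectome has
~10⁴ edges × thousands of permutations; per-edge model objects would not
fit the budget); it is validated against a per-edge regression oracle
(statsmodels) to 1e−8 and against the closed-form two-sample *t* when there
are no covariates.

Degenerate edges with zero residual variance get `t = ±1e6` (configurable
cap) with a warning, keeping enhancement finite on pathological inputs.

Both directions are analyzed separately (decrease: tested group below
reference; increase: above), each at the full α — reporting mirrors the
practice of presenting "both directionalities" side by side rather than a
two-sided test. This is a reporting convention, configurable via
`RunConfig.directions`.

"Adjusted" edge values for reporting remove only the nuisance fit (estimated
with group in the model) and re-add the grand nuisance mean; group mean
differences of adjusted values equal the GLM contrast exactly (an algebraic
identity the suite checks numerically).

## Threshold-free enhancement

At threshold *h*, edges with `t > h` decompose into components connected
through shared nodes; the extent of a component is its edge count. The
enhanced score integrates `extent^E · h^H` over a ladder of K evenly spaced
thresholds up to the graph's maximum positive statistic. Defaults
E = 0.5, H = 2.25, K = 100 — the exponents carried over from voxel-wise
threshold-free enhancement practice, where the height exponent ≈2 and a
sub-linear extent exponent balance focal strong effects against distributed
weak ones; they are exposed as parameters, and score convergence in K is
part of the test suite. The implementation adds edges to an incremental
union-find in descending threshold order and shares one extent evaluation
across ladder runs with an unchanged edge set (O(m²) finds instead of
O(m·K) component recomputations); it is tested for exact (1e−10) equality
against a naive threshold-loop oracle and against the analytic integral for
an isolated edge.

## Permutation inference

For each permutation the group assignment is re-randomized and *t* and
enhancement recomputed. Default scheme is Freedman–Lane (permute residuals
of the nuisance-only model, re-add the nuisance fit) because nuisance
covariates are in the model; `simple_label` permutation is available and is
what the exhaustive-enumeration tests use. When the requested permutation
count reaches the number of distinct reassignments (tiny n), the engine
warns and enumerates all of them, making p-values exact.

Two deliberate statistical choices:

- **Signed enhanced statistic.** The per-edge statistic compared against
  the nulls is `s_e = TFCE(+t)_e − TFCE(−t)_e` (at most one term is
  nonzero). The one-sided score alone has a point mass at zero — every edge
  leaning the wrong way scores exactly 0, and its p-value against a
  nonnegative null is 1 — so roughly half of all null p-values would pile
  up at 1. The signed statistic is continuous under the null, giving
  uniform uncorrected p-values (verified by per-edge KS tests across 200
  null cohorts), while `max(s, 0)` recovers the per-direction score. Since
  the max-null dominates every per-edge null realization-wise and ties
  count as ≥, `p_corrected ≥ p_uncorrected` holds everywhere by
  construction.
- **Per-permutation ladder top.** Every enhancement — observed and permuted
  — runs its threshold ladder up to that graph's own maximum, so each score
  approximates the same ladder-free integral `∫₀^{t_e} extent(h)^E h^H dh`.
  Fixing the ladder at the observed maximum instead truncates permuted
  graphs that exceed it, deflates the max-null, and measurably inflates the
  family-wise error rate (0.155 instead of ~0.05 in a 200-cohort null
  study); with the per-permutation ladder the measured rate is 0.045 over
  400 null cohorts.

The add-one estimator `(1 + #{null ≥ obs})/(P + 1)` bounds p-values below by
`1/(P+1)` and counts ties conservatively.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes: a shared
random support mask at a given edge density; per-edge log-normal weights
(baseline log-mean ~N(4, 0.75²), within-edge SD uniform on [0.3, 0.6] —
arbitrary units chosen to give realistic-looking weight magnitudes and
coefficient-of-variation); linear age (default −0.01/year, a mild decline)
and sex (+0.1) effects on the log scale; per-batch additive shifts and
multiplicative noise scales; and a planted effect, by default a *decrease*
for group B of `effect_size` within-edge SDs on a connected subnetwork
covering `planted_edge_fraction` of present edges (connected planting grows
a snowball over the support graph). Cohort defaults mirror a two-epoch
patient/control design (50 + 92 subjects, 162 nodes, ages 18–60); the
calibration studies in the tests use smaller sizes (20 nodes, 30 + 30) so
the suite runs in minutes on one CPU. The 162-node "destrieux162"
parcellation is a synthetic stand-in whose lobe and hemisphere counts echo
the Destrieux atlas (74 cortical + 7 subcortical per hemisphere); region
names are generated strings, not atlas labels.

What the generator does **not** emulate — hence what passing tests do not
show about real data: spatial autocorrelation of edge weights, hub/module
topology of real connectomes, heavy-tailed or zero-inflated weight
distributions, subject-level global scaling (e.g. head size), batch effects
correlated with group composition, or measurement error correlated across
edges. Calibration results (FWE control, p-value uniformity) are therefore
statements about the inference machinery under the stated model, not about
any specific imaging cohort. The null-calibration studies use
`edge_density=1.0` (complete 20-node support) so that every simulated
dataset tests the identical edge set, which per-edge uniformity testing
across datasets requires.

## Known limitations

- Exchangeability blocks are carried on the design but whole-cohort
  permutation is the only implemented scheme; no within-block restriction.
- No fixed-threshold (component-level NBS) inference; no non-parametric
  harmonization; no covariate-adjusted (GAM) or longitudinal ComBat.
- Permutation runtime scales linearly in P × (GLM + 2 enhancements); at the
  default P = 5000 on a 162-node, ~4500-edge dataset a full two-direction
  run takes tens of minutes on one CPU.
- The enhancement exponents E, H are conventions, not estimates; conclusions
  at non-default exponents require rerunning the permutation analysis.
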