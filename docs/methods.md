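# Methods

## Gene-wise linear models and variance moderation

Each gene is modelled as y_g = Xβ_g + e_g with Var(e_g) = σ²_g W_g⁻¹,
where X is a shared full-column-rank design matrix and W_g an optional
non-negative diagonal weight matrix (zero weights encode missing
cells). With no weights the fit is one vectorised QR solve for all
genes; weighted genes are fit individually, and a gene whose weighted
design loses rank is flagged rather than failing the run. Saturated
genes (d_g = 0) carry an undefined sample variance and are excluded
from hyperparameter estimation, but remain testable through the
posterior (s̃²_g = s₀², total df = d₀).

The prior (d₀, s₀²) is estimated by equating empirical to expected
first and second moments of z_g = log s²_g. Under the hierarchical
model, e_g = z_g − ψ(d_g/2) + log(d_g/2) has mean log s₀² − ψ(d₀/2) +
log(d₀/2) and variance ψ′(d_g/2) + ψ′(d₀/2) (ψ, ψ′ digamma and
trigamma). The excess of the empirical variance of e_g over the mean
sampling term ψ′(d_g/2) is inverted through the trigamma function
(monotone Newton iteration, relative tolerance 1e-8). When the excess
is non-positive the moment equation has no positive solution: d₀ is
reported as +∞ (every gene shares s₀² = exp(ē)) — likewise when the
solution exceeds 1e6, a cap that keeps the total degrees of freedom
finite in double precision. The log-variance scale is used because its
moments are finite for any degrees of freedom, making the moment
estimator stable at very small d_g.

Tests are two-sided throughout: the simulation shifts are
one-directional, but the hypotheses tested are β_gj = 0.

## Resampling-based empirical Bayes tests

The reference distribution is built under the complete null (no gene
differentially expressed) by resampling whole arrays, which preserves
the inter-gene correlation structure:

* **permutation** — group labels are permuted over arrays; an
  exhaustive mode enumerates all C(n₁+n₂, n₁) assignments (≤ 12
  arrays) exactly once, identity included;
* **bootstrap** — arrays are first mean-centred within each group per
  gene (removing any group effect, which is what "matching the null
  hypothesis" requires), then drawn with replacement within group.

For every resample the *full* pipeline is rerun — fit, prior
re-estimation, moderation — because the resampled statistic should be
the statistic the observed data received; a `refit_prior=False` flag
freezes the observed prior for sensitivity analysis. The four variants
cross the resampling scheme with the extremeness measure (|t̃| vs the
parametric p-value). P-values pool all m·B null values with an add-one
correction, giving resolution 1/(mB+1) and strictly positive values;
a per-gene (non-pooled) option restricts each gene to its own B null
values. Degenerate resamples (e.g. a bootstrap draw that repeats one
array until a gene's residuals vanish) are snapped to exact-zero
variances; a fully degenerate resample falls back to an infinite-d₀
prior so its null statistics are (numerically) zero rather than
rounding noise.

The benchmarking rejection rule for PM and the resampling variants is
an unadjusted p ≤ 0.05.

## SAM

The penalised statistic is d_i = (mean₂ − mean₁) / (s_i + s₀), s_i the
pooled standard error of the difference. The fudge factor s₀ is chosen
from the {0, 5, …, 100} percentiles of s: genes are partitioned into
s-quantile windows (100 windows, fewer for small gene sets so each
carries a stable estimate), the spread of d within each window is
measured by the median absolute deviation, and the candidate
minimising the coefficient of variation of those spreads is kept —
the classic construction that makes the spread of d independent of s.

B label permutations (s₀ held fixed at its observed value) give sorted
statistics d^b_(i), whose column means d̄_(i) are the expected order
statistics. For a threshold Δ, walking up from the origin of the
d_(i)-vs-d̄_(i) plot, the first gene with d_(i) − d̄_(i) ≥ Δ opens the
positive calls (all genes with larger rank), and symmetrically
downwards; cut points are inclusive. E(V) is the mean number of
permuted statistics at or beyond the cut points (mean, not median; no
π₀ correction — both exposed as options), and the FDR estimate is
E(V)/R, defined 0 when R = 0. Δ is selected by scanning the observed
departures in ascending order and keeping the first (largest-R) call
whose estimated FDR meets the target; the benchmark uses target 0.05.

## The synthetic-data generator

One scenario cell generates Y (m genes × 2n arrays) on the log2 scale
as Y_g = σ_g · ε_g, plus an `effect` shift (default 1.0) added to the
group-2 arrays of the first round(m·π₁) genes — those genes are the
ground-truth positives. Components:

* **per-gene SDs** σ_g = `sd_scale` · χ²₄/4 (a scaled chi-square with
  4 df applied to the standard deviations, unit mean at scale 1);
* **correlation** from a rank-3 random factor model: each gene loads
  on 3 shared array-level factors with loading norm √0.4 in a random
  direction, giving pairwise correlations 0.4·cosθ and mean |ρ| ≈ 0.2;
  loadings and factors are redrawn per dataset;
* **noise families**: correlated standard normal; a standardised
  lognormal exp(c·Z) with shape c = 1.0 (per-gene skewness ≈ 6.2,
  strongly right-skewed); and an 80/20 per-observation mixture of
  N(0, σ²_g) and N(−2.5σ_g, (0.5σ_g)²), which is left-skewed with thin
  tails (standardised skewness ≈ −0.24). The minority-component mean
  sits at −2.5σ because a nearer component (e.g. −1.5σ) actually
  produces *right* skew — the majority component's variance term
  dominates the third moment.

All constants are `ScenarioConfig` fields. Randomness flows from a
single `(seed, replicate)` pair through `numpy.random.SeedSequence`,
so any cell of any grid is independently reproducible and datasets are
shared across methods within a replicate (paired comparisons).

### Calibration of `sd_scale`

The benchmark tables this harness reproduces report a strong-signal
regime: at n = 4 per group and a unit log2 shift, the parametric
moderated-t attains mean sensitivity ≈ 0.98. With unit-mean SDs the
attainable power at n = 4 is ≈ 0.48, so the SD scale was calibrated
once, at design time, to the reported operating point: `sd_scale` =
0.18 yields PM sensitivity 0.982 and realised FDR 0.300 at
(n=4, π₁=0.10, normal), matching the reported 0.980/0.310. The scale
was frozen before the acceptance suite was written and is not adjusted
per scenario.

### What the generator does and does not emulate

It emulates correlated, heteroscedastic, possibly skewed log-scale
expression with a clean two-group design and a fixed additive effect.
It does not emulate probe-level artefacts, normalisation residue,
batch effects, missing values, variance–mean trends, or effect-size
heterogeneity. Passing benchmarks therefore demonstrates the operating
characteristics of the six procedures under controlled distributional
violations — not performance on any particular real platform.

### Known limitation of the reproduction

In the published tables, the parametric method's realised FDR under
lognormal and mixed-normal noise equals π₀ at *every* sample size
(≈ 0.90 at π₁ = 0.10 even at n = 48) — i.e. ~98% of true nulls
rejected. No generator in which null genes are identically distributed
in both groups can produce that: at n = 48 the two-sample t-statistic
is CLT-normal regardless of skew. Under this package's generator
(shift applied to DE genes only, as the ground-truth contract
requires) the maximum attainable PM lognormal FDR at π₁ = 0.10 is
≈ 0.2–0.3 across all shape choices scanned. The corresponding
benchmark cells are reported as computed; the qualitative ordering
(PM worst, PBB/SAM best at FDR control under skew) reproduces, the
extreme magnitude does not.

## Evaluation metrics

For each replicate the rejection mask is tabulated against the truth:
U, V, T, S with m₀ true nulls, R = V + S rejections; sensitivity
S/(m−m₀), specificity U/m₀, realised false discovery proportion V/R
(0 when R = 0). Identities U+V = m₀, T+S = m−m₀ are asserted on every
tabulation. Grid summaries average the per-replicate rates.

## Problem sizes

The shipped benchmark protocol uses m = 500 genes, B = 500 resamples
and 50 replicates per cell (30 for the n = 48 lognormal cell), the
package's desk-scale defaults; the harness accepts B = 1000 and any
replicate count. Null-calibration checks use B = 200 at n = 12 over
50 complete-null replicates; directional method-ordering checks use
B = 150–200 with 4–5 replicates per cell.
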