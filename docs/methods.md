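# Methods

`bmtime` analyses targeted-panel (TempO-Seq-style) time-course transcriptomics
for time-dependent activation of cellular stress-response pathways.  The
pipeline has four stages — sample selection and probe filtering, per-time-point
differential expression, pathway over-representation, and benchmark-time
modelling — plus a synthetic-data generator whose planted responses carry
analytic ground truth, so every stage can be validated end to end without any
external dataset.

## Study design emulated

A compound is profiled at nine time points (1, 2, 4, 6, 8, 12, 16, 20, 24 h)
with three biological replicates per time point, alongside vehicle controls
with the same design: 27 treated and 27 control samples per compound.  Counts
arrive pre-quantified on a fixed probe panel (~3,565 probes) with probe IDs of
the form `GENE_probeid`; the gene symbol is everything before the last
underscore.  Several genes carry more than one probe.

## Probe filtering and normalisation

Per compound, probes with a row sum below 100 across that compound's treated
plus control samples are removed.  The comparison is inclusive (>= 100
retains); the threshold is configurable.  Size factors are classical
median-of-ratios: s_j = median over reference probes g of y_gj / gm_g, where
gm_g is the geometric mean across samples and the reference set is the probes
positive in every sample.  Factors are not rescaled further.  Note the exact
algebra of this estimator: scaling one sample's counts by c moves *every*
factor through the geometric means (by c^(1/n)); only factor ratios s_j/s_k
obey the clean scaling identity, and that is the form our invariant tests
assert.

## Differential expression

Per time point, treated vs time-matched control is tested with a
negative-binomial Wald test at fixed per-probe dispersion.  Group means are
fitted by a vectorised Newton solve of the NB score equation on the log scale
with size-factor offsets; the log2 fold change is the difference of fitted log
means, its standard error comes from the Fisher information, and the two-sided
normal Wald p values are Benjamini–Hochberg adjusted per table.  Significance
uses p-adj < 0.01 and |log2FC| > 1.

Dispersions are a deliberate simplification of the empirical-Bayes machinery
of dedicated DEG packages: a method-of-moments estimate pooled over all
replicate groups of a compound (all time points, both arms), floored at zero,
then shrunk (weight 0.3 by default, configurable) toward a fitted trend
alpha(mu) = a1 + a0/mu.  Estimating once per compound and reusing the value in
each 3-vs-3 test stabilises the small-sample tests.  With the true dispersion
supplied, the test is well calibrated at n = 3 per group (type-I error ~0.05
at the 0.05 level for baseline counts ~200); the acceptance harness verifies
exactly this setting.

Per-gene time-point statistics for reporter-style replicate measurements use
one-way ANOVA with Dunnett's many-to-one post-hoc adjustment (equicorrelated
multivariate t, numerically evaluated via scipy), and reporter fluorescence
traces are baseline-subtracted against their first time point.

## Over-representation analysis

ORA runs at the time point with the most significant DEGs (earliest time on
ties), an option enabling all time points.  Probe-level calls collapse to gene
symbols (a gene is significant if any of its probes is).  Each gene set,
intersected with the panel background, is scored with the exact hypergeometric
upper tail P(X >= k); sets with overlap k >= 5 form the FDR family
(Benjamini–Hochberg q values; the gate-before-FDR order is configurable
because the original tooling's order is not documented).  Significance
requires k >= 5, p < 0.01, q < 0.05.

## Benchmark-time modelling

The benchmark-dose framework is applied with time as the exposure axis: the
benchmark time (BMT) is the earliest time at which the fitted response departs
from baseline by the benchmark response (BMR).

**Response construction.**  For each probe, the per-replicate response at time
t is log2(normalised treated count + 0.5) − log2(mean normalised control at t
+ 0.5).  The t = 0 anchor — the analogue of the zero-dose group — is built
from control-only contrasts: each control replicate against the mean of the
other control replicates at its time point, pooled over time points and
centred at zero.  This gives the anchor 27 observations carrying pure
replicate noise; curve fits are correspondingly stabilised at baseline.

**Trend prefilter.**  A Williams-type trend test screens probes: the
isotonically amalgamated mean of the last level (pool-adjacent-violators in
the hypothesised direction, which for the top level equals the extreme of the
weighted suffix means) minus the anchor mean, standardised by the pooled
within-level error.  Both directions are tested; one-sided p values come from
permutation of observations across levels (1,000 permutations by default,
add-one corrected) and p = min(1, 2·min one-sided p), so the smallest
achievable p is 2/(n_perm+1).  Eligibility requires p < 0.05 and a maximal
|level-mean log2FC| > 1.

**Model families.**  Ten families are fitted by unweighted Gaussian least
squares: Linear, Poly2–4 (linear solves), Power γ+βt^δ (δ ∈ [1,18]), Hill
γ+vt^n/(k^n+t^n) (n ∈ (0,18]), Exp2 a·e^{bt}, Exp3 a·e^{sign(b)(|b|t)^d}, and
the plateau forms Exp4 a+M(1−e^{−bt}) and Exp5 a+M(1−e^{−(bt)^d}).  The
plateau forms are the classical a(c−(c−1)e^{−bt}) with M = a(c−1); the
reparameterisation changes no mean function or BMT but stays well conditioned
when the baseline is near zero, as it is on the fold-change scale.  Every
nonlinear family is profiled: amplitude parameters enter linearly once the
rate/shape parameters are fixed, so fitting reduces to a deterministic grid
plus local refinement over one or two nonlinear parameters (data-derived
starts, no random state).  Shape exponents are capped at 18 — the standard
benchmark-dose guard against step-function degeneracy.

**Selection and goodness of fit.**  AIC = 2p − 2 ln L̂ with the Gaussian
likelihood at the MLE variance and p = mean parameters + 1 (common variance);
constants cancel identically across families, so equal-parameter fits differ
by n·ln(RSS₁/RSS₂).  Ties within 1e−6 go to fewer parameters, then fixed
family order.  The fit p value is the likelihood-ratio test of the fitted
curve against the saturated per-time-level-means model, chi-square with
df = (#levels − #mean parameters), and 1 when df <= 0.

**BMR and inversion.**  The default BMR is 1.349 × the anchor standard
deviation — the continuous-endpoint convention of benchmark-dose practice —
resolved per probe; an absolute log2FC BMR ("abs:1.0") is available.  The BMT
is the smallest t > 0 with |μ(t) − μ(0)| = BMR: closed form for Linear, Power
and Hill, otherwise a dense-grid scan (log-spaced early points so small BMTs
are not skipped) refined by Brent's method; no BMT is reported if the response
never reaches the BMR before 10× the last observed time.

**Confidence bounds.**  Parametric bootstrap: Gaussian residuals are resampled
onto the fitted curve and the same family refitted (seeded at the original
estimate), recomputing the BMT at the fixed resolved BMR.  The residual scale
is the unbiased sqrt(RSS/(n−p)) — the MLE scale is visibly too small once a
family spends five parameters on thirty points — and each replicate draws its
σ from the scaled inverse-chi-square sampling distribution so variance
uncertainty propagates.  Bounds are the percentile interval (default level
0.90, 250 replicates; bootstrap BMTs beyond the horizon enter as +inf and
widen the upper bound).  More than 50% failed refits voids the bounds.  In
simulation this interval covers the true BMT at ~0.89 for nominal 0.90.

**Retention and summaries.**  A probe is retained iff BMT ∈ [0.1 h, 24 h]
(the 6-minute floor matching the reporting window), BMTU/BMTL < 40 (strict),
and fit p > 0.1 (strict).  Retained BMTs are summarised as an accumulation
curve (cumulative gene count at or before each time); per-time DEG tables
yield the earliest-response gene ranking (first significant time ascending,
|log2FC| descending on ties); and the predicted log2FC at the BMT comes from
a weighted five-parameter logistic fit on x = log10(t + 0.1): one unweighted
fit supplies residual weights w_i = 1/max(1e−4, r̂_i²) for a single weighted
refit (the exact weighting scheme of the original analysis is undocumented;
this residual scheme is our choice).  If the 5-PL fails, monotone
interpolation of level means is the flagged fallback.

## Synthetic data generator

Counts are negative binomial with mean s_j·q_g·2^{δ_g(t_j)} for treated
samples (δ ≡ 0 for vehicle): library factors s_j log-normal (CV 0.25),
baselines q_g log-uniform over 0.5–500 (responders 20–500, representing the
robustly expressed stress genes the panel targets), per-probe dispersion
log-normal with median 0.05 (log-sd 0.6) — three-replicate bulk-assay scale.
Planted responders follow δ(t) = f(t;θ) − f(0;θ) for a family from
{Linear, Power, Hill, Exp4, Exp5} with per-gene jitter of amplitude (×
lognormal 0.2), onset (× uniform 0.75–1.35) and shape; a configurable
fraction (default 25%) is down-regulated.  Pathways are disjoint gene sets
assigned at the gene level (multi-probe genes never straddle pathways).  The
default compound set has four active archetypes with staggered pathway onsets
plus one inert archetype; the truth table stores each responder's family,
parameters and analytic BMT.

What the generator does *not* emulate: probe-specific technical artifacts of
the assay chemistry, batch structure, outlier samples, and correlated
co-regulation beyond shared pathway timing.  Passing recovery tests therefore
demonstrate correctness of the estimators under the stated noise model, not
robustness to those real-data features.

## Recovery scoring

Recovery joins pipeline output to the truth table: DEG sensitivity and
false-discovery proportion against responder flags, top-ORA-set correctness,
Spearman correlation of the earliest-gene ranking against planted onsets, and
the BMT relative-error distribution.  Because the default BMR is anchor-SD
based and therefore data-dependent, the truth BMT is recomputed per probe by
inverting the *planted* curve at that probe's resolved BMR — estimate and
truth always share one benchmark-response definition.

## Problem sizes and harness conditions

The validation harnesses run at sizes chosen for single-CPU practicality:
recovery uses one active compound with 160 planted Hill/Exp5/Exp4 responders
in a 520-probe panel (500 Williams permutations, 60 bootstrap replicates);
trend-test calibration uses 2,000 null trials of 1,000 permutations; Wald
calibration uses 6,000 null probes; bootstrap coverage uses 200 simulations
of 100 replicates; model-selection sanity uses 200 replicates of linear truth
(slope 0.08 log2/h, residual σ = 0.3).

Recovery-harness responders use amplitudes of 4–6 log2 units — the scale of
the strong stress-gene inductions the emulated assay reports for its flagship
responders — with activation half-times inside the 24-h window.  This matters:
the achievable BMT precision is set by the slope of the response at the
benchmark crossing relative to replicate noise.  Under the default noise
model, sharply sigmoidal responders (Hill, Exp5 with d >= 2) recover with
~0.15 median relative error, while slowly saturating curves (Exp4 with
half-time >= 8 h, amplitude ~2.5) are frequently best-fit by Linear and their
BMTs land up to 2× late — a genuine identifiability limit of 3-replicate,
9-time-point designs, not an estimator defect.  Analyses of real data should
treat BMTs of weak, slowly saturating responders with corresponding caution.

## Known limitations

* Dispersion estimation is moments-plus-trend, not full empirical Bayes; with
  very few probes the trend fit is unstable (the shrinkage weight is
  configurable down to 0).
* Wald tests at n = 3 rely on the supplied dispersion being roughly right;
  strongly misestimated dispersions shift calibration.
* The Williams permutation p is granular (floor 2/(n_perm+1)); prefiltering
  at p < 0.05 needs n_perm >= 100 to be meaningful.
* Bootstrap bounds inherit model-selection optimism: the interval is built
  within the selected family only, one reason empirical coverage sits ~1
  point under nominal.
* The 5-PL predicted fold change extrapolates poorly outside the observed
  window; predictions are only reported at BMTs inside it.
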