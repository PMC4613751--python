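# Methods

## The question the pipeline answers

Two populations of a broadcast-spawning marine invertebrate with different
settlement histories may have diverged genetically in reproductive traits.
Rearing progenies of both populations and their F1 hybrids in a common
garden removes environmental differences, so expression differences that
persist — and that are *additively inherited*, i.e. intermediate in
hybrids — are candidates for heritable differentiation, possibly driven by
diversifying selection. The pipeline quantifies this with eP_ST, an
expression analogue of the quantitative-genetic differentiation index
Q_ST, and compares observed values against a permutation null.

## Models and procedures

### Preprocessing

* **Array QC.** An array is dropped when strictly more than
  `max_nonuniform_frac` (default 0.03) of its features are non-uniform.
  The boundary case (exactly 3 %) is kept.
* **Feature filter.** Negative-filtered cells become missing; transcripts
  missing everywhere are removed.
* **Quantile normalization.** On complete data, the classic
  sort / row-mean / unsort scheme; sorted columns are afterwards exactly
  equal. With missing cells, the reference distribution is the mean of
  per-column empirical quantile functions on an n-point grid, and each
  observed value maps through its average rank among the column's observed
  values, interpolating on the grid. Ties get the mean of the spanned
  reference values. Normalization runs *before* imputation, so the
  missing-data path is exercised in routine use.
* **KNN imputation.** Neighbours are transcripts (rows); distance is the
  mean squared difference over co-observed samples; the k = 10 nearest
  transcripts with an observed value in the target sample donate their
  mean. Ties break by row order. Observed cells are never altered.
  k is not dictated by the study design; 10 is the de-facto default of
  expression KNN imputers.

### Redundancy analysis and variance partitioning

Responses (samples × transcripts) are column-centered, never scaled; the
design matrix uses treatment coding without an intercept. The constrained
axes are the singular directions of the fitted values of the multivariate
least-squares regression of Y on X; eigenvalues are squared singular
values over (n − 1). Partial RDA residualizes both Y and X on the
conditioning design first. The factor shares are ratios of *constrained*
variances: share(sex) = constrained(Sex | Progeny) / constrained(Sex +
Progeny), and analogously for progeny — i.e. fractions of the explained,
not total, variance. In a balanced orthogonal design the two shares sum
to one exactly.

"Contribution" of a transcript to an axis is its loading (right singular
vector entry), unscaled by the eigenvalue — any per-axis monotone scaling
leaves tail membership unchanged. Tail selection is nearest-rank:
⌈q·n⌉ smallest and ⌈(1−q)·n⌉ largest scores, which on 31,918 distinct
scores at q = 0.001 gives 32 + 32 = 64 transcripts. Ward clustering of
selected transcripts uses 1 − Pearson correlation between expression
profiles as dissimilarity.

### Per-transcript ANOVA

The additive fixed-effects model `expression ~ sex + progeny` is fitted by
least squares, restricted to the two parental progenies (hybrids take no
part in the differential-expression contrast). F statistics use type-II
sums of squares — robust to the sex-ratio imbalance between progenies and
identical to type-I when balanced. No interaction term is fitted: only
main effects are interpreted downstream. BH adjustment is the standard
step-up procedure (delegated to statsmodels); missing p-values pass
through. The default selection cutoff is an adjusted p below 10⁻⁴.

### Additivity filter

H0: μ_HYB − (μ_FRA + μ_DAN)/2 = 0, tested as a linear contrast with the
variance pooled across all three groups, df = n_total − 3 and

    SE = sqrt( s²_pooled · (1/n_H + 1/(4 n_F) + 1/(4 n_D)) ).

The pooled contrast (rather than a one-sample t against a constant)
respects the sampling error of the estimated parental means. A transcript
is *additive* when the test fails to reject at α = 0.01. Accepting H0 is
logically hazardous — low power calls a transcript additive — and is kept
deliberately because it is how the field operationalizes the filter; the
hazard is a documented property, not a bug to fix. Degenerate case: zero
pooled variance with zero contrast is additive with t = 0; with non-zero
contrast, p = 0.

### eP_ST and the permutation scan

Variance components come from the one-way method of moments on the two
parental groups: σ̂²_GW = MS_within, σ̂²_GB = max(0, (MS_between −
MS_within)/n₀) with n₀ = (N − Σn_i²/N)/(k − 1) for unbalanced groups;
negative among-population estimates clip to zero. Then

    eP_ST = σ̂²_GB / (σ̂²_GB + 2 σ̂²_GW),

defined as 0 when both components vanish; the statistic lies in [0, 1]
and is invariant to rescaling the expression values.

The scan runs per sex (sex dominates gonadal expression, so pooling sexes
would swamp the population signal): additivity filter → observed eP_ST per
additive transcript → `n_perm` label permutations of the FRA/DAN samples
(hybrids excluded from eP_ST entirely) → pooled null across transcripts →
one global 0.999-quantile threshold per sex → outlier iff observed eP_ST
*strictly* exceeds the threshold. The additivity filter is fixed before
resampling. A single integer seed makes the scan reproducible.

Pooling the null across transcripts yields a single per-sex threshold
(matching how a single outlier cut-off per sex is reported in such scans);
a per-transcript null would need far more permutations per transcript for
the same tail resolution.

### Phenotype statistics

Sex distributions are compared with Pearson χ² (2 × k table, no Yates
correction — immaterial at ~60 individuals per progeny), both omnibus and
pairwise. The condition index is 100 · wet flesh weight / total weight
(percent). Its two-way ANOVA (sex, progeny) reports Shapiro–Wilk on
residuals and Bartlett across groups as diagnostics; pairwise LSD t-tests
among progenies (MSE and residual df from the ANOVA) run only when the
progeny effect is significant at 0.05 (Fisher's protected LSD) and are
summarized as compact letters.

## The synthetic-data generator

Each transcript has a baseline log2 intensity ~ N(8, 1.5²). A fraction
`frac_sex_de` (default 0.36) receives a sex offset ±e/2 with
e ~ N(0, sex_effect_sd²); a fraction `frac_progeny_de` receives a progeny
offset δ ~ N(0, progeny_effect_sd²) applied as FRA = μ − δ, DAN = μ + δ;
hybrids sit at the mid-parent mean (= μ) for additive transcripts and at
μ + `dominance_shift` otherwise. Noise is i.i.d. Gaussian. Missing cells
and non-uniform / negative feature flags are Bernoulli at configurable
rates. Sex assignment uses fixed female fractions per progeny (defaults
0.60 DAN, 0.27 FRA, 0.42 HYB — male-biased in FRA, female-biased in DAN,
intermediate hybrids) and condition indices are Gaussian around
per-progeny means (defaults 17.5 / 16.4 / 17.5 % for DAN / FRA / HYB at
sd 1 %).

Defaults for the effect-size and noise scales (sex 1.0, progeny 0.5,
noise 0.5 log2 units) are stated once for adequate test power; no
empirical effect-size distribution for real between-population expression
differences is available to calibrate them. What the generator does *not*
emulate: probe-level intensities, spatial array artefacts, dye effects,
heavier-than-Gaussian noise tails, correlated transcripts
(co-expression), or any real annotation. A green pipeline test therefore
establishes correctness of the statistical machinery under the assumed
model, not biological realism.

## Numerical choices

* Array-drop rule is strictly greater-than the 3 % threshold.
* Quantile-normalization grid interpolation is linear; exactness (bit
  equality of sorted columns) holds on complete matrices.
* RDA keeps singular directions with s > 1e-9 · s_max, capped at the
  design rank; rank deficiency after conditioning is an error naming the
  columns.
* Tail counts use an 1e-9 epsilon inside the ceiling to absorb binary
  float slop (0.001 · 1000 is not exactly 1).
* "Exceeds the null quantile" is strict (>); the empirical quantile is
  numpy's default linear interpolation.
* Constant transcripts: flagged with missing p in the ANOVA; an error in
  clustering (correlation undefined).
* A degenerate all-equal condition-index table short-circuits to F = 0,
  p = 1, one letter group.

## Known limitations

* The mean of the plug-in eP_ST ratio is biased low by ≈ 0.005 at n = 30
  per population (Jensen's inequality; the between mean square has a
  single degree of freedom with two populations), although the variance
  components themselves are estimated without bias. The permutation null
  shares the same bias, so outlier calling is calibrated; point estimates
  of eP_ST at small n are not.
* The additivity filter's retain-on-non-rejection logic conflates low
  power with additivity (see above).
* With only two populations there is no way to separate drift from
  selection per transcript; the scan ranks candidates, it does not prove
  selection.
* GEO series-matrix support parses the value table only (no platform
  annotation merging).
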