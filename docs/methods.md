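# Methods

This note records the models implemented in `ringpheno`, the defaults and
why, the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Chronology model

Ring widths w_t (mm) are converted to basal area increments
BAI_t = π(R_t² − R_{t−1}²) with cumulative radius R_t = pith offset + Σ w_i.
The pith offset defaults to 0 (cores taken to the pith); a `from_bark`
direction anchors the accumulation at the known outer radius instead. The
conversion is exact and conserves area: Σ BAI = π(R_n² − R_0²).

Standardization works on the log scale. A Hugershoff curve
g(t) = a·t^b·e^(−ct) + d (a > 0, b ≥ 0, c ≥ 0; d free) is fitted to
log BAI by least squares. Because the model is linear in (a, d) for fixed
(b, c), the fit profiles those two out on a 6×6 grid of (b, c) and polishes
the best grid point with bounded Levenberg–Marquardt using the analytic
Jacobian; if the nonlinear fit fails or does no better than a straight line
in t, the linear fit is used and flagged. The growth index is the ratio-type
score exp(log BAI − fit), which is centered near 1 by construction so that a
score of 0.7 reads directly as "30% below expected growth". A difference
index was the alternative; the ratio form was chosen because event-year
scores then have the natural multiplicative interpretation.

Widths of exactly zero (locally absent rings) are floored at 0.001 mm before
the log; interior missing years are an error, not an imputation.

Prewhitening fits AR(p) by conditional least squares with p ∈ 0..min(10, n/4),
all orders compared by AIC on the common sample t = p_max..n. The selected
order is the *smallest* one within 2 AIC units of the minimum: models closer
than that are statistically indistinguishable (Burnham–Anderson), and plain
lowest-AIC keeps a spurious AR term on ~22% of white-noise series, which
would leak detrending noise into the sensitivity phenotypes. Residuals are
recentered to the pre-whitening mean; the first p values, which have no full
AR prediction, pass through unchanged so every tree keeps the same calendar
coverage (the dplR convention of leading missing values would make
population chronologies start at tree-specific years).

Population chronologies are per-year Tukey biweight means (tuning constant
c = 9, MAD scale — the dendrochronology convention) across trees; a
single-tree population passes through with a warning. Chronology quality is
the mean pairwise interseries correlation r̄ (pairs with < 15 common years
skipped) and the expressed population signal
EPS = N·r̄/(N·r̄ + (1 − r̄)), defined for r̄ > 0.

## Climate

The drought code recursion uses the standard Canadian FWI formulation:
evapotranspiration V = 0.36·(max(T, −2.8) + 2.8) + L_f(month), floored at 0,
adds 0.5·V per day; rain above 2.8 mm recharges the moisture equivalent
Q = 800·e^(−DC/400) by 3.937·(0.83·P − 1.27) before the dry step. The
snow-free season is fixed at May–October with a startup DC of 15 (the
CFFDRS overwintering default); both are configurable, replacing an explicit
snow model. DC is undefined outside the season, so drought-code columns for
off-season months never enter the correlation window (10 of the 16 labels
remain for DC; all 16 for the other variables).

Monthly temperature and precipitation are means of the daily values (a
totals mode exists for precipitation); freezing days count days with
tmin < 0 °C. Every (variable, month) series is linearly detrended on
calendar year before correlation, so sensitivities reflect interannual
anomalies, not trends.

## Phenotypes

CS traits are Pearson correlations between growth scores and one climate
column over the analysis years, with a percentile bootstrap over years
(default 1000 resamples; degenerate zero-variance resamples redrawn);
significance = the 95% CI excludes zero. A percentile (not BCa) interval is
used because nothing in the pipeline needs the extra machinery and the
year-resampling bootstrap is the transparent default once prewhitening has
removed serial correlation; block bootstraps were considered unnecessary for
the same reason. Zero-variance climate columns (freezing days in summer) are
skipped — the trait does not exist. The response-function variant regresses
the chronology on principal components of the standardized climate columns
(eigenvalue > 1 retained), rotates the coefficients back to monthly space
and bootstraps them the same way; it serves as a collinearity-robust
cross-check, not a replacement.

Type-A traits are arithmetic means of the *raw* series over the analysis
window; type-B traits are the chronology score of one event year.

## Clinal screen

CS labels must be significant in ≥ 5 populations before clinal testing (a
variance screen against testing flat traits). Population traits are
regressed on MAT_p; linear and quadratic (on centered MAT_p) models are
compared by AIC, quadratic winning only when its AIC is lower by more than
1e−6 and the linear fit is not already numerically perfect. The
block-sample-size covariate is kept only when significant (p < 0.05) in a
preliminary fit. The overall-F p-value tests "no relationship with MAT_p";
traits with p < 0.01 (plus externally supplied dendrometric traits) pass to
association. Regressions are unweighted: weighting populations by sample
size was considered and rejected for transparency, since block sizes are
nearly balanced by design.

Mantel tests correlate off-diagonal upper triangles under simultaneous
row/column permutation of one matrix, two-sided, with
p = (1 + #{|r*| ≥ |r|})/(1 + n_perm), so p can never be 0; tiny matrices can
be enumerated exhaustively. Growth dissimilarity is 1 − r between population
chronologies; companions are great-circle distance and |ΔMAT_p|. The
spatially corrected correlation used once in the source analysis for the
MAT_p–MAP_p association is out of scope; a plain Spearman correlation is
reported with that caveat.

## Genetics and association

Genotypes are additive minor-allele dosages (minor defined on the analysis
sample). Filtering drops failed SNPs (call rate), then SNPs with MAF
strictly below 0.03; trees are only filtered when a threshold is given.

Ritland kinship per biallelic locus is
(P_x·P_y/p + (1−P_x)(1−P_y)/(1−p) − 1)/(m−1) with dosages P ∈ {0, ½, 1},
sample allele frequencies, m = 2; the multilocus estimate averages over loci
typed in both trees, monomorphic loci excluded, negative estimates retained
(truncation available as a flag). Allele frequencies come from the analysis
sample because no reference panel exists for a garden study.

DAPC mean-imputes missing dosages, centers/scales, retains the smallest
number of PCs explaining ≥ 90% variance (capped at n/3), k-means with fixed
k (default 3, BIC curve over k = 1..10 reported for diagnostics), then LDA
posteriors give the Q matrix; k − 1 columns enter the models as covariates.
Note that DAPC posteriors are confident *by construction* — the LDA is
trained on the k-means labels from the same data — so membership sharpness
is not evidence of real structure; on structure-free data the assignments
are simply uncorrelated with the true origins, and that is the null
behaviour the tests check.

The mixed model y = Xβ + Sα + Qv + Zμ + ε with μ ~ N(0, 2K·σ²ₐ),
ε ~ N(0, σ²ε·I) is solved EMMA-style: eigendecompose 2K once per trait
(after a 1e−6 diagonal jitter; remaining negative eigenvalues — routine for
marker-based kinship estimates — are clipped to zero, the nearest-PSD
bending used by mixed-model software, with a strict mode available), rotate,
estimate δ = σ²ε/σ²ₐ by REML on a 100-point log grid over 10^±5 plus
golden-section refinement (the refinement can never end below the best grid
point), then test each SNP by a GLS F-test at the null-model optimum
(P3D). Full per-SNP REML is available and used for conformance on small
fixtures; at n ≈ 225 the p-value differences are negligible and P3D is
orders of magnitude faster. SNPs with missing dosages are handled exactly by
re-decomposing on the observed subset. Labels count models with p < α = 0.05
(strict; missing p-values count as non-significant), uncorrected for
multiple testing — the deliberate design of the classification scheme, which
trades per-test stringency for cross-model agreement.

## Synthetic data

The generator emulates a single-garden provenance trial: 38 provenances with
MAT_p uniform on 1–11 °C laid on a south–north gradient (so climate distance
tracks geography; MAP_p loosely correlated with MAT_p, Spearman ≈ 0.4);
~6 trees per population (2–10) in two blocks; daily garden climate as a
seasonal sinusoid with AR(1) anomalies, a 0.03 °C yr⁻¹ warming trend and
seasonal gamma rainfall, from which the monthly table, drought code and
freezing days are derived through the climate module itself; 128 post-filter
SNPs with Balding–Nichols cluster structure (three clusters — two warm-origin
provenances vs a west/east split of the rest — divergence F = 0.10,
1% missing calls); rings 1989–2014 analysed over 1993–2014.

Growth is multiplicative on the log scale:
log BAI_t = Hugershoff(age) + Σ_ch s_ch·z_ch(t) + event_t + ε_t with
ε ~ N(0, 0.25²), so the standardization pipeline is exactly well-specified
under the null and detrending error is separable from sensitivity error.
Two channels are planted: July temperature (base −0.02, slope −0.018 per °C
of MAT_p, per unit-SD anomaly) and previous-October freezing days (−0.02,
−0.006). Three causal SNPs add centered allele-substitution effects of 0.04
to the July-temperature sensitivity (≈ 0.5 SD of the realized tree-level CS
trait). The 2003 event year receives a negative shock of −0.15 − 0.015·(MAT_p
− 6). The channel slopes were calibrated so the *realized* population-level
clinal fit of the July-temperature CS trait lands near adj R² ≈ 0.5 after
the pipeline's own attenuation (detrending, prewhitening, n = 22 correlation
sampling noise) — i.e. so the synthetic study reproduces the magnitude of
clinal signal the phenotyping approach is designed to detect. An optional
mean-growth mode adds MAT_p- or dosage-linked shifts to mean log-BAI for
type-A trait studies.

What the generator does *not* emulate: a shared year effect beyond the
planted channels. Real tree-level series at one site share most of their
interannual variance (r̄ ≈ 0.8 in the emulated study) because trees respond
to the full weather field; here only the planted channels are shared, so
synthetic r̄ is ≈ 0.02–0.05. Consequently, passing recovery tests show that
planted clines and causal effects survive the pipeline at realistic effect
sizes — they do not show that chronology-quality statistics on real data are
reproduced. Nor does the generator model densitometric microstructure,
spatially explicit gene flow, or within-garden microsite effects.

## Seeds and determinism

Every stochastic step takes an explicit seed; the generator fans a single
seed into independent substreams per stage (climate, provenances, trees,
genotypes, growth), so a stage can be rerun in isolation byte-identically.
Bootstrap profiles consume one generator sequentially and are
bit-reproducible under a fixed seed.

## Known limitations

* The null "very likely" rate of the three-model classification is ~2% per
  SNP–trait pair, not α³: the three models are nested fits to the same data
  (the Q and Q+K p-values correlate at ≈ 0.98), so cross-model agreement
  screens out far less than independence would suggest. The classification
  is implemented exactly as specified; its error control should be read as
  "roughly one shared-significance test", not a triple filter.
* EPS is reported unrounded; with r̄ = 0.80 and N = 233 the closed form
  gives 0.9989, which truncates (rather than rounds) to the conventionally
  quoted 0.99.
* The drought-code season is a fixed May–October window; sites with
  ephemeral snowpack need the configurable season bounds.
* P3D holds variance components at the null-model optimum; for very large
  SNP effects the full-REML mode is the conservative choice.
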