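# Methods

This note documents the statistical procedures, the defaults and the
design decisions in `urfomics`, in the order the pipeline runs them.

## Radiomic texture features

Features are computed on a single shared discretization of the ROI:
equal-width bins over the per-image foreground intensity range with a
**fixed bin count** (default 32).  A value x maps to level
⌈(x − min)/w⌉ with w = (max − min)/n_bins, clipped to [1, n_bins]; the
minimum maps to level 1 and the top edge is closed so every pixel
receives a level; constant ROIs collapse to one level.  Fixed bin count
(rather than fixed bin width) keeps features comparable across images
with different dynamic ranges, at the cost of making texture features
invariant to strictly increasing affine intensity transforms — a
property the test suite asserts.

The 86 features split 18/22/14/16/16 across first-order, GLCM, GLDM,
GLRLM and GLSZM.  Conventions:

* **GLSZM** zones are connected components of equal gray level;
  8-connectivity by default (4 configurable).  Conservation
  Σ s·counts(i,s) = n_pixels holds by construction and is tested.
* **GLRLM/GLCM** use the four 2-D directions (0°, 45°, 90°, 135°) at
  distance 1; features are computed per direction and averaged
  (the standard 2-D aggregation).  The four-angle average is invariant
  under 90° rotations.
* **GLDM** dependence counts 8-neighbours within gray-level tolerance
  α = 0.
* Logs are base 2 with ε = 2.2 × 10⁻¹⁶ added inside the log only, so
  empty cells contribute nothing and populated cells are unbiased.
* First-order Entropy/Uniformity use the discretized histogram; all
  other first-order features use raw intensities.  Skewness/kurtosis of
  constant ROIs are defined as 0.

## Normalization, aggregation and differential selection

Because features and genes live on incommensurate scales, both are
max-value normalized per column (x̃ᵢⱼ = xᵢⱼ / maxᵢ xᵢⱼ).  The formula is
undefined for negative values (several first-order features can be
negative), so columns containing negatives are divided by the maximum
absolute value; all-zero columns pass through with a warning.  Pearson
correlation and rank statistics downstream are invariant to this
scaling, so the choice only affects fold changes of signed features.

Multi-image patients are averaged (arithmetic mean per feature) to one
row per patient before testing; conflicting labels within a patient are
an error.

Differential features satisfy a two-sided Wilcoxon rank-sum p < 0.05
and max(FC, 1/FC) > 1 where FC = mean(positive)/mean(negative) on the
normalized scale.  The fold-change screen is deliberately
direction-agnostic: most reported differential features *decrease* in
HER2-positive tumours, so a literal FC > 1 rule would contradict the
selection it is meant to reproduce.  The rank-sum test is exact by
enumeration for combined n ≤ 12 without ties and uses the normal
approximation with tie and continuity corrections otherwise.  No
multiple-testing correction is applied across the 86 features by
default (an optional BH flag exists), matching the original selection
at raw p < 0.05.

## Cross-cohort pairing in the perturbation procedure

The imaging and expression cohorts contain different patients, yet the
procedure correlates a feature with a gene across "paired" samples.
This is the method's central ambiguity, and the package makes the
pairing rule explicit (`PerturbationConfig.pairing`):

* **shared** — one random index subset per perturbation, applied to
  both cohorts.  Meaningful when the two cohorts have equal class sizes
  and their sample order encodes a correspondence (a paired design, or
  the bundled synthetic cohorts, which are latently index-aligned).
  Under this mode a genuine feature–gene association survives
  subsampling and is flagged in essentially every perturbation.
* **independent** — subsamples drawn independently from each cohort and
  paired in drawn order.  This is the fully unpaired reading.  Under
  it the permutation distribution of Pearson's r has mean 0 and
  variance 1/(m−1) *regardless of any planted structure*, so genuine
  associations are statistically indistinguishable from null pairs and
  every flag is a pairing artifact; the min-hits filter then controls
  the per-gene false-call rate at roughly the binomial tail
  P(hits ≥ min_hits | n_perturbations, p₀) with p₀ ≈ 0.034 at
  subsample 50.  Applied to truly unpaired public cohorts, the
  procedure's output should be interpreted with this in mind.
* **auto** (default) — shared when class sizes coincide, otherwise
  independent.

Defaults follow the published configuration: 75 perturbations with
≥ 6 hits (test), 25 with ≥ 2 (validation), |r| > 0.3, p < 0.05.
Subsample size "auto" = min(class size in imaging cohort, class size in
expression cohort, 50) — the procedure requires only "the same number"
from each cohort, and capping at 50 keeps the per-perturbation null
rate stable.  With several expression datasets, perturbations are
allocated round-robin (3 × 25 mirrors the three-cohort design) and hit
counts pool across datasets.  Perturbation k of class c draws from a
dedicated `SeedSequence(seed, spawn_key=(c, k))` stream, so results are
independent of execution order.

Negative-related genes (≥ min_hits flags in the negative class) are
removed from each feature's positive-related set to form the
**positive-specific** set.  Because consecutive subsamples share most
of their samples, per-gene flag counts are overdispersed relative to a
binomial; a null gene with an unlucky full-cohort correlation can
accumulate many hits.  This "knockout" of genes by chance negative-class
hits runs at ~10–15 % per gene in the synthetic study and is a property
of the method, not of the implementation.

## Enrichment and module mining

Over-representation uses the upper-tail hypergeometric p
P(X ≥ x | N, K, n) with the **universe = all genes annotated in the
catalog** (keeping enrichment independent of the expression input).
The main analysis calls a term enriched at raw p < 0.05; BH-adjusted
calls are one flag away (used for validation-style analyses).  The
hypergeometric test is discrete and therefore conservative: the null
call rate is below the nominal 5 % (measured ≈ 2.4 % on random
queries).

A feature's "function set" is its enriched terms pooled across catalog
files.  Simpson similarity |F_i ∩ F_j| / min(|F_i|, |F_j|) is computed
between every non-differential feature and every differential feature;
candidates exceeding 0.6 (strict) become auxiliary features, reported
with their best partner (ties broken toward the partner with the
smaller enrichment p-sum — a reporting choice that never affects
membership).  Auxiliary candidacy is restricted to the features of the
same 86-feature extraction.  The URF-module is the disjoint union of
differential and auxiliary features with its (auxiliary, partner, sim)
edge list.

## Classification

Logistic regression is implemented natively: L2-penalized maximum
likelihood by IRLS on features standardized with training-split
statistics, intercept unpenalized, gradient-norm tolerance 1e-8.
λ = 1.0 on the standardized scale is the default.  The native
implementation keeps the whole evaluation deterministic given a seed;
other classifiers can be plugged in through the same
fit/predict-probability interface.  AUC is the midrank Mann–Whitney
statistic (equal to the trapezoidal area under the empirical ROC);
sensitivity/specificity are reported at the Youden-optimal threshold of
each test split.  Evaluation uses repeated stratified 70/30 holdout —
200 repeats by default in tests and examples, configurable to the
10 000 used at full scale — and feature-set comparisons reuse identical
splits so ΔAUC is paired.

## Synthetic study generator

The generator's defaults define the study conditions used by the tests
and the acceptance script: 60+60 patients, 2 images each (64×64 pixels,
elliptical ROI ~22×16 px), 1000 genes with 30 planted genes per planted
feature at target correlation r\* = 0.85, three expression datasets,
10 planted catalog terms per feature (20 genes each from the 30-gene
pools) over 30 uniform decoy terms.

* **Phantoms** are Gamma(2, 1) speckle smoothed with a per-class
  Gaussian scale inside an elliptical ROI, rescaled to 8-bit.  For this
  family, Zone Entropy grows monotonically with the smoothing scale
  (broader zone-size/gray-level spread), so the positive class uses the
  larger scale (1.6 vs 0.8), reproducing the reported direction of
  higher ZE in HER2-positive tumours; zone/run statistics separate the
  classes strongly at these settings.  Setting both scales equal gives
  a null phantom.
* **Expression cohorts** have the same class sizes as the imaging
  cohort and are latently index-aligned to it (different nominal
  patients).  A planted gene is r\*·z(f) + √(1−r\*²)·ε in positive
  samples (z(f) the standardized positive-class feature profile) and
  pure noise elsewhere.
* **Auxiliary twins** are chosen adaptively among features that are
  *not* differential on the supplied phantom table (the generator runs
  the same selection procedure the pipeline uses).  Twin genes load on
  the standardized mixture z(z_twin + z_partner), which guarantees
  correlation ≥ r\*·√((1+c)/2) ≥ 0.6 with both pair members whatever
  their mutual correlation c; the pair's shared catalog terms are drawn
  from these mixture genes, which is what makes the twin functionally
  similar to its partner downstream.
* Ground truth (planted features, gene lists, terms, twins) is always
  written beside the data; recovery scoring never re-derives it.

What passing the synthetic recovery tests shows — and does not show:
the pipeline correctly recovers planted monotone linear feature–gene
structure under index-aligned cohorts with Gaussian noise.  Real
ultrasound adds attenuation, shadowing and operator variability that
the phantoms do not emulate, real expression has correlated gene
modules and batch structure, and real cohorts are *not* index-aligned —
under honest unpaired cohorts the association stage degenerates to its
null behaviour (see the pairing section above).  Recovery on synthetic
data is therefore a correctness check of the machinery, not evidence
that the procedure extracts biology from unpaired cohorts.

## Numerical and degenerate-input choices

Constant feature or gene vectors inside a perturbation yield r = 0
(never flagged) rather than an error; the scalar `pearson_with_p` API
raises on constant input.  Zero-maximum columns pass max-normalization
unchanged with a warning; a zero negative-class mean makes the fold
change +∞ with a warning.  Splits that lose a class are redrawn (up to
10 attempts, then an error).  Features with empty positive-specific
gene sets have empty function sets and are skipped by the Simpson
stage.  All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawn keys.

## Scale of bundled analyses

Tests and the acceptance script run the full pipeline at 60+60
patients, 1000 genes, 75 perturbations and 200 holdout repeats; these
sizes reproduce every qualitative property of the full-scale
configuration (320 patients, ~20k genes, 10 000 repeats) while keeping
a complete run near one minute.  The 10 000-repeat and full-size
settings are plain configuration changes.
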