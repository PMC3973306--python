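# Methods

## Model

For a paired training study with n samples assayed in both a surrogate and a
target tissue, methylation beta values are arranged as n × m matrices X
(surrogate) and Y (target). Each CpG probe j is calibrated independently:

* **LM**: y_ij = a_j + b_j x_ij + e_ij, fitted by ordinary least squares on
  pairwise-complete observations. The closed form (slope = cov(x, y)/var(x),
  intercept = ȳ − slope·x̄) is used; it agrees with the normal equations to
  1e-10 (tested). A constant regressor falls back to an intercept-only model
  that predicts mean(y); fewer than 3 usable pairs flags the probe
  `insufficient_data` (predictions are missing, the probe is never silently
  dropped). LM predictions are *not* clamped to [0, 1] by default: the
  out-of-range count under extrapolation is a diagnostic of model
  fragility at small n, and callers can clip downstream when a beta scale is
  required.
* **SVR**: epsilon-insensitive support-vector regression with RBF kernel,
  using the defaults of the classical R implementation the field uses
  (e1071): epsilon 0.1, cost 1, kernel width gamma = 1/#predictors, and
  standardization of inputs and outputs (sd with n−1 denominator) with the
  output transform inverted at prediction. The fitted machine is stored as
  explicit numbers (standardized support-vector coordinates, dual
  coefficients, bias), so prediction is a pure function of the serialized
  model. Predictions are confined to the training-target range
  [min(y), max(y)] — the model's defining property in contrast to the LM —
  enforced by clipping: an RBF machine's far-field prediction tends to the
  bias term, but clipping makes the guarantee unconditional for every query.
* **Multi-probe LM**: for each target probe, predictors are the same-id
  surrogate probe (always first) plus the K−1 surrogate probes with largest
  absolute Pearson correlation with the target vector in training data, ties
  broken lexicographically by probe id; coefficients by multivariate least
  squares, collinear predictors dropped greedily (in selection order) with a
  warning. With K = 1 the fit delegates to the closed-form single-probe
  path, so the nesting is bitwise exact. The selection rule (genome-wide
  top-|r|, default K = 5) is this package's design; the multi-probe idea
  itself does not prescribe one. The evaluation set for the extension —
  probes with target-tissue SD in [0.1, 0.2] and raw cross-tissue R² < 0.3 —
  is drawn uniformly with a seeded RNG.

Missing data policy throughout: pairwise-complete per probe (maximizes
usable data; per-probe n is recorded). Model sets serialize to a versioned
JSON container so a model trained in one study can be applied to another.

## Accuracy assessment

R² here is the **squared Pearson correlation** between two beta vectors, not
1 − SSE/SST; the two differ for biased predictions, and squared correlation
is the convention for agreement between methylation profiles. It is
undefined (reported missing, with a reason) for constant vectors or fewer
than 3 pairs. MAE is the mean absolute difference over pairwise-complete
entries. Both are computed per sample (across probes) and per probe (across
samples), the latter alongside the target-tissue SD of the probe, since
accuracy is expected to track variability: for probes that barely vary,
technical noise dominates and R² is low even when MAE is tiny.

Cross-validation holds out one sample, or one whole family so relatives
never span the train/test split, per fold; models are fitted on the training
partition only. Training folds below 10 samples trigger a warning (the
recommended minimum training size is 10; below 3 is an error). The held-out
predictions are assembled into a full predicted matrix before metrics are
computed. Leakage-freedom — corrupting a held-out family's target values
never changes that family's own predictions — is asserted by test.

The raw cross-tissue correlation summary reports per-sample R² between the
two tissues before calibration, for all probes and after extreme-probe
filtering (removal of probes with pooled minimum beta > 0.9 / maximum < 0.1,
and the stricter 0.8/0.2 level, pooled over all supplied subjects and
tissues). Constitutively methylated or unmethylated CpGs inflate apparent
between-tissue agreement; the filtered summaries show the relationship at
informative loci. The two filter levels are nested by construction.

The decile-density diagnostic bins probes by the true target value into 10
equal intervals (left-closed right-open, the last bin including 1.0; a value
on an edge belongs to the upper bin) and measures how often the raw
surrogate value and each model's prediction fall inside the bin.

The sample-size experiment draws seeded random training subsets of sizes
3, 4, 5, 6, 7, 8, 10, 20, 30, 39 (10 replicates each; the full size runs
once), fits both models and predicts an independent test set. Each
(seed, size, replicate) cell has its own RNG stream, so any cell reproduces
independently.

## Preprocessing

Raw-intensity inputs follow the standard chain: beta = M/(M + U + 100)
(strictly below 1 for positive offset; 0/0 defined as 0); masking of cells
with detection P > 0.05 (27k profile) or detection P > 0.01 / beads < 3
(450k profile) — all thresholds strict inequalities; removal of samples with
> 20% missing probes (also strict); removal of SNP-flagged probes (flags are
taken from the annotation table; the variant lookup is external input).

Quantile normalization equalizes distributions across samples: on complete
data each sample's sorted vector becomes the across-sample mean of order
statistics exactly; with missing values, per-sample sorted values are
interpolated onto a common grid of length equal to the maximum non-missing
count to form the reference, which is interpolated back to each sample's own
grid. The 27k profile normalizes methylated and unmethylated intensities
pooled together, then recomputes betas; the 450k profile is a simplified
two-step equivalent of the published category-wise pipeline: sample-wise
quantile normalization of betas followed by a per-category, per-sample
monotone quantile mapping of Infinium II betas onto the empirical
distribution of the category's Infinium I betas (type I probes unchanged;
ties get average ranks; a single type II value maps to the type I median).
Background and color-bias correction are accepted as pre-applied to the
supplied intensities; the chain consumes normalized signals.

## Downstream utility

The association scan regresses each probe's methylation on a binary outcome;
with a 0/1 regressor the OLS coefficient is exactly the case/control mean
difference (asserted bitwise in tests), with the usual pooled-variance
standard error. No covariates are included by default, matching the simple
model the analysis is defined by. The effect-size bias comparison treats
target-tissue effects as the gold standard and reports the fraction of
probes where the calibrated effect is strictly closer than the raw surrogate
effect, with ties counted separately.

Hierarchical clustering of samples uses Euclidean distance over probes with
complete data (dropped probes are logged, not imputed — the
smallest-assumption choice) and average linkage by default (complete and
Ward available); distance and linkage are this package's defaults, as the
analysis itself does not prescribe them. Samples are processed in
lexicographic id order, so permuting input rows cannot change the tree.
Trees export as Newick with branch lengths equal to merge-height
differences, and a cophenetic-correlation helper compares trees built on the
same samples.

A note on which model serves which purpose: the affine LM calibration
preserves between-sample geometry (Euclidean distances are re-weighted by
the fitted slopes toward the target tissue's scale) and preserves small
case/control mean differences, so LM predictions are the right input for
clustering and effect-size comparisons. The epsilon-insensitive loss of the
SVR ignores residuals within 0.1 standardized units, which flattens subtle
differences at small n; SVR earns its keep for point prediction under
outliers and extrapolation, where its range guarantee binds.

## Synthetic data

The generator produces the structure the method assumes. Per-probe surrogate
means come from a bimodal mixture: 20% constitutively methylated probes
(Beta(40, 2), means near 0.95), 20% constitutively unmethylated (Beta(2, 40)),
and a broad middle component (0.1 + 0.8·Beta(2, 2)) — reproducing the
U-shaped beta distribution that motivates extreme-probe filtering (roughly
a third of probes are removed by the 0.9/0.1 filter, as on real arrays).
Between-individual SDs are small for constitutive probes (≤ 0.03) and
exponential-tailed for the rest (0.01 + Exp(0.06), capped at 0.25), so most
probes vary little and a minority vary substantially, as observed on arrays.

The target tissue is an affine transform per probe:
y = (mu + delta) + b·(x − mu) + N(0, noise_sd), truncated to [0, 0.999].
Conserved probes have b ~ N(1, 0.15) and |delta| ≤ ~0.02; 20% of probes are
tissue-divergent with consistent mean shifts |delta| ≥ 0.1 and slopes drawn
from Uniform(0.2, 1.8) — both attenuation (e.g. cell-mixture dilution) and
amplification occur between real tissues, and this spread is what makes
per-probe recalibration informative. Constitutive probes keep b = 1,
delta = 0. Technical noise defaults to SD 0.02, the scale implied by
duplicate-sample correlations above 0.99. Families (default: pairs) share a
random intercept carrying 30% of the between-individual variance, giving
leave-one-family-out CV something real to protect against. A binary outcome
(30% cases) can mark a random 5% of non-constitutive probes with effects
~ N(0, 0.1), either in the target tissue only (default) or expressed in the
surrogate and transmitted through the affine map (`outcome_in_surrogate`) —
the latter is the scenario in which effect-size de-biasing by calibration is
measurable, since an effect absent from the surrogate cannot be recovered by
any calibration.

Truncation, not a logit transform, keeps values in [0, 1]: it induces mild
nonlinearity near the boundaries (useful for exercising SVR) but means the
generating slope is the true regression slope only where no sample was
truncated — parameter-recovery checks therefore condition on variable
(surrogate SD > 0.1), untruncated probes, where fitted LM slopes correlate
> 0.99 with the generating slopes.

What the generator does **not** emulate: batch and chip effects, genotype
(meQTL) structure, cell-type composition shifts, probe cross-hybridization,
and chemistry-specific (Infinium I vs II) distribution differences beyond
what the alignment step is tested on. Passing tests therefore demonstrate
the statistical machinery, not robustness to those real-data artifacts.

## Problem sizes and numerical choices

Test and acceptance workloads use desk-scale versions of the study designs:
40 samples in 20 families × 2000 probes for the reference calibration study,
14 singleton samples × 800–1000 probes for the outcome/clustering analyses,
a 39-train/10-test split × 150 probes for the sample-size grid. These sizes
keep every property measurable (hundreds of variable probes per study) at
interactive runtimes.

Other fixed choices: probe/sample ids compare case-sensitively; matrices are
exchanged as tab-separated UTF-8 with `NA` for missing and exact float
round-tripping; file orientation is an explicit flag (never auto-detected —
silent transposition is the most dangerous failure mode for n ≪ m
matrices); alignment of two matrices keeps the first matrix's order;
variance below 1e-24·n counts as a constant regressor; dendrogram
comparisons are by cophenetic Pearson correlation over sample pairs.

## Known limitations

* The calibration is per-CpG and assumes the surrogate–target relationship
  estimated in training transfers to new samples; tissue- or
  population-specific relationships, disease processes confined to the
  target tissue, and exposures absent from the surrogate all violate this.
* SVR hyperparameters are fixed to the reference defaults, not tuned;
  tuning is deliberately out of scope for reproducibility.
* The 450k normalization is a simplified equivalent of the published
  category-wise pipeline and does not reimplement background or color-bias
  correction.
* Effect-size de-biasing requires the association to be (partially)
  expressed in the surrogate tissue; for target-only effects the calibrated
  and raw estimates are equally uninformative and calibration only adds
  estimation noise at near-constant probes.
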