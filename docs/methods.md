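# Methods

This note documents the models and procedures implemented in
`metabofinger`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data generator does and does not
emulate.

## The data model

A `FeatureTable` holds a features × samples matrix of non-negative
intensities with per-feature coordinates (m/z in Th, RT in min) and
per-sample design metadata (sample type, exposure group, batch, platform
mode, injection order). Missing values (`NaN` in memory, empty cells on
disk) mean *peak not detected* and are distinct from measured zeros; the
blank and presence rules depend on that distinction. All randomness in the
package flows from a single seed through named substreams (generator, CV
folds, permutations, forests, imputation), so any stage is reproducible in
isolation.

## Synthetic study generator

The generator emulates a two-group cell-exposure study: per run,
8 exposed + 8 control biological samples, 6 pooled-QC injections at evenly
spaced injection orders, 2 extraction blanks, and 12 spiked internal
standards, with a second batch replicating the design with identical truth
but independent noise. Per feature *f* and sample *s*, on the natural-log
scale,

    log I_fs = b_f + delta_f·[s exposed] + g_f·d(o_s) + eps_bio + eps_ana

where `b_f` is a log-normal baseline across features (log10 mean 5.0,
sd 0.8 — a 4–5 decade dynamic range typical of QToF feature tables),
`delta_f` is the log true fold change (uniform |log2 FC| in [3, 5] for the
100 differential features of 2000, zero otherwise), `d(o)` is a smooth
random cubic drift curve shared across features (maximum multiplicative
excursion 0.3) with feature-specific gain `g_f ~ U(0.2, 1)`, and the noise
terms are log-normal with coefficients of variation 0.20 (biological,
biological samples only) and 0.10 (analytical, all samples). QC samples
sit at the grand biological mean with analytical noise only; blanks sit at
5 % of the biological level except for 50 contaminant features that appear
at biological scale in blanks. Values below the run-level 2 % intensity
quantile are censored to missing (limit-of-detection behavior), a further
1 % of entries are dropped at random, and values clip at a 5·10⁸
saturation ceiling. Batch-2 coordinates jitter uniformly within ±3 ppm
and ±0.05 min to exercise cross-batch matching.

What the generator does **not** emulate: inter-feature correlation
(features are conditionally independent given group and drift — real
metabolite intensities are strongly correlated, which mainly affects
multivariate null distributions), chromatographic peak shapes, adduct and
isotopologue chemistry beyond a simple +1.00335 Da partner, retention-time
drift, and non-log-normal error tails. Tests passing on this generator
therefore demonstrate the pipeline's correctness and calibration under
its stated assumptions, not performance on any particular instrument.

## Drift correction

Per feature, a cubic smoothing spline is fit to log QC intensity versus
injection order. With only ~6 QC points the spline must not approach
interpolation — a noise-tracking fit is flat at the QC orders but wiggles
between them, *injecting* variance into the biological samples — so the
smoothing penalty grid spans a quarter of the QC variance up to an
effectively unpenalized single cubic, and the penalty is chosen by
leave-one-out cross-validation over the QC injections. All samples are
corrected on the log scale by subtracting the spline's deviation from its
mean level at the QC orders. The correction is retained per feature only
if the *leave-one-out* corrected QC RSD is lower than the uncorrected QC
RSD; the out-of-sample criterion matters because any fitted curve lowers
the in-sample QC RSD by construction. Features with fewer than 4 usable
QC values are left uncorrected with a logged reason.

## Filters

Applied in fixed order after duplicate/isotope merging and drift
correction; the order is part of the contract (the rules are per-feature,
so the surviving set equals the intersection, but the per-stage removal
attribution depends on order):

* **Blank**: remove a feature iff max present intensity over biological
  and QC samples is strictly below 10× the mean blank intensity, missing
  blank values counting as zero (both choices configurable).
* **Presence**: keep iff detected in ≥ 75 % of the control group *or*
  ≥ 75 % of the exposed group; QC and blank columns never count — "sample
  group" means the biological groups.
* **RSD**: keep iff the exposed-group RSD (100·sd(n−1)/mean over present
  values) is strictly below 30 %; undefined RSDs (fewer than 2 present
  values) are removed with reason "undefined".

Blanks are dropped from the table after the blank filter; they carry no
further information.

## Imputation, transforms, scaling

Missing values are imputed missForest-style on log intensities: initialize
at feature medians, visit features in order of increasing missingness,
regress each on all others with a 100-tree random forest (√p candidate
features per split) over the samples where it was observed, and stop when
the relative change of the imputed values stops decreasing (returning the
previous sweep) or after 10 sweeps. Fold changes are *never* computed on
imputed data: the univariate arm reads the drift-corrected, filtered,
unimputed snapshot on the raw intensity scale.

PQN uses the per-feature median over QC samples as the reference spectrum
and divides each sample by the median of its quotients against the
reference. The reference and quotients are always computed on the raw
intensity scale — with an even number of QC samples the median averages
the two central values, and an arithmetic average of logs is a geometric
average of intensities, so computing on the log scale would silently
change the factor; log-scale input is back-transformed for the factor and
normalized by subtraction. Pareto scaling centers each feature and divides
by the square root of its standard deviation, leaving each feature with
variance equal to its original sd; constant features are centered to zero.

## Univariate arm

Per feature, Shapiro–Wilk runs per group on the raw snapshot values
(degenerate/constant groups count as non-normal); if either group rejects
normality at 0.05 the two-sided Mann–Whitney U is used (exact when both
n ≤ 12 without ties, else the tie-corrected normal approximation),
otherwise a two-sided Welch t-test (a pooled-variance t is a config
switch). P-values are Benjamini–Hochberg adjusted by default — FDR control
is the norm in metabolomics; Bonferroni and raw-p modes are config
switches — and the selection rule is adjusted p < 0.05 **and** FC > 5 or
FC < 0.2 (a zero control mean yields +∞, passing the upper rule). The
deliberately strict FC band trades sensitivity for a very low false
positive rate.

## Multivariate arm

PLS-DA uses NIPALS on a single centered ±1 dummy response (for one
response each component is extracted in closed form). The component count
is chosen by stratified, seeded 7-fold cross-validation with a parsimony
rule: add a component only while Q² improves by at least 0.01 (threshold
and a pure Q²-maximization rule are config switches). The rule matters
because with n = 16 samples and thousands of features the fitted R²
saturates to exactly 1.0 within a few components regardless of the labels,
while Q² plateaus after the first; choosing the Q² maximum would make
permuted fits tie the observed R² and degenerate the permutation p-value.
For the same reason the y-scrambling test re-runs the cross-validated fit
with the model dimensionality *fixed* at the observed component count —
the convention of established PLS validation tools — and reports
(1 + #{permuted ≥ observed}) / (n + 1) for both R² and Q² (reporting the
mean permuted statistic instead is a config switch).

The random-forest classifier is bagged CART trees (√p candidate features
per split, 500 trees) built so each tree's bootstrap sample is accessible:
the OOB AUC scores each sample by its mean class-probability over the
trees that did not see it, and the mean decrease in accuracy of feature
*j* averages, over all trees, the drop in that tree's OOB accuracy when
*j* is permuted among its OOB samples (zero for trees that never split on
*j*). The multivariate selection is {VIP ≥ 1.0} ∪ {top 50 by MDA}; both
knobs are unstated in common workflows' reports and follow chemometrics
convention here, as config keys.

## Cross-batch validation

Features are matched across batches greedily one-to-one on m/z (10 ppm)
and RT (the platform's IS tolerance: 0.5 min HILIC, 0.2 min RPLC), nearest
m/z winning and RT breaking ties — transparent, and adequate at these
tolerances; a globally optimal assignment is deliberately out of scope. A
feature is *validated* iff it is combined-selected (univariate OR
multivariate) in both batches and the fold-change directions agree; the
direction rule automates the manual fold-change review such workflows
otherwise perform and can be disabled, and a stricter same-arm mode is a
config switch. Review artifacts are per-feature control/exposed boxplots
per batch and a tabular fingerprint of validated features with per-batch
fold changes and normalized log2 FC.

## Numerical choices and degenerate inputs

RSD uses the n−1 standard deviation. Undefined RSDs propagate as NaN and
are skipped in medians. Strict inequalities follow the stated rules
everywhere (a feature at exactly 10× blank is kept; exactly 30 % RSD is
removed; FC exactly 5 is not selected). Outlier cutoffs (group median −
3×MAD feature counts; 97.5 % chi-square quantile on PCA Mahalanobis
distance with a normal-consistent MAD scale so a gross outlier cannot mask
itself; any IS failure) are package choices exposed as config keys.
Internal standards are ordinary generated features flagged in truth, so IS
failures (low height, saturation, mass offsets) can be simulated. A
removed-sample re-run policy is left to the caller: `analyze_batch` is a
pure function of its inputs.

## Simulation sizes used by the test suite

The acceptance-style checks run the full default design (2000 features,
two batches, 1000 permutations) once, and the paired-seed comparison of
validated versus single-batch FDR at a reduced size (200 features, 20
differential, 20 seeds) — the comparison concerns a monotone property of
the validation rule, not absolute performance, and is insensitive to the
table width. Statistical calibration uses 5000 null features for the gated
test's type-I error and 200 replicates × 99 permutations for the
permutation test's rejection rate.

## Known limitations

Sensitivity of the validated selection under the default conditions is
structurally capped: with biological CV 0.20 on top of analytical CV 0.10
the exposed-group CV is ≈ 22.5 %, and the sample RSD of an 8-replicate
group then exceeds the 30 % cutoff with probability ≈ 0.08 — so requiring
survival in two independent batches caps expected validated sensitivity
near (1 − 0.08)² ≈ 0.84 before LOD-censoring losses, independent of effect
size. This is a property of the strict QC regime itself, which buys its
low false positive rate with exactly this sensitivity cost. Features
completely censored in the exposed group (the strongest possible
down-regulation) are removed as "undefined RSD" rather than reported —
a caller wanting presence/absence calls must look at the filter log.
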