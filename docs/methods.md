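# Methods

This note documents the statistical procedure `genesig` implements, the
choices made where the design was genuinely open, and what the synthetic
testbed does and does not establish about real data.

## Data model

The unit of analysis is a genes × samples matrix of already-normalised
log-scale intensities (e.g. RMA log2 values) with a binary per-sample
outcome (1 = distant metastasis within five years) and an optional
categorical stratum (ER status). Missing values are a load error, not a
state: public series matrices are expected to be complete after
preprocessing, and silent imputation inside a selection pipeline would be
untraceable. Matrix orientation is fixed genes-as-rows; the reader errors
on malformed input rather than guessing a transpose.

## Selection pipeline

**Screening.** Genes with median intensity below `intensity_threshold`
(default 5) are eliminated as unexpressed. "Median below the floor in a
group" admits two readings; the default (`both`) eliminates a gene only
when it is low in *both* outcome groups, because a gene expressed in one
group only is a differential signal worth keeping. The strict `any` reading
is a switch. Surviving genes are tested with a two-sided pooled-variance
(Student) t-test, kept at `p_threshold` (default 0.005). No multiplicity
correction is applied — the screen is a ranking device, not an inference,
and the fixed raw cut keeps the candidate pool small. Welch's test is
available by flag. Ties in p-value keep matrix row order so the pipeline is
deterministic.

**SVM-RFE.** Candidates are standardised once (training mean, sd with
ddof=1) — without this, |w| is not comparable across genes. A linear
soft-margin SVM (C = 1) is fitted and the gene with the smallest w² removed,
iterating to a total order (`step` > 1 available for speed; the final batch
is ordered by descending |w|). Within-batch w² ties break by the screening
order. The reverse elimination order is the ranking. The ranking is then
truncated to the largest configured candidate count (default counts
{2, 7, 12, 102} → 102), capped by the ranking length and by n − 2 so the
downstream VIF regressions stay determined.

**VIF selection.** VIF_j = 1/(1 − R²_j), R²_j from regressing feature j on
the other selected features plus an intercept, computed by least squares on
standardised values (VIF is scale-invariant; standardising is purely for
conditioning). 1 − R²_j below 1e-12 returns an infinity sentinel; computed
values are floored at the theoretical minimum 1. Selection is a greedy
forward pass in rank order: the first gene is always accepted; each later
gene is tentatively added and *all* VIFs of the tentative set recomputed;
the gene is kept only when every VIF is below the threshold (default 10,
the conventional alarm level; 5 and 100 are the usual stricter/looser
comparators). The full re-check is the only variant that guarantees the
final-set property "max VIF < threshold", which the tests audit with an
independent normal-equations oracle. A backward mode (repeatedly drop the
worst VIF) is provided for comparison. Candidate sets reaching the sample
count are refused rather than silently regularised.

**Gene-count optimisation.** For counts c = 1..(size of the VIF-selected
set), a k-fold outcome-stratified CV (default k = 10, folds shared across
counts) yields mean validation AUC per count. The rule operates on first
differences d_i of this curve: sort descending, take the value at rank
⌈q·m⌉ (q = 0.25) as the threshold, and choose the largest count whose
incoming difference is ≥ threshold − 1e-12 *and* strictly positive; if no
difference qualifies, the first count is chosen. The strict-positivity
clause prevents a plateau of exact zeros from dragging the choice past the
curve's maximum (and makes the documented invariant — for monotone curves
the choice never exceeds the first argmax — hold unconditionally); the
1e-12 slack merely absorbs float noise among nominally equal differences.
Tie counts at the threshold resolve to the largest qualifying count. With
fewer than three counts the differential rule is undefined and the whole
selected set is kept.

## Models and evaluation

**Models.** The default predictor is maximum-likelihood logistic regression
(intercept, no penalty) on training-standardised genes. Under complete
separation the likelihood has no maximiser; the fit falls back to a ridge
penalty of λ = 1e-6 (numerically indistinguishable from ML elsewhere) with
a logged warning. Comparators: linear SVM (C = 1; its signed margin is
mapped through a logistic function so scores live in [0, 1] — AUC only uses
the ordering) and random forest (500 trees, √p features per node, seeded).

**AUC** equals the Mann-Whitney U statistic scaled to [0, 1] with ties
counted ½; the test suite verifies exact agreement with brute-force pair
counting. **Mann-Whitney comparisons** between arms use the exact null
distribution when both groups have ≤ 8 tie-free observations, otherwise the
normal approximation with tie correction and *no* continuity correction —
so two identical AUC lists compare at p = 1 exactly rather than 0.998.

**Repeated splits.** Each repeat shuffles every (outcome × stratum) cell
with a generator seeded by (master_seed, repeat_index) and allocates
round(n·f) samples to training (f = 2/3 at the default 2:1 ratio, clamped
so both sides are non-empty). All signature arms share the identical splits
— a paired design that reduces comparison variance — while the Mann-Whitney
test, following standard practice in this protocol, treats the lists as
independent. Distributions are summarised by median, quartiles and the
2.5–97.5 percentile interval (the "95% CI"); a percentile interval was
chosen because the AUC list is the full object of interest and no
normality assumption is warranted at 200 repeats.

**External validation.** *Signature transfer* (exp1): the external cohort
is repeatedly split and the model refitted on its training portion with the
fixed gene list — this isolates the generalisability of the *genes*.
*Model transfer* (exp2): both cohorts are Z-scored per gene (whole dataset,
ddof = 1), the model is fitted on training portions of the discovery cohort
and applied to the entire external cohort — this additionally tests the
*coefficients*. Z-scoring on the full external dataset (rather than per
split) uses no outcome labels, so it leaks no class information; users who
need split-wise renormalisation can Z-score subsets explicitly. Missing
signature genes in the external cohort are an error, never imputed.

## Synthetic testbed

`SyntheticConfig` defaults describe the study conditions: n = 150 samples,
outcome prevalence 0.35, ER+ fraction 0.7 (drawn independently of outcome),
5 informative genes with a mean shift of 1.0 baseline-sd between groups
(per-gene AUC Φ(1/√2) ≈ 0.76; signs alternate, mixing up- and
down-regulated genes), 10 equicorrelated decoy blocks of 5 genes at
ρ = 0.9 (generated by a shared latent factor, x = √ρ·f + √(1−ρ)·ε, which
hits the target correlation exactly in expectation), 2000 independent null
genes of which 10% are centred at 2.0 — below the intensity floor — and
the rest at 8.0 ± 1.0 on a log2-like scale.

`generate_pair` draws two cohorts from the same class-conditional model and
perturbs the second with a per-gene location shift ~ N(0, batch_shift_sd²)
and a lognormal scale factor exp(N(0, (batch_shift_sd/2)²)). The scale law
was fixed a priori so that at the reference setting batch_shift_sd = 2 the
scale distortion is comparable in magnitude to the location shift on the
log2 scale (a shift sd of 2 ≈ 4-fold intensity change; e^{±1} scale
factors), as seen between array platforms. Both distortions are affine per
gene, hence removed exactly by per-dataset Z-scoring — which is precisely
the assumption behind the model-transfer design, and the testbed's point.

What passing tests on this generator do *not* show: robustness to
nonlinear batch effects (quantile distortions), probe-level artefacts,
outcome-correlated strata, gene-gene regulatory structure beyond
equicorrelation, or missingness. Results on real cohorts depend on those.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at its design
scale (≈2000 null genes, n = 150, 10-fold CV, 20–50 split repeats;
25 replicate cohorts for the recovery study), sizes at which every
distributional claim checked is stable across seeds. All randomness flows
from explicit seeds through `numpy.random.SeedSequence`; reruns are
byte-identical. Degenerate inputs fail loudly: zero-variance genes cannot
be Z-scored, standardised or fitted; singleton strata cannot be split;
single-class folds abort CV with a suggestion to lower k; empty stage
outputs name the stage and threshold that emptied them.

## Known limitations

* The intensity floor (5) presumes log2-scale intensities; other
  normalisations need a rescaled threshold.
* Greedy forward VIF selection is order-dependent by design (it protects
  the best-ranked genes); it does not find the globally largest
  low-collinearity subset.
* The differential-AUC rule is an elbow heuristic; no standard-error band
  is attached to the chosen count.
* Survival/time-to-event structure is reduced to a binary five-year
  outcome; censoring is not modelled.
* The Mann-Whitney comparison between arms ignores the pairing induced by
  shared splits and is therefore conservative.
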