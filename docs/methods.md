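# Methods

`cfmosaic` implements a desk-scale analog of a multimodal cell-free DNA
(cfDNA) liquid-biopsy workflow: nine per-sample feature groups are
extracted from fragment-level records and methylation count tables, a
stacked ensemble separates cancer from healthy samples at a
specificity-anchored cutoff, and a graph neural network assigns a tissue
of origin (TOO) to detected cancers.  Because real multi-cancer cfDNA
cohorts are access-restricted, the package ships a seeded generative
simulator whose defaults encode the contrasts such assays report; every
stage of the pipeline is exercised and tested against data from that
simulator.

## The synthetic cohort model

**Reference genome.** A seeded random genome (default two chromosomes of
1 Mb) stands in for the human reference.  At 1 Mb per chromosome every one
of the 256 possible 4-mers occurs thousands of times, so end-motif
positions can be sampled directly from an index of motif start positions.
Bin widths are scaled by `bin_scale = 1/50` relative to their human-genome
counterparts: methylation/copy-number bins of 20 kb play the role of 1 Mb
bins, and 100 kb fragment bins play the role of 5 Mb bins, so the binning
logic runs over many bins without a full-size genome.

**Fragment lengths.** Healthy plasma cfDNA has a sharp mononucleosomal
peak at 167 bp.  The healthy length distribution is a discretized Gaussian
mixture on 100–250 bp with a broad (sd 20 bp) and a narrow (sd 2 bp)
component both centred at 167 bp; the narrow component reproduces the
knife-edge modal peak of real size profiles and keeps the empirical mode
stable at moderate fragment counts.  Tumor-derived fragments are shorter:
the tumor distribution is the same mixture centred at 145 bp.  Fragments
at or below 150 bp are "short", 151–250 bp "long".  The short-fragment
mass of each distribution is calibrated through the identity

    p_short = r / (1 + r),

which makes the expected short/long count ratio equal `r`.  The healthy
distribution is calibrated to `r = 0.27` and the pure-tumor distribution
carries `P(short) = 0.35`; the default tumor fraction `t ≈ 0.089` is the
solution of the mixture equation

    (1 - t) p_healthy + t p_tumor = 0.29 / 1.29,

so a default cancer-class cohort has an expected bin-wise short/long ratio
of 0.29.  Each fragment's length is drawn from the
tumor-fraction-weighted mixture.

**End motifs.** Fragment 5' ends are placed by sampling a 4-mer from the
class's 256-entry motif distribution and then a uniformly random indexed
reference position of that motif.  The healthy motif distribution is
uniform; cancer classes share a ±20% relative tilt on ten designated
motifs (up: CAAA, TAGA, CAGA, CAAG, CAAT; down: CGCT, CGCC, CGCA, GCCT,
CGTT), and each class carries an extra +30% tilt on six private motifs so
TOO is learnable from motif profiles.  Excess probability mass is
re-normalized uniformly over untouched motifs.

**Methylation.** Counts are binomial: for an interval with healthy
baseline `b`, tumor-level shift `s` and tumor fraction `t`, the methylated
count at depth `d` is `Binomial(d, clip(b + t·s, 0, 1))`.  The 450-region
target panel has seeded baselines in [0.15, 0.55]; 339 regions carry a
tumor-level shift of +0.5 (hyper-DMRs), 63 of −0.5 (hypo-DMRs) and 48 are
null, and each cancer class adds +0.8 on a private block of 20 hyper
regions.  Genome-wide bins have baselines in [0.60, 0.80] and a shared
tumor-level shift of −0.2 (global hypomethylation) plus per-bin Gaussian
noise (sd 0.01).  Default depths are 2000 reads per target region (deep
capture fraction) and 1000 per genome-wide bin.

**Copy number.** Each cancer class owns genomic segments with an integer
tumor copy number `c` (6 for gains, 0 for losses).  The cfDNA-level log2
copy ratio of a segment is `log2(1 + t(c/2 − 1))`; fragment positions are
thinned by rejection sampling so expected per-bin counts scale with
`2^log2ratio`.

**What the simulator does not model.** Sequencing error, bisulfite
conversion failure, GC-coverage bias (per-bin GC effects exist only
through the random base composition), mappability structure, batch
effects, age- or inflammation-driven methylation drift, and biological
within-class heterogeneity beyond binomial/multinomial noise.  Passing
tests therefore demonstrate that the *algorithms* recover effects of the
designed kind and size — not that the trained models would transfer to
clinical cohorts.

## Feature extraction

All coordinates are 0-based half-open; a fragment belongs to the bin
containing its 5' start.  Only fragments of 100–250 bp are analyzed.

* **TM / GWM** — methylation ratio `m / (m + u)` per target region / per
  genome-wide bin.  Zero-coverage intervals yield a missing value (never
  0), imputed downstream with the training-cohort median.
* **CNA** — per-bin fragment counts are divided by a LOESS trend of count
  against bin GC fraction (span 0.65), scaled by the sample median,
  winsorized at median ± 4·MAD and log2-transformed.  When GC is constant
  (as in the uniform-composition mini-genome) the trend reduces to the
  mean, making the correction a no-op rather than a numerical hazard.
* **FLEN** — the 151-entry length frequency vector (percent; sums to 100).
* **SHORT / LONG / TOTAL / RATIO** — per fragment-bin counts of short and
  long fragments, their sum, and the short/long quotient (missing when a
  bin has no long fragments).
* **EM** — frequency of the 256 reference 4-mers at fragment 5' ends,
  lexicographic order, summing to 1; windows containing a non-ACGT base
  are excluded from numerator and denominator.

SHORT, LONG and TOTAL are z-scored with means/SDs fitted on training
samples only and applied unchanged to validation samples (leakage-safe);
zero-variance features get SD 1 and are flagged.  RATIO, FLEN, EM, TM,
GWM and CNA enter models on their natural scales.

## Differential analysis

Per-feature two-sided Wilcoxon rank-sum tests (exact null at small n
without ties) with Benjamini–Hochberg step-up correction by default and a
Bonferroni switch for the end-motif analysis.  The log2 fold change uses
group means with a 1e-6 pseudo-mean floor for positive-valued features
and falls back to the mean difference (flagged) otherwise.  Features with
adjusted p ≤ α (default 0.05) are called hyper/up or hypo/down by the
sign of the fold change.

## Detection model (stage 1)

Per feature group, logistic regression, random forest and gradient-boosted
trees are tuned by 5-fold stratified grid search on cross-validated AUC
(grids are configuration; the defaults are lasso/ridge/unpenalized LR with
C ∈ {0.01, 0.1, 1, 10}; RF with 100/300 trees and depth ∈ {None, 5, 10};
boosted trees with depth ∈ {3, 5}, learning rate ∈ {0.05, 0.1} and
100/300 rounds).  Tree models drop features with importance below 1e-4.
The winning algorithm per group is reported with its 20-fold stratified CV
AUC (mean of fold AUCs, with a normal-approximation 95% CI).

The stacked ensemble is a logistic meta-learner over base-model
probability scores.  The meta-learner is trained exclusively on
*out-of-fold* scores — a sample's score always comes from a base model
that never saw that sample's fold — because in-sample base scores would
bias the stacked AUC upward.  All 511 non-empty subsets of the nine groups
are evaluated by cross-validated AUC; ties prefer smaller subsets, then
lexicographic order.  The decision cutoff is the smallest observed score
threshold whose specificity on the selection set reaches the target
(default 95%) under the rule "cancer if score ≥ cutoff"; if the target is
unreachable the classifier degenerates to all-negative with a warning.
AUC is computed by trapezoidal ROC integration (verified in tests against
the Mann–Whitney U identity), confidence intervals by 2000-replicate
stratified bootstrap, and AUC comparisons by DeLong's paired test with
midrank placements.

## Tissue of origin (stage 2)

Only samples called cancer by stage 1 are localized.  Node vectors are
the concatenated feature groups (optionally variance-filtered to the top
200 features per group), standardized on training nodes and
unit-L2-normalized, so pairwise Euclidean distances live in [0, 2].  The
graph draws an edge wherever the distance is below δ = 0.8 — the bounded
embedding is what makes a fixed δ meaningful — and any isolated node is
connected to its single nearest neighbour (flagged).  On weak-signal
embeddings the threshold rule can leave most nodes isolated, in which
case the fallback produces a sparse nearest-neighbour graph; δ is a
configuration knob.

The classifier is a three-layer attention message-passing network (hidden
size 44, 4 heads; head outputs concatenated through an ELU in hidden
layers and averaged into class logits in the last layer; a
mean-aggregation switch is provided).  Training is transductive —
unlabeled nodes relay messages but contribute no loss — with focal loss
(γ = 2, per-class weights defaulting to inverse class frequency) and Adam
(learning rate 1e-3).  Model selection follows stratified 10-fold
cross-validation over labeled nodes, keeping the model from the
highest-accuracy fold.  The network and its gradients are implemented on
a small reverse-mode automatic-differentiation core over numpy arrays
(`cfmosaic.autodiff`), whose gradients are verified against central finite
differences in the test suite.

Feature importance is estimated per class by a mask-learning explainer: a
sigmoid feature mask is optimized to keep that class's nodes confidently
predicted from masked inputs while an L1 penalty shrinks uninformative
features; the mask value in [0, 1] is the importance score, thresholded
at δ_f = 0.9.  A class-weight-balanced random forest (3-fold grid search,
10-fold CV accuracy) serves as the flat baseline.

## Numerical choices and degeneracies

* All randomness flows from explicit integer seeds; per-sample simulator
  seeds are derived from the master seed via `numpy` seed sequences and
  recorded in the cohort manifest.  Identical design + seed reproduces
  byte-identical cohort files.
* Grid-search ties keep the first parameter set in grid order; algorithm
  ties keep the earlier algorithm in (LR, RF, XGB) order.
* Empty bins are floored at 2^-10 before the CNA log2; zero probabilities
  are clipped at 1e-12 inside the focal loss.
* Segment softmax in the attention layer subtracts the per-segment
  maximum (a constant shift, gradient-exact) for numerical stability.

## Problem sizes used in the checks

The shipped checks run on the miniature genome with, typically, 20–40
samples per cohort at 20k–50k fragments for calibration and recovery
checks, a 200-vs-200 cohort at 5k fragments for motif recovery, and a
390-sample two-cohort analog (260 healthy + 130 cancer, split 300/90
train/validation) for the end-to-end run — sizes chosen so the designed
effects are comfortably detectable while the whole suite runs on a single
CPU in minutes.  The reduced tuning grids used by the end-to-end smoke
runs are ordinary configuration; the full default grids are exercised on
the smaller fixtures.

## Known limitations

* The ε-threshold δ = 0.8 was reported for an unspecified embedding
  scaling; the standardize-then-L2-normalize choice here is one defensible
  reading and is configurable.
* Focal-loss γ and α, the tuning grids, and the simulator's effect sizes
  are not published quantities; they are package defaults, documented
  above, not estimates of any study's values.
* Cohort-specific clinical numbers (detection AUCs near 0.93–0.95,
  sensitivities at 95% specificity, TOO accuracies near 0.7) depend on
  restricted patient data and are out of scope; the package reproduces
  procedures and calibration targets, not clinical performance.
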