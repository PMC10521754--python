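# Methods

## Problem and model

The task is weakly supervised binary classification: a patient is a *bag*
of histology tiles plus a serum-biomarker 4-vector (CEA, CA125, CA19-9,
AFP), and only the bag-level lymph-node-metastasis (LNM) label is observed.
No tile-level labels exist, so the image channel must discover which tiles
matter.

The classifier has three parts.

**Image channel.** Tile images are mapped to feature rows by a frozen
convolutional backbone (below), standardized with training-set statistics,
and reduced to the most discriminative dimensions by MMD selection. A
linear + ReLU layer embeds each instance `h_k`; gated attention

    a_k ∝ exp( wᵀ( tanh(V h_k) ⊙ σ(U h_k) ) ),   Σ_k a_k = 1

produces convex weights, and the bag representation is `z_img = Σ_k a_k h_k`
over the embedded instances. The construction is permutation invariant, and
duplicating instances renormalizes the softmax without changing `z_img`.
Plain (non-gated) attention is available by config.

**Biomarker channel.** The min-max-normalized 4-vector passes through a
one-hidden-layer ReLU network with a tanh-bounded output `z_bio`.

**Fusion and head.** Sigmoid gates computed from the concatenation
`[z_img ‖ z_bio]` rescale each modality elementwise (controlling each
representation's expressiveness); a constant 1 is appended to each gated
vector and the fused representation is the flattened Kronecker product,
length `(d₁+1)(d₂+1)`. The appended ones preserve the unimodal sub-blocks,
so fusion never discards single-modality information; the cross terms model
pairwise interactions. The exact functional form of the gates is this
package's reconstruction — the gating mechanism is named in the tensor-fusion
literature without a canonical formula. A ReLU hidden layer and softmax give
class probabilities; training minimizes categorical cross-entropy
`L = −(1/N) Σ_i Σ_c δ(y_i=c) log P(y_i=c)` with the true-class probability
clamped at 1e−12 (training robustness; a warning is emitted rather than an
error). Ablation modes replace the missing channel with a learned constant
vector so the head's shape is unchanged; the image-only mode provably
ignores biomarker input.

The network, its gradients and Adam live in a ~300-line reverse-mode
autodiff core over numpy arrays (`mmil._autodiff`); gradient correctness is
pinned by finite-difference tests at 1e−7 on composite graphs and 1e−4 on
the loss/logits path.

## Instance feature extractor

The default backbone (`tinyconv`) is two 5×5 stride-2 convolutions (8 and
16 channels, ReLU) with seeded random weights, followed by per-channel
global mean and standard-deviation pooling (feature_dim 32). It is frozen:
random convolutional projections act as a generic texture encoder whose
channel statistics respond to nucleus density and blob structure, which is
the discriminative content of the tiles (and, at the bag level, what
separates the classes). Preprocessing is fixed: pixels scaled to [0, 1] and
standardized with mean 0.5 / std 0.25 per channel; off-size tiles are
resized. The backbone registry keys on (name, input size, seed) so swapping
a backbone changes only `feature_dim` downstream.

## Feature selection

Each feature dimension is scored independently: pool instance values over
all positive bags and all negative bags, compress each pool to a 50-bin
histogram over the combined range, and compute the squared MMD between the
two histogram-weighted samples (Gaussian kernel, per-dimension median
heuristic bandwidth with a deterministic subsample). The top `n_keep`
dimensions (default half) are kept. The estimator is the biased
V-statistic, non-negative and exactly zero for identical samples; the
histogram-compressed variant equals a weighted double kernel sum over bin
centers. Scoring dimensions (rather than pruning instances) is a design
choice where the underlying selection scheme is described only as
"histogram + MMD" in the MIL literature; the alternative instance-pruning
reading is noted but not built. Selection is fitted on training folds only
and frozen, like every other fitted transform; each records the bag ids it
saw and the evaluation path asserts disjointness from test bags.

## Tiling

0-based (row, col) indices, half-open pixel boxes, row-major enumeration,
stride = tile size (non-overlapping; the stride is not specified in the
protocol this follows, and non-overlap is assumed). Edge tiles that would
exceed the image are dropped, never padded. ROI overlap is an exact pixel
count; tiles with overlap < 20 % are excluded, so a tile at exactly 20 % is
kept. Microns-per-pixel is metadata only — no rescaling.

## Biomarker imputation and scaling

MICE with predictive mean matching, single-imputation output: markers are
swept in fixed order (CEA, CA125, CA19-9, AFP); each marker is regressed by
OLS on the other three over its observed rows; each missing cell receives
the observed value of one of the `k_donors = 5` rows with nearest predicted
mean, drawn uniformly with a seeded generator; `n_iterations = 10` sweeps.
Defaults follow common MICE practice — the source protocol names the method
without settings. Only the four markers enter the regressions (whether the
label was used is unstated; excluding it is the conservative choice).
Observed cells are never altered and every imputed value lies in the
marker's observed support (a PMM guarantee, asserted in tests). The frozen
model (final coefficients + donor pools) applies to held-out rows without
refitting. Min-max scaling is fitted on training rows; apply-time values
are clipped to [0, 1] (external cohorts can exceed the training range) and
a constant marker maps to 0.

## Statistics

AUC is the tie-corrected Mann–Whitney statistic from midranks (tested to
1e−10 against both trapezoidal ROC integration and brute-force pair
counting). The Youden cutoff maximizes J = sensitivity + specificity − 1
over observed thresholds under the rule "score ≥ cutoff ⇒ positive", ties
broken toward the lower threshold (higher sensitivity); the reported cutoff
is the midpoint of the gap below the winning threshold. Bootstrap CIs are
percentile intervals from B = 1000 class-stratified resamples (stratified
resampling guarantees both classes in every replicate). The rank-sum test
enumerates all C(n, n₁) rank assignments with midranks for combined n ≤ 20
and uses the tie-corrected normal approximation otherwise; all tests are
two-sided. Cross-validation is stratified (labels are imbalanced in the
clinical setting); fold counts are configuration, not constants.

## Synthetic study conditions

The generator emulates the *structure* of a private two-class cohort, not
its images. Tiles are noisy pale fields with Poisson-placed dark ellipses
("nuclei", mean 6 per 64-px background tile); positive bags contain key
tiles whose nucleus rate is multiplied by `density_ratio = 3` (node-positive
tumors show denser tumor-cell populations). Key tiles are assigned
per-tile with probability `key_tile_fraction = 0.06`, floored at one key
tile per positive bag — so the image signal is real but sparse and varies
between bags. Biomarkers are log-normal with class medians from a
T3-stage clinical table (CEA 5.06/3.45 ng/mL, CA125 11.90/11.10 U/mL,
CA19-9 12.11/8.13 U/mL, AFP 2.44/2.48 ng/mL for LNM+/LNM−) and sigmas
(0.22, 0.22, 0.18, 0.18); CA19-9 is by far the most discriminative marker,
as in the clinical table. A `missing_rate = 0.1` fraction of biomarker
cells is masked completely at random (the weakest testable missingness
assumption; the label is never masked).

The sigma and key-fraction values were calibrated once, at design time, so
that the two channels are *complementary at the package's cohort scale*
(80 patients, 40 train / 40 test, 20 tiles of 64 px — sizes chosen so the
full ten-replicate protocol runs in minutes on one CPU): each single
channel is informative but imperfect, and the fused model reliably exceeds
both ablations. Consequences worth stating plainly: the biomarker sigmas
are far tighter than clinical marker tails (real CA19-9 spans five orders
of magnitude), the tiles are not H&E renderings, and passing tests
demonstrate that the *pipeline* recovers planted multimodal structure — not
that these AUC levels transfer to clinical data.

The centre-shift variant used by the fine-tuning protocol multiplies all
biomarker medians by 1.5 (assay calibration gap) and adds an RGB offset of
(−35, −20, +15) to every tile (staining-protocol drift — the dominant
centre-to-centre difference in multicentre histopathology). Both frozen
preprocessing and the frozen model are applied unchanged to the shifted
cohort; fine-tuning runs 5 epochs at 0.3× the base learning rate from the
frozen checkpoint. A biomarker-scale shift alone leaves the frozen model
statistically unharmed at these sample sizes, which makes the
frozen-vs-fine-tuned comparison a coin flip; the stain component creates a
genuine, recoverable domain gap.

## Training defaults

Adam (β = 0.9/0.999, ε = 1e−8), learning rate 0.01, 60 epochs, batch size 8
bags, weighted random sampling with replacement under inverse class
frequency (each batch class-balanced in expectation). Representation dims
8 (image) and 8 (biomarker) — balanced so neither modality dominates the
fused product (fused length 81); attention hidden 16; classifier hidden 32;
dropout 0 by default (config-exposed). Hidden sizes are honest defaults,
config-exposed, not claimed faithful to the original system — they were
never published. All weights come from a seeded generator; evaluation mode
is deterministic.

## Interpretation

A tile's LNM probability is defined by singleton-bag inference through the
trained model with the patient's biomarker vector held fixed (the
definition is this package's choice; attention-weight maps are available as
an alternative through the same structure, and a neutral-biomarker mode
yields pure-image maps). Heatmaps use a monotone colormap (inferno),
transparent cells for unretained tiles and an embedded legend strip;
rendering is byte-deterministic. Histomic features of top-probability
tiles: nuclei are segmented by grayscale inversion + Otsu + small-object
removal (< 9 px) + connected components (color-deconvolution stain channels
only make sense for real H&E input and are out of scope for the synthetic
tiles); per-nucleus area and solidity; Haralick sum-average
Σ k·p_{x+y}(k) from the symmetric, normalized GLCM at distance 1 averaged
over four directions (8 gray levels for the low-dynamic-range synthetic
tiles, 32 suggested for real H&E); mean first-nearest-neighbor centroid
distance via a KD-tree. A tile with no detected nuclei yields zero count
and NaN morphology, not an error.

## Numerical choices and degenerate inputs

Loss clamp 1e−12; attention softmax max-shifted for stability; feature
standardization floors std at 1e−8; constant feature dimensions score 0 in
selection (not an error); a constant marker min-max-maps to 0; bootstrap
of a resampling-invariant metric gives a zero-width interval; the Youden
search on all-equal scores reports J = 0. Fusion dimension is capped
(default 65536) with an error advising smaller representation dims. NaNs
fail fast with the pipeline stage named.

## Known limitations

* The backbone is a random frozen projector; no pretrained-network weights
  are bundled, and real H&E transfer would need a stronger extractor behind
  the same `BackboneSpec` interface.
* Single imputation only — no Rubin pooling across multiple imputations.
* The generator does not emulate stain variation within a cohort,
  pyramid/WSI formats, or realistic biomarker tails (see above).
* Tile probabilities from singleton-bag inference are one of several
  defensible readings of "per-tile probability"; conclusions drawn from
  heatmaps inherit that choice.
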