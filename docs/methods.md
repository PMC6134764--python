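# Methods

This note documents the models, defaults and design choices behind
`cytofingerprint`, and what the synthetic studies do and do not show.

## Data model and gating

A sample is an `EventMatrix`: N events × C channels of finite,
arbitrary-unit intensities in acquisition order.  Files are read/written
as FCS list mode (3.1 written — single dataset, 32-bit float,
little-endian, channels matched case-sensitively by the `$PnN` short
name; 3.0 and 3.1 accepted on read, datatypes F/D, both byte orders) or
as CSV with a header row of channel names.  Only the pulse-*area*
channels `FSC-A`, `SSC-A`, `AmCyan-A` are analyzed; height/width variants
are ignored.

Instrument gating templates are graphical and instrument-specific, so
gating here is axis-aligned thresholding: per-channel lower bounds remove
low-signal background (debris, dead cells) and an FSC-A upper bound
removes putative doublets.  The default gate is a no-op; thresholds are
configuration, not constants.  Gating preserves event order and is
idempotent.

## Fingerprints

Fingerprints chunk the gated stream into consecutive, non-overlapping
runs of `chunk_size` = 1000 events; `floor(N/1000)` vectors per sample,
trailing remainder discarded.  The 1000-event choice tracks a worst-case
Wald confidence-interval argument for estimating distributional
proportions to a few percent (`wald_sample_size(0.03, 0.95)` = 1068; 1000
is the round design value).  Each vector is the channel-block
concatenation [FSC | SSC | AmCyan], events in acquisition order within a
block.  Two documented variants are off by default: per-channel ascending
sorting within blocks (makes the fingerprint permutation-invariant) and
random-draw chunking.  A distribution-statistics featurizer
(mean/SD/percentiles per channel) is provided as an optional extra, not
used by the pipeline.

Label clubbing maps carbon-source labels onto the four putative
anaerobic-digestion groups: CELL→HYDRO, GLUC→ACIDO, PROP/BUTY→ACETO,
ACET/SLUD/BLAN/NONE→METHA.

The 75/25 train/test split is stratified per label (training count =
round-half-up of fraction × n; 1500 → 1125/375) and splits by *vector*.
Vectors of one replicate are correlated, so a replicate-aware split
(`by_replicate=True`) that keeps all vectors of a (label, replicate)
together is provided for leakage-controlled evaluation; the default
mirrors the simplest protocol.

## Autoencoder anomaly screen

One hidden layer (default 2000 units, tanh), linear output, trained with
Adam (learning rate 1e−3, batch 32, 10 epochs) to minimize reconstruction
MSE.  Inputs are standardized per feature on the training set and
identically at scoring; this makes MSE thresholds scale-free, which
matters because raw cytometry intensities span decades.  The score of a
vector is the per-coordinate mean ‖x − x′‖²/d (the raw squared norm is
available via `per_coordinate_mean=False`); the score of a sample is the
mean over its vectors (median and max exposed).  A sample is an outlier
iff its score is *strictly* above the threshold.  Thresholds do not
transfer between experiments or scalings, so the default policy derives
one from the data: the 95th percentile of training-sample scores, which
by construction flags ≈5% of reference samples.  Training is plain
single-threaded numpy, hence bit-reproducible for a fixed seed, and
checkpoints (npz of weights + scaler) round-trip scores exactly.

## Supervised models

All four algorithms share one contract (train / predict_proba /
accuracy), with class order fixed lexicographically.  Defaults:

| model | configuration |
|---|---|
| GB  | gradient boosting, 200 trees, depth 5, learning rate 0.1, multinomial deviance |
| DRF | random forest, 200 trees, depth 20 |
| NB  | Gaussian naive Bayes, variance floor 1e−9 × max feature variance |
| DL  | feed-forward net 2000/1000/500, rectifier with dropout (input 0.1; hidden 0.2/0.2/0.1), both L1 and L2 at 1e−5 (independently switchable), 10 epochs, Adam 1e−3, batch 32 |

GB, DRF and NB are scikit-learn estimators; the DL network is implemented
in numpy (softmax / cross-entropy, inverted dropout, per-feature input
standardization) so that its weight matrices are directly inspectable for
variable importance.  Per-class accuracy is recall of the true class
under argmax; an optional per-class decision threshold reproduces
fixed-threshold recall.

Nested cross-validation: stratified 4-fold outer / 3-fold inner.  The
inner loop picks, per outer partition, the grid point with the best
inner-CV mean accuracy; each selection is scored once on its disjoint
outer fold; the final choice is the grid point with the best mean
outer-fold accuracy, ties broken by smaller outer SD, then grid order.
The shipped default grids are editable config — they are a stand-in, not
a canonical search space.  A stratified 5-fold run (`kfold_stability`)
serves as an overfitting check.

## Evaluation

One-vs-all ROC per class: thresholds swept over the unique predicted
probabilities (plus a sentinel), AUC by trapezoidal integration, which
equals the Mann–Whitney pair-ordering probability with ties counted ½
(asserted against an independent pair-counting oracle in the tests).
Only the four per-class AUCs are reported; no macro/micro averaging.
Gedeon importance propagates absolute weight magnitudes through the first
two layers: score_i = Σ_j (|w1_ij|/Σ_i′|w1_i′j|) · Σ_k (|w2_jk|/Σ_j′|w2_j′k|),
normalized to max 1, then summed within the three channel blocks.  All
plots are emitted alongside CSVs of the same numbers, so nothing is ever
read back from pixels.

## Synthetic studies

Each class draws events from a mixture of truncated-at-zero Gaussians
(negative draws resampled) in the raw intensity scale, with an additive
per-day mean drift; per-sample seeds derive deterministically from
(study seed, class, replicate, timepoint).  The default design is the
full study geometry — 3 replicates × 5 time points × 100,000 events per
sample — and the default four classes (CELL/GLUC/PROP/ACET, two
components each, between-class gaps ≥ 5 pooled SD in at least one
channel) are separable by construction.  Anomaly classes are built by
shifting a base class's component means.

What this emulates: per-class multimodal location/scale/weight structure,
replicate/time-point provenance, and anomalous classes far from the
training manifold.  What it does not: optics and spillover, log-amplifier
artifacts, doublet formation, within-replicate autocorrelation beyond
mean drift, and realistic class overlap.  Passing tests therefore
demonstrate the *machinery* (bookkeeping, learning, ranking, thresholds)
— near-perfect accuracies and AUCs on separable synthetic classes say
nothing about accuracy on instrument data, where class overlap is the
norm.

## Problem sizes and numerics

Test and acceptance runs scale the study down, keeping its geometry:
bookkeeping checks run at the full 100,000 events/sample; the model
comparison uses 5,000 events/sample (75 vectors per class) with reduced
capacities (GB 30 trees/depth 3, DRF 60 trees, DL 300/150/80 at 5
epochs); the anomaly study uses 3,000 events/sample with a 200-unit
autoencoder.  These sizes are the package's chosen desk-scale defaults
for its own verification; the full-size configuration is the generator's
default.  The chance-behavior control permutes the labels of a complete
dataset copy *before* splitting: with separable clusters, permuting only
the training labels quantizes test accuracy to multiples of 1/K via
cluster-plurality learning, whereas permuting the whole copy yields the
intended concentration at chance (≈25% for four balanced classes).

Degenerate inputs: empty event matrices vectorize to zero vectors;
zero-variance features get unit scale in standardization and a variance
floor in NB; constant scores yield AUC 0.5; a score exactly at the
anomaly threshold is not an outlier.

## Known limitations

Published accuracies/AUCs from instrument data (e.g. overall accuracies
in the 53–71% range) are not reproducible from synthetic studies and are
not targeted; reproducing them requires the original deposited FCS data.
The fixed-threshold per-class accuracy variant cannot be pinned to any
published numbers because those thresholds were never printed.  FCS
support covers list-mode 3.0/3.1 with datatype F/D — integer datatypes,
multi-dataset files and analysis segments are out of scope.
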