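# Methods

## Problem setting

Binary classification of subjects (ADHD vs typically developing) from an
anatomical T1 volume plus five clinical covariates, in the ADHD-200 data
dialect. The pipeline's central idea is dimensionality reduction before
learning: a frozen 2D backbone compresses each volume to a 200 × 20
feature map, and small classifiers are trained on the maps, not the
voxels. This keeps training tractable on a single CPU and makes every
intermediate artifact (slab, map, activation overlay) inspectable.

## Demographic preprocessing

Rows are excluded only when *both* site QC flags are 0; a missing flag
counts as questionable only when the other flag is also 0 or missing
(rationale: the exclusion rule names the double-zero case, and a single
passing flag is positive evidence). Unparseable QC values exclude the row
outright. Validation then requires the diagnostic code in {0, 1, 2, 3}
and age, gender, handedness, Full4 IQ present and within configurable
windows — defaults age (0, 30] years, IQ (40, 200), gender {0, 1},
handedness [-2, 3]; the source tables never publish legal ranges, so
these are deliberately generous paediatric-cohort choices. The LD_OR_ODD
flag is 1 iff a vocabulary term ("LD", "ODD", "learning disorder",
"oppositional defiant") occurs as whole tokens, case-insensitively, in
the free-text secondary diagnoses. Labels binarise 0 → 0 and any subtype
1/2/3 → 1.

Min–max scaling of the continuous attributes to [0, 1] is **fit on the
training subjects of each fold only** and clipped on held-out subjects.
Fitting on the full cohort would leak test-set statistics into training;
this is a deliberate deviation from protocols that normalise everything
once up front. A constant attribute maps to 0 with a warning.

## Slab standardisation

Target geometry is 200 slices × 224 × 224 × 3. The slice axis is the
inferior–superior axis read from the NIfTI affine (fallback: axis 0 with
a warning). Volumes with more than 200 slices keep the contiguous central
window starting at ⌊(native − 200)/2⌋; volumes with fewer get zero-valued
slices padded symmetrically, the extra slice of an odd deficit at the
back ("equal number front and back" is impossible for odd deficits).
Resizing is bilinear with a Gaussian anti-alias prefilter when
downscaling; the implementation resizes the non-blank band of the volume
in one vectorised call with zero smoothing along the slice axis, so
padding stays exactly zero and no intensity crosses slice boundaries.
Intensities are divided by the per-volume maximum (switchable off); no
intensity normalisation is prescribed by the protocol this mirrors, so it
is an explicit design choice. Channel replication copies the grayscale
values onto three identical channels.

## Feature extraction

The extractor is a pure function of its spec: truncated convolutional
stack → global average pooling → fixed linear projection to 20 features.
Pooling before the projection avoids a ~25k-dimensional flatten and makes
the contract independent of the conv stack's spatial output size. The
projection is a seeded random linear map with no nonlinearity and is
never trained: freezing it keeps feature maps reproducible bit for bit
(the extractor fingerprint — a hash of all effective weights — rides
along in every saved map's sidecar). Whether a trained projection would
help is an open question deliberately left out of scope; nothing
downstream depends on it.

Two weight sources implement one contract. The `random` backbone is a
small bias-free seeded conv stack (3→8 stride-2, pool, 8→16 stride-2;
ReLU) — bias-free so blank slices map to exactly zero activation, which
in turn makes all padded rows of a feature map identical (the testable
trace of the padding scheme). The `pretrained` source consumes a local
`.npz` of conv kernels (e.g. exported VGG-style ImageNet weights); no
test or example requires such a file.

Random convolutional features are a well-understood baseline: they
preserve coarse spatial intensity structure, which suffices for the
phantom studies here. On real MRI, pretrained features would be expected
to matter; passing phantom tests therefore validates the plumbing and the
protocol, not clinical performance.

## Activation mapping

The map is the channel mean of the last convolutional activation,
bilinearly upsampled and min–max normalised to [0, 1]. A constant
activation has no contrast; 0/0 is resolved by convention to an all-zero
map, which is also what blank padded slices produce. Overlays blend a
perceptually uniform colormap (viridis, configurable) onto the grayscale
slice with weight α.

## Classifiers

All four architectures consume the same (200, 20) map and emit one
sigmoid probability; layer widths are configurable and deliberately
small. Defaults: CNN2D — two 3×3 conv blocks (16, 32 filters) with 2×2
max pooling; CNN1D — two kernel-5 conv blocks (32, 64 filters) with
pooling, features as channels; LSTM/GRU — one 64-unit recurrent layer
reading slices inferior → superior, final hidden state retained (the
LSTM's forget-gate bias starts at 1 to keep gradients alive over 200
steps). Every trunk feeds a dense head (default 64 units, ReLU, dropout
0.2); with covariate fusion the 5 attributes are concatenated to the
first dense layer's input, adding exactly 5 × width weights. All weights
carry an L2 penalty (default 0.01); biases are exempt. Classification
threshold is 0.5.

The layers run on an in-repo numpy library (im2col convolutions, manual
BPTT for the recurrences, Adam with bias correction). Every backward pass
is verified against central finite differences in the test suite.

## Training and evaluation protocol

Class balance first: the majority class is down-sampled uniformly
(seeded) to the minority count. Stratified, shuffled k-fold (default 10)
then partitions the balanced cohort; every subject is tested exactly
once. Early stopping monitors validation *accuracy* with patience 10 over
at most 100 epochs and restores the best epoch's weights; the validation
set is an inner stratified 10% carve-out of the training fold (clamped to
at least one subject per class), never the test fold — using the test
fold would leak. Batch size 8, Adam at 10⁻³, binary cross-entropy.

Feature maps are z-scored per feature column with statistics fit on the
training fold only: a frozen backbone emits features of arbitrary (small)
scale, and standardisation is what makes the small networks trainable in
tens of epochs. Covariate scaling is refit per fold the same way. Three
named seeds (downsample, split, train) are recorded in every artifact.

Metrics per fold: accuracy, precision, recall, F1 at threshold 0.5, and
rank-based AUC with tie correction. Degenerate denominators (no predicted
or no true positives) yield 0 with a logged warning; a single-class test
fold leaves AUC missing and it is excluded from the mean. Reporting
writes per-fold and summary CSVs, a mean-metric heatmap over
(architecture, covariate-mode) pairs, and a per-fold AUC plot for the
best model.

## Synthetic cohorts

A phantom is a bright ellipsoid (semi-axes ≈ 0.84/0.80/0.74 of the half-
volume) with a smooth radial gradient over a zero background, per-subject
anatomy jitter (±3% on the semi-axes), Gaussian noise inside the brain
mask, and — for diseased subjects — an intensity increase of 0.05 ×
`effect_size` in a fixed anterior ellipsoidal subregion, echoing the
prefrontal involvement that motivates slice-based ADHD work. Native slice
counts vary per subject over {native − jitter, native, native + jitter}
(default jitter 60) so both the padding and the cropping branch of slab
standardisation occur in one cohort. The phenotype CSV mirrors the
ADHD-200 dialect, with covariates of diseased subjects shifted (IQ down
6 × `covariate_effect`, age up 1 ×) and a configurable fraction of rows
corrupted round-robin (double-zero QC, out-of-range label, missing IQ).

What the phantoms do **not** model: tissue classes, scanner/site effects,
registration error, motion, or functional time series. Passing tests on
phantoms demonstrates that the pipeline is correct and that the protocol
recovers a localized anatomical effect; it says nothing about accuracy on
clinical data.

## Study conditions used by the tests and the acceptance script

Desk-scale sizes, chosen once as this package's conditions: shape checks
use native slice counts in 140–260 and in-plane matrices 160–256; the
padding trace uses a 150-slice volume (pads 25/25). Null calibration runs
20 cross-validations on effect-free cohorts (10 per class, 40 ± 10 native
slices at 64 px, `effect_size` 0, `covariate_effect` 0) with a small
CNN1D — mean AUC must sit within 3 standard errors of 0.5. Signal
recovery uses 30 subjects per class at the standard geometry (200 ± 60
native slices, 96 px in-plane), `effect_size` 10, `noise_sd` 0.02, and
the full protocol (≤ 100 epochs, patience 10, 10 folds); the best
architecture's mean AUC is the reported quantity. In-plane resolution and
classifier widths are scaled down relative to a full study purely to keep
single-CPU runtimes short; slice-count geometry follows the standard
draw, since slice thickness variation is part of the condition being
tested.

## Known limitations

- The recurrent models (LSTM/GRU) train on 200-step sequences from only
  ~50 subjects per fold at desk scale; they are wired and gradient-checked
  but usually trail the convolutional models under these conditions, and
  chance-level recurrent results on tiny phantom cohorts are expected.
- The `pretrained` backbone path is exercised with a synthetic stand-in
  weights file in tests; real exported weights change numbers, not
  contracts.
- Subject counts from any particular public release are not reproduced;
  the balancing rule (equalize to the minority count) is implemented as
  stated and reports its own counts.
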