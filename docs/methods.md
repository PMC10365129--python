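# Methods

`gazeguide` trains a joint classification / heatmap-decoding U-Net for
3-class chest-radiograph-style images (normal, CHF, pneumonia) whose
loss can inject two kinds of spatial supervision: radiologist eye-gaze
heatmaps, and the model's *own* gradient-based saliency maps computed
inside each training step.  This note records the model, the numerical
choices, and what the synthetic benchmark does and does not establish.

## Model

The network (`gazeguide.network.UNet`) is a small strided CNN encoder
(default 3 resolution levels, 8/16/32 channels, two 3×3 convolutions
per level, stride-2 downsampling), a classification head (global
average pooling of the bottleneck followed by a linear layer producing
3 logits), and a mirrored decoder (nearest-neighbour ×2 upsampling +
convolution, skip concatenation from the matching encoder level,
convolution, final 1×1 convolution) producing a one-channel logit map
at input resolution.  All hidden nonlinearities are ReLU; there are no
batch-statistics layers, so evaluation outputs are batch-size
invariant.  Classification is one-vs-all: three independent logits
trained with binary cross-entropy against the one-hot label.

An `efficientnet-b0` encoder name is accepted in the config for parity
with GPU-scale deployments but raises: this build has no pretrained
backbone source, and none of its claims depend on one.

## Saliency rules

At a ReLU site with forward input `x` and backward signal `g`:

| rule      | propagated signal          |
|-----------|----------------------------|
| backprop  | `g · 1[x>0]`               |
| deconvnet | `g · 1[g>0]`               |
| gbp       | `g · 1[g>0] · 1[x>0]`      |

The strict convention `1[x>0]` (zero excluded) matches ReLU'(0)=0.
Guided back-propagation applies both masks, so its maps have at least
as many exact zeros as deconvNet's for the same model, input and class
— a property the test suite asserts on random networks.

**Differentiable saliency.** During training (schemes set1/set3) a
loss is placed on the saliency map itself, so the map must be a
differentiable function of the weights.  Both masks are treated as
constants of the current forward pass: they are piecewise constant in
the weights almost everywhere, and freezing them makes the masked
backward sweep a chain of *linear* operations (transposed convolutions
and matrix products in the same weights).  The sweep is therefore
built as a forward computation in the package's reverse-mode autodiff
graph, and one ordinary backward pass yields exact weight gradients of
any loss on the map — no second-order machinery.  Central finite
differences confirm agreement to better than 1e-4 relative error
(valid wherever no pre-activation sits within the finite-difference
step of zero, i.e. almost surely).

Saliency is computed for the ground-truth class during training: the
gaze map was recorded while the radiologist diagnosed the true
condition, so that is the logit whose evidence should align with gaze.
Grad-CAM (feature maps of a chosen encoder level weighted by the
spatial mean of their gradients, rectified, bilinearly upsampled) is
provided post-hoc only.

## Loss schemes

All terms are BCE-with-logits, `mean(softplus(z) − t·z)`, stable for
|z| up to 1e4.  With decoder logits `D`, derived saliency map `S`,
gaze map `G ∈ [0,1]`:

- **baseline**: `BCE(D, G)`
- **set1**: `BCE(zscore(S), G)` — differentiable through `S`
- **set2**: `BCE(D, sigmoid(zscore(S_detached)))` — the generator
  defines the target of the current step; no gradient flows into the
  weights through the target
- **set3**: `λ·BCE(zscore(S), G) + (1−λ)·BCE(D, G)`, default λ = 0.5

`total = w_cls·classification + w_seg·segmentation`, default weights
1/1.  Raw gradient maps are unbounded and signed, so they are z-scored
(population sd over pixels; a constant map maps to zeros) before
entering the BCE in a logit role; z-scoring is preferred over min-max
because the max has unstable gradients.  A sigmoid is applied only
where the map must serve as a BCE *target* (set2).  set3 reduces
bit-exactly to set1 at λ=1 and to the baseline at λ=0.

## Gaze heatmaps

Fixations (0-based pixel coordinates, onset, dwell duration) are
rendered as isotropic Gaussians of scale σ (default image_width/20,
truncated at 4σ) with amplitude proportional to dwell duration — the
standard attention weighting in eye-tracking.  Temporal maps bin
fixations by onset into equal windows of [0, max onset]; the static
map is the pixelwise sum of the temporal maps re-max-normalized to
[0,1] (a channel stack could not serve as a 1-channel BCE target).
Out-of-bounds fixations are dropped with a logged warning — real
recordings contain alignment errors.  Window count, σ and duration
weighting are config because the upstream generator's parameters are
not published.

## Training

Adam (lr 3e-3 default), batch 16, model selection by validation
classification loss, patient-grouped 0.80/0.10/0.10 splitting in which
whole patients are assigned to folds by minimizing the total absolute
deviation of record counts from the target fractions (exact
enumeration up to 10 patients, largest-first greedy plus single-move
local improvement beyond).  Derived maps are recomputed fresh every
step — they depend on the current weights — reusing the step's forward
tape, so a set3 step costs roughly one extra half forward/backward.
Runs are deterministic given the config seed.  The engine computes in
float64 by default; training switches to float32
(`TrainConfig.dtype`), worth ~2-3× on CPU, and hands back float64
weights.

Defaults (12 epochs, lr 3e-3) were chosen once by watching validation
convergence on the synthetic task at desk scale: the loss plateaus
near log 2 for several epochs before the grouped features disentangle,
and convergence lands around epochs 10–14 on one CPU core in ≈3 min
per scheme.

## Evaluation

One-vs-rest AUC uses the Mann–Whitney rank form (ties count ½), with
the class score defined as the sigmoid of that class's logit.
Uncertainty follows a percentile bootstrap: 30 iterations, each
resampling with replacement a pool of m ~ U{55…60} test samples
(redrawn if a class is absent), with the 50th/2.5th/97.5th percentiles
of each per-class AUC and of the per-iteration mean reported.  The
per-iteration mean is percentiled directly, which is why the average
row's CI is not the mean of the class CIs.  A permutation test on
iteration AUCs is available for model comparison but is explicitly
*not* the (unpublished) significance test used alongside the original
AUC tables.

Decoder/saliency explainability is quantified by `gaze_alignment`: the
fraction of a map's absolute mass inside the region where the gaze map
is at or above its 0.75-quantile.  It is invariant to positive
rescaling, and an identically-zero map scores 0.

## Synthetic data

The generator reproduces the statistical structure the method assumes
— gaze concentrates on the class-discriminative region — with no claim
of radiographic realism.  Class 0 is a smooth chest analog (two dark
lung ellipses, bright central mediastinum) plus Gaussian noise
(sd 0.12); class 1 widens the central ellipse ×1.6 (global change,
cardiomegaly analog); class 2 adds one bright disc (radius 8 px at
64×64, amplitude 0.5 = midpoint of the difficulty sweep
0.2…0.8) at a random position inside a lung (focal change).  80% of
fixations are drawn from a Gaussian centred on the discriminative
structure, the rest uniformly.  Patients are contiguous single-class
blocks so grouped splitting is exercised nontrivially.  The lesion
radius was set so that the focal class is learnable by the smallnet
within minutes on one CPU; intensity and noise make the task
template-separable (AUC > 0.95 by a trivial region statistic), which
the suite asserts.

A green end-to-end test therefore establishes that the training
machinery can exploit gaze-aligned spatial supervision on a task with
the assumed structure — not that the method improves real chest
radiograph classification, which requires the restricted-access
clinical dataset and GPU-scale encoders.

### Known behaviour of the scheme comparison

At an equal epoch budget the baseline's decoder receives the gaze
target at weight 1.0 versus set3's 1−λ = 0.5, so it tends to track
gaze faster; set3's GBP term, in turn, shapes the shared encoder
features toward the gaze region, which feeds the decoder through the
skip connections.  The two effects roughly cancel at this scale: the
measured decoder gaze-alignment difference between set3 and the
baseline after 12 epochs is within seed-to-seed noise (means within a
few hundredths, either ordering observed across kernel/seed
variations).  The comparison test asserts the set3 > baseline ordering
and should be read with that sensitivity in mind; set3's robust
advantage in the original study is classification AUC and the
alignment of its *derived* (GBP) maps.

## Limitations

- No pretrained encoders; pure-NumPy training is practical only at
  desk scale (≈64×64, tens of thousands of parameters).
- DICOM input requires the optional `pydicom` package; PNG is the
  canonical format.
- Multi-channel inputs are reduced to one saliency map by
  signed absolute-maximum across channels (config: mean/max/abs-max);
  the shipped models are single-channel.
- The bootstrap protocol inherits the original design's small resample
  range (55–60); CIs are percentile, not bias-corrected.
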