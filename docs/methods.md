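# Methods

## Problem setting

A compact lesion at position (y, x) in a 2D breast image appears in the
parallel-beam sinogram as a band around the curve
t(θ) = c + (x − c_x)·cos θ − (y − c_y)·sin θ, whose width at each angle is
the lesion's chord length along that ray. Segmenting this band directly in
the projection domain and backprojecting the segmented band localizes the
lesion without ever reconstructing the image. The package implements that
pipeline end to end on synthetic data: phantom generation → sinogram pairs →
U-Net segmentation → filtered backprojection (FBP) → centroid metrics.

## Acquisition geometry

All sinograms use a limited tomosynthesis-style arc of −25° … +25° in 2.5°
increments (21 projections), the regime in which reconstruction is most
artifact-prone and direct projection-domain analysis is most attractive.
The Radon transform and FBP are delegated to scikit-image
(`radon`/`iradon`, `circle=False` so mass outside the inscribed circle is
kept; linear interpolation). Geometry conventions (0-based row/col, detector
rows = positions t, columns = angles; pixel centers at integer coordinates)
are fixed by the tests against brute-force line-integral oracles.
Mass conservation of the transform holds to ~1e-4 relative on smooth
phantoms; isolated single-pixel impulses show up to ~20% column-sum
wobble, which is the expected phase-dependent error of sampling a bilinear
interpolant's projection on a unit detector grid — tolerances in the tests
distinguish these two regimes rather than pretending the spike case is
exact.

## Synthetic phantoms

Each phantom is an elliptical breast support (≥ 30% of the frame) filled
with a smooth intensity dome plus band-limited Gaussian texture (σ ≈
size/16, amplitude 0.05). Lesions are hyperintense ellipses (semi-axes
~2.5–13 px at 256², contrast 0.25–0.45) with an optional radial harmonic
boundary perturbation (harmonics k = 2–4 only, so the centroid stays on the
nominal center; amplitude ≤ 0.2). The intensity bump peaks at the lesion
center and falls smoothly to zero at the boundary. The DBT mode rescales
contrast by 0.6 and adds N(0, 0.03) pixel noise, emulating the lower
conspicuity and higher noise of tomosynthesis slices; the modality mix
defaults to 20% DBT, roughly the composition of the annotated clinical
cohorts this generator stands in for. Every sample derives its RNG stream
from (dataset seed, patient index, image index), so datasets are bytewise
reproducible and stable under reordering.

What the phantoms deliberately do not model: anatomical parenchyma
patterns, microcalcification clusters, hypointense lesions, detector
physics, scatter, or volumetric DBT stacks. Passing tests therefore show
that the *pipeline mathematics* works under controlled conditions — they
are not evidence of clinical-grade performance.

## Sinogram pairs and lesion-focused extraction

The image sinogram is min–max normalized to [0, 1]. The mask sinogram is
the Radon transform of the binary lesion mask, binarized at 50% of its own
maximum — the "core trace": a ray counts as crossing the lesion when its
intersection length is at least half the longest chord. The threshold is
configurable, and the choice matters more than it looks. A permissive rule
(a few % of max) produces targets so wide that a slope-less horizontal band
centered in the crop already scores Dice ≈ 0.6; small-data training then
converges to exactly that shortcut, and a slope-less prediction is useless
downstream because the trace *slope* is what encodes the lesion's
y-coordinate — its backprojection smears into a vertical streak with ~30 px
centroid error. The tight core-trace target keeps the per-angle band narrow
so only slope-following predictions score well; under the same recipe and
seed it cut the held-out median centroid error from ~31 px to ~6 px. For
training, both sinograms are cropped to the detector-row band containing
the lesion trace (margin 10 rows), bilinearly resized to 128×128 and
re-normalized (masks re-binarized at 0.5). The band interval and the
original detector count are carried along so predictions can be re-embedded
into full sinogram coordinates before backprojection.

## Network and training recipe

The segmentation network is a standard 4-level U-Net: encoder blocks of
[3×3 conv → batch-norm → ReLU] ×2 with dropout p = 0.2 and 2×2 max-pooling;
a double-conv bottleneck; decoder blocks of [2× upsample → 3×3 conv] with
skip concatenation and a mirrored double conv; 1×1 conv + sigmoid head.
Channel widths double per level from `base_channels`. Upsampling is
nearest-neighbor followed by a convolution by default (exact 2× bilinear is
available); batch-norm appears symmetrically in encoder and decoder.

Because the package targets plain CPU environments, the network and its
backpropagation are written in numpy: 3×3 convolutions use the shift
decomposition (nine pointwise GEMMs accumulated into shifted views), so
nearly all arithmetic runs in BLAS. Every layer's backward pass is
finite-difference checked in float64; end-to-end gradient checks use a
looser tolerance only because ReLU/max-pool kinks make finite differences
themselves inexact.

Optimization follows a fixed recipe: Adam, lr 1e-4, L2 weight decay 1e-6,
batch size 16, no schedule, no early stopping; the checkpoint with the
highest validation Dice (on thresholded predictions, threshold 0.5) is
retained. The loss is `BCE + (1 − soft Dice)` with BCE clamping eps 1e-7
and Dice eps 1e-5. Augmentation applies, each with probability 0.5 per
sample: joint rotation uniform in ±15°, joint horizontal flip, and
Gaussian noise (σ 0.02) on the image only; masks are re-binarized after
interpolation. Splits are by patient (default 70/15/15), never by image,
and the training loop is a pure function of its seed.

## FBP verification and binarization

Predicted sinogram masks are resized back to their detector band, embedded
into a zero full-height sinogram, ramp-filtered and backprojected. The
reconstruction is clamped at zero, smoothed with a Gaussian (σ 2 px) and
thresholded at 0.5 of its maximum (Otsu optional). The smoothing step
matters: backprojecting *binarized* (flat) bands under a 50° arc produces
streak-crossing speckle — with two lesions per image the crossing points
can out-shine the lesions themselves, fragmenting the thresholded mask. A
2 px smoothing consolidates the energy; on ground-truth mask sinograms it
brings the median centroid error of the full crop→resize→embed→FBP
roundtrip from ~8 px down to ~2 px at 256², without inflating single-lesion
cases. Output scaling follows scikit-image's iradon convention; all
downstream use is relative-threshold binarization, so the global scale is
immaterial.

## Metrics

Dice uses the (2|P∩G| + ε)/(|P| + |G| + ε) form with ε = 1e-5; IoU is
|P∩G|/|P∪G| with the empty-union convention IoU = 1. The identity
IoU = Dice/(2 − Dice) is exact whenever both are computed from the same
counts with ε = 0 (verified by exhaustive enumeration of all 3×3 mask
pairs); it does *not* commute with averaging, so converting a mean Dice is
not the same as averaging per-sample IoUs. Centroids are means of 0-based
nonzero pixel coordinates; an empty mask raises rather than returning a
silent origin. The location match is max(0, 100·(1 − d/D)) with D the
image diagonal; the evaluation-image size defaults to 224×224. Cropped IoU
restricts scoring to the ground-truth lesion's bounding box plus a margin
(default 10 px). Multi-lesion images are scored per ground-truth lesion
(8-connected components); predicted components are assigned one-to-one by
minimum-total-centroid-distance (optimal assignment, which coincides with
exhaustive enumeration at these sizes); surplus ground-truth lesions are
reported as unmatched with overlap 0 rather than silently dropped.

## Problem sizes used in the test suite

The self-contained recovery experiment trains the default recipe on 60
synthetic patients (2 images each, 70/15/15 patient split, 128×128 model
inputs) with `base_channels` 12, bilinear decoder upsampling and 40
epochs, then checks held-out sinogram Dice and post-FBP median centroid
error at 224×224. These sizes are the package's own desk-scale choice:
wide enough for the U-Net to leave the "predict a fat central band"
shortcut and follow lesion traces, small enough that the whole suite runs
on one CPU core in tens of minutes. At this scale the held-out sinogram
Dice reaches ≈ 0.65 and the median centroid error ≈ 6 px; the remaining
localization error is dominated by slope noise in the predicted traces
(under a ±25° arc the lesion's y-coordinate is encoded only in the trace
slope, so the error ellipse is elongated along y). The oracle-path floor
of the same pipeline is ≈ 2 px — closing the gap is a matter of
segmentation quality, i.e. training scale, not of the reconstruction or
metric stages. The 8-sample overfit run (batch 2, lr 1e-3, 200 epochs,
64×64 inputs, augmentation off, train Dice measured in eval mode) guards
the wiring of model, loss, and optimizer.

## Known limitations

* Phantom realism is intentionally minimal (see above); absolute Dice
  values on phantoms do not transfer to clinical data.
* The numpy backend is single-threaded BLAS; training wall-clock scales
  quadratically with `base_channels`.
* Precision/recall approximations from Dice are not implemented — no
  standard formula exists without extra assumptions.
* Bitwise reproducibility holds for a fixed BLAS; different SIMD kernels
  may reorder floating-point sums and shift late-training trajectories
  slightly, which is why acceptance thresholds carry margin.
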