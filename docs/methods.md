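# Methods

This note records the models implemented in `dermafusion`, the
parameter choices that matter, what the synthetic data does and does
not establish, and the numerically delicate decisions.

## Enhancement

The fused enhancement stage is a k×k average (box) filter followed by
CLAHE, in that order.

* **Box filter** (`kernel_size`, default 5 → a 25-pixel
  neighborhood): replicate padding at borders. Zero padding would
  darken borders, which CLAHE would then amplify into a halo.
  Output is float64; quantization happens once, at the end of
  `enhance`.
* **CLAHE** (`clahe_tile`, default 8 tiles per side; `clahe_clip`,
  default 2.0): delegated to scikit-image's
  `equalize_adapthist`. Our clip parameter follows the OpenCV
  convention (multiple of the uniform histogram bin height) and maps
  to scikit-image's [0, 1] fraction as `clip / 256`. On RGB images
  only the YCbCr luminance channel is equalized — per-channel
  equalization shifts hue, which matters for lesions whose class
  signal is largely chromatic. Note that for small tiles (fewer
  pixels per tile than histogram bins) the clip limit cannot bind
  and CLAHE degenerates to per-tile full equalization; tests that
  reason about noise amplification therefore use tiles of ≥ 32×32
  pixels.

## Segmentation

* **Edge map**: f = |∇(G_σ ∗ I)|² on the grayscale (standard
  luminance weights) image, normalized to peak 1. The sign
  convention is "non-negative magnitude"; the snake descends its
  negative. σ defaults to 2 px.
* **GVF**: the Xu–Prince diffusion
  u_t = μ∇²u − (u − f_x)(f_x² + f_y²), explicit Euler with 5-point
  Neumann Laplacian. μ defaults to 0.2 (higher μ = smoother field,
  appropriate for noisier edges). The step defaults to
  0.95/(4μ + max b), which satisfies both the diffusion CFL bound
  dt ≤ 1/(4μ) and the reaction-term bound. Convergence is declared
  when the largest per-step update falls below `tol` (default 1e-6);
  otherwise the final stationarity residual is reported on the
  returned field. The default 800 iterations give the field a
  capture range of roughly √(4·μ·iters) ≈ 25 px, enough for the
  default initialization on ≤ 224 px frames. A direct sparse solve
  of the same discretized stationarity system (`gvf_direct_solve`)
  serves as the oracle on small grids.
* **Snake**: semi-implicit step x ← (I + γA)⁻¹(x + γκF(x)) with the
  periodic pentadiagonal internal-energy operator A built from
  tension α (default 0.1) and rigidity β (default 0.1); γ = 1,
  κ = 2. The external force is bilinearly interpolated from the GVF
  field and normalized to unit vectors, so capture range does not
  depend on edge strength. The contour is resampled to 2 px
  arc-length spacing every 10 iterations; initialization is a
  centered circle of radius 0.45·min(H, W). 300 iterations default.
  Collapse (fewer than 3 points, or zero extent) raises rather than
  returning an empty mask.
* **Coordinates**: 0-based row-major, origin top-left; bounding
  boxes half-open.

## Feature extraction

Convolution is implemented as valid cross-correlation (no kernel
flip) with explicit stride and zero padding — the deep-learning
convention. Pooling takes the max or mean of fully contained k×k
windows; global average pooling is the per-channel spatial mean.

The backbone registry records the declared feature-map geometries and
GAP vector lengths for DenseNet121 (1024), MobileNet (1024) and VGG19
(4096). The recorded map shapes are metadata only — they are not all
mutually consistent with the canonical architectures, and the adapter
abstraction absorbs that: what the pipeline relies on is the vector
length. Each backbone has a **toy adapter**: a fixed He-initialized,
seeded stack (4×4/stride-4 conv → ReLU → pools → 3×3 conv → ReLU)
with 1×1 projection heads at two scales whose GAP vectors concatenate
to the declared width (a quarter from the early stage, the rest from
the deep stage). The two scales make the features sensitive to both
local texture and global color, which is what separates the synthetic
classes. Toy adapters are deterministic functions of (backbone name,
seed) and require no downloads; `EXTERNAL_ADAPTERS` lets users plug
in real pretrained models without any package change. Inputs are
resized to 224×224 before extraction.

## t-SNE reduction

Exact (non-accelerated) t-SNE: tree-based gradients only help for 2–3
output dimensions, far below the registry targets (724/694/921).

* Per-point bandwidths by bisection on β = 1/(2σ²) until the
  conditional entropy equals log(perplexity) within 1e-3;
  conditionals symmetrized and normalized (P symmetric, zero
  diagonal, sums to 1 within 1e-9).
* Gradient descent on KL(P‖Q) with learning rate 200, momentum
  0.5 → 0.8 at iteration 250, early exaggeration ×12 for the first
  100 of 500 iterations; Q floored at 1e-12. The KL trace (against
  the un-exaggerated P) is recorded; divergence (non-finite
  embedding) raises with the iteration index.
* **Samples vs columns**: "reducing the features" can be read as
  embedding the n samples into d coordinates or as selecting d of
  the original columns. The published matrix shapes (n × 724 etc.)
  are unambiguous only about the embedding reading, so `embed` is
  the default mode; `select` (keep the d highest-variance columns)
  is provided for the other reading. Neither is claimed to be the
  original authors' intent.
* When d ≥ n (desk-scale runs), the embedding is capped at n − 1
  live dimensions — n points span no more — and zero-padded back to
  the registry width so fusion arithmetic still sees the declared
  column counts.
* Perplexity is capped at (n − 1)/3 for small n.

## Dataset arithmetic

Per class of size n: test = round(0.40·n), val = round(0.06·n), both
half-away-from-zero, train = n − test − val. This is the unique
simple rule consistent with every published per-class count,
including the 772.5 → 773 validation half-case and a training cell
where rounding the training fraction directly would be off by one.
Balancing multiplies an n-image training class by (k + 1) — originals
kept, k augmented copies per original — which is the only reading
consistent with every published post-augmentation count. Augmentation
(rotation ±25°, flips, ≥85%-area crop, resize back) happens only on
the training split, after splitting, so no test item can leak.
Augmentation seeds derive deterministically from
(seed, class, original index, copy index).

## Classification heads

* **Random forest**: scikit-learn's bagged trees (100 trees, √p
  features per split, bootstrap on); scores are vote fractions.
* **FFNN**: 15 hidden rectifier layers as published; widths are not
  published and default to a geometric taper from max(p, 128) down
  to the output count with a floor of 16 per layer — very deep,
  very narrow rectifier stacks collapse to dead units, and the floor
  is what makes the published depth trainable. MSE on one-hot
  targets (as published) via a multi-output regressor; a
  cross-entropy switch exists. Adam, learning rate 1e-3, 800
  epochs, inputs standardized with statistics fit on the training
  rows only. Both heads are deterministic given their seed.

## Evaluation

One-vs-rest TP/FP/FN/TN from the K×K confusion matrix; percentages
per the standard formulas. Two published ambiguities are handled by
reporting both candidates rather than guessing:

* The per-class "accuracy" of published tables is not derivable from
  the stated formulas (one-vs-rest accuracy would be far higher for
  rare classes than printed); the report carries both `accuracy`
  (one-vs-rest) and `within_class_accuracy` (diagonal fraction of
  the class row, = sensitivity).
* A ratio definition of AUC (TPR/FPR) is not the area under any
  curve; the report's `auc` column is the standard trapezoidal
  one-vs-rest area (matching the prose definition "area under the
  ROC curve"), and the literal ratio at the max-Youden operating
  point is kept separately as `rate_ratio`.

Zero-denominator metrics are NaN ("undefined"), never raised; macro
means skip NaN entries.

## Synthetic data

The generator emulates what the pipeline needs and nothing more: a
skin-toned background with a soft illumination gradient, one
elliptical lesion per image with a seeded low-order-Fourier radial
boundary perturbation (amplitude = `border_irregularity`; 0 gives an
exact ellipse, keeping area and co-registration analytically
checkable), class-specific lesion color with a gentle zero-mean
texture, additive Gaussian noise, and optional dark Bézier hair
strokes (off by default so segmentation tests are clean). The default
eight class templates differ in color, eccentricity and border
irregularity, with the palette chosen so that inter-class color
distances are well above the per-image jitter (±12 per channel) —
the classes are discriminable *by design*. Noise defaults to σ = 4
(8-bit units), a mild sensor-noise level.

What a green end-to-end test establishes: the stages compose, stay
deterministic under a fixed seed, and preserve enough class signal to
classify an easy dataset. What it does not establish: performance on
real dermoscopy images, which vary in ways this generator does not
model (hair density, rulers and gel artifacts, multi-lobed lesions,
illumination color casts, class-overlapping morphologies).

Gaussian feature blobs follow the scikit-learn `class_sep`
convention: unit within-class standard deviation, class means at
`class_sep` times coordinate-axis vertices (pairwise distance
`class_sep·√2`).

## Pipeline

Stage seeds derive from the global seed by hashing the stage name
(CRC-32), so stages can be re-run in isolation. Reduction runs on
the full dataset before splitting — the t-SNE embedding is
transductive, and this matches the published order of operations —
so the class-balancing stage operates on feature rows: an augmented
"copy" is the original reduced feature vector plus seeded Gaussian
jitter of 0.05 column standard deviations (a desk-scale stand-in for
image-space augmentation; with the balanced synthetic datasets the
default plan adds no copies). Pipeline runs on 128×128 synthetic
frames by default to keep a full eight-class run around three
minutes on one CPU.

## Known limitations

* The GVF snake assumes a single, roughly centered lesion; it is not
  a multi-instance segmenter.
* The toy backbones are random-projection features, good enough to
  separate the synthetic classes but in no way a substitute for
  pretrained networks on real images.
* Exact t-SNE is O(n²) in memory and time; it is meant for
  desk-scale n, not the full 25k-image archive.
* The FFNN head at its published depth trains reliably only with the
  width floor described above; narrower overrides may not converge.
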