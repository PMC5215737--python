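# Methods

This note documents the models and procedures implemented in `flairseg`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic validation does and does not show.

## Problem setting

The segmentation target is the hyperintense region on skull-stripped FLAIR
MRI of glioma patients — edema plus much of the tumor appears as elevated
signal once CSF is suppressed. Inputs are 3-D volumes in NIfTI-1; array
axes are (x, y, z) as stored, axial slices are `data[:, :, k]`, voxel
indices are 0-based, and masks are stored as unsigned 8-bit. Two images
are grid-compatible iff shapes match and spacings agree within 1e-5
relative; every (volume, mask) operation enforces this.

## Synthetic phantoms

Because clinical FLAIR with multi-rater annotations cannot ship with a
package, every stage is validated on synthetic phantoms with analytic
ground truth:

* brain: centred ellipsoid with semi-axes 0.42× the grid dimensions,
  baseline tissue signal 100 (arbitrary units); outside-brain voxels are
  exactly 0, as in skull-stripped data;
* lesions: ellipsoids with per-axis radii drawn from
  `lesion_radius_range` (default 4–8 mm), placed fully inside the brain
  with at least one voxel of separation between lesions (so *n* lesions
  are *n* 26-connected components by construction); lesion signal is
  baseline × (1 + `lesion_intensity`), default contrast 0.6 — markedly
  hyperintense, as FLAIR lesions are;
* bias: a multiplicative field exp(random degree-2 polynomial), centred
  and scaled so its peak-to-trough ratio equals `bias_amplitude`
  (default 1.2, a mild but visible inhomogeneity);
* noise: additive Gaussian, SD 4 on the 100 baseline (≈ 4%), applied
  inside the head only, clipped at 0;
* optional residual-skull artifact: a thin bright partial shell just
  outside the brain (1.8× baseline), never part of the truth mask — it
  emulates the skull-stripping failures that dominate false positives in
  practice.

Defaults (20-case cohorts of 64×64×24 voxels at 1 mm³, 1–2 lesions per
case, 75/25 train/test split) are the reference study conditions used by
the test suite and `scripts/acceptance.py`. Generation is a pure function
of (spec, seed); per-case seeds derive from the master seed by a fixed
splitmix64-style mix, so case *i* is reproducible in isolation.

Simulated raters flip each true lesion voxel to 0 with probability
1 − sensitivity and each background brain voxel to 1 with probability
1 − specificity, independently per voxel. This is exactly the generative
model STAPLE assumes, which makes parameter recovery a well-posed test of
the EM implementation; it deliberately omits the boundary-correlated
errors of real raters.

What passing on phantoms does *not* show: robustness to anatomical shape,
partial-volume gradients, multi-focal infiltrative lesions, or non-tumor
hyperintensities (e.g. vascular disease). The phantoms exercise the
machinery, not clinical generality.

## Preprocessing

**Bias correction.** A degree-`order` (default 2) polynomial is fit by
least squares to log-intensities over the brain mask and exponentiated;
the volume is divided by the field. The field is rescaled to mean 1 over
the mask so correction preserves mean brain brightness — note this holds
to first order only: with E[f] = 1, E[v/f] − E[v] carries
Jensen/covariance terms of order var(f) (≈ 3×10⁻⁴ relative at amplitude
1.2), which is the tolerance the tests assert. This is a deliberate
surrogate for full N4: it captures the low-frequency inhomogeneity that
matters here while keeping the package dependency-free; externally
N4-corrected input can be supplied and the built-in correction disabled
(`--bias-order 0`).

**Nyúl standardization.** Landmarks are intensities at percentiles
{1, 10, 20, …, 90, 99} over brain voxels (the foreground is the provided
brain mask — volumes are skull-stripped, so no foreground threshold needs
deriving). Fitting maps each training volume's [p1, p99] linearly onto the
standard range [0, 100] and averages the mapped landmarks across volumes;
application maps a new volume piecewise-linearly through (own landmark →
standard position). Beyond the outer landmarks the terminal segments are
extended linearly rather than clipped — extreme hyperintensities are the
segmentation target and must keep their ordering. The map is monotone
non-decreasing by construction (strictly increasing landmarks are
enforced; ties raise a degenerate-histogram error, which genuinely occurs
on noise-free two-level phantoms). Standardization is idempotent on the
standard scale up to interpolation tolerance. The scale is fit on the
training partition and applied everywhere.

## Segmentation model

Architecture: encoder of 7 convolutions (3×3, stride 1, 'same' zero
padding, ReLU, He initialization) grouped into pooling blocks [2, 2, 3]
with channel widths [16, 32, 64]; each block ends in a 2×2 max-pool that
records argmax indices; the decoder mirrors the encoder block-for-block,
upsampling by scattering values to the recorded indices and convolving
(channel widths stepping back down 64 → 32 → 16); a 1×1 convolution to 2
channels and per-pixel softmax produce the probability image. Seven
convolutions each followed by pooling would collapse a small training
tile, so three pooling stages (downsample ×8) is the deepest hierarchy
compatible with 10×10 tiles; this grouping is a design choice, as are the
filter counts, kernel size, loss and optimizer — none of which are forced
by the architecture concept.

Training: 10×10 ROIs are sampled from axial slices, half centred on
lesion voxels and half on background brain voxels (a deliberate 50/50
class balance; lesion voxels are ~1% of the brain, so unbalanced sampling
would starve the positive class). Cases without lesions cede their quota
to the rest. Tiles are reflect-padded to 16×16 (the next multiple of 8);
the cross-entropy loss counts only the original 10×10 region. Inputs are
z-scored with the training-tile statistics, which are stored on the model
and reapplied at inference. The optimizer is mini-batch SGD with momentum
0.9, learning rate 1e-3, batch 64, 30 epochs; plain first-order SGD with
these small batches needs the momentum term to traverse the plateau of
the early epochs within a 30-epoch budget. Training is deterministic
given the seed (single-threaded BLAS assumed for bit-exactness).

The configured default of 600 000 ROIs reflects full-scale training; the
reference experiment uses 5 000 tiles and 30 epochs — at the phantom's
task difficulty this saturates (training loss falls > 95% and held-out
Dice exceeds 0.9), so desk scale does not bottleneck the validation.

Inference is fully convolutional: each axial slice is reflect-padded to a
multiple of 8, pushed through the network as one batch, cropped back, and
the tumor-channel probabilities are reassembled into a 3-D map. For two
classes, "class with maximum probability" and "P > 0.5" coincide; the
decision is implemented as the threshold so it remains a single tunable.

The layers (convolution via nine shifted BLAS matrix products, pooling
with indices, unpooling, softmax/cross-entropy) are implemented in NumPy
float32 with hand-derived gradients; backpropagation is verified against
central-difference numerical gradients to 1e-7 relative in float64. One
caveat of exact gradient checks at initialization: biases start at 0 and
unpooled feature maps contain all-zero windows, so some pre-activations
sit exactly on the ReLU kink where the subgradient convention (0 at 0)
differs from a finite difference; checks are therefore run at randomized
biases.

## Postprocessing

`binarize` uses a strict inequality (P > threshold, default 0.5); a voxel
at exactly 0.5 is background. `filter_small_components` removes 3-D
connected components of ≤ `min_voxels` voxels (default 10) at
26-connectivity (configurable 6/18/26); components are volumetric even
though inference is slice-wise. The filter is idempotent and only removes
voxels; both properties are asserted against brute-force flood-fill
oracles in the tests.

## STAPLE

Two-class EM as described above. Numerical and design choices:

* prior: global scalar, default the mean foreground fraction across
  raters over the region ("from-raters"); held fixed across iterations,
  so the EM monotonicity guarantee applies to the (p, q) updates;
* initialization p_j = q_j = 0.99999 (near-perfect raters), the standard
  choice;
* E-step in the log domain with logsumexp normalization; M-step clamps
  p, q to [1e-6, 1 − 1e-6] and flags raters whose mask is all-0 or all-1
  over the region as degenerate;
* convergence: max voxel-wise |ΔW| < 1e-7 or 100 iterations;
* analysis region: default the bounding box of the rater union dilated by
  5 voxels. The specificity estimate scales with how much empty
  background is counted, so the region is an explicit, reported parameter
  (pass the brain mask for brain-relative specificities). The consensus
  mask thresholds W at 0.5 (strict).

On the generative model it assumes (the simulated raters), the
implementation recovers sensitivities within ±0.02 and specificities
within ±0.005 of truth with 5 raters on a 48³ phantom, and the consensus
reproduces the true lesion at Dice ≥ 0.98; one test cross-checks the
consensus and sensitivities against SimpleITK's independent STAPLE filter.

## Metrics and comparisons

FPF is defined as FP/|reference| — normalized by the reference lesion
volume, not by the background size — which is why reported maxima can
exceed 1. Empty-vs-empty mask pairs define Dice = Jaccard = 1; an empty
reference makes TPF/FPF/FNF undefined (raised as errors, never silent
0/0). Summaries use sample SD (n−1; 0 for a singleton) and
linear-interpolation quantiles. Since Dice = 2J/(1+J) is strictly
increasing in J, order statistics (median, quartiles, extremes) of Dice
and Jaccard columns must be consistent under the identity; the package
ships a published multi-rater benchmark table and verifies this identity
on it to printing precision (±0.001 after 3-decimal rounding) — a
zero-cost integrity check on any such report, including this package's
own.

Method comparison on paired per-case columns defaults to the two-sided
Wilcoxon signed-rank test (identical columns return p = 1 by convention);
a chi-square mode dichotomizes cases at the pooled median and applies the
Yates-corrected 2×2 test. The chi-square construction for continuous
paired metrics is not uniquely defined, which is precisely why both modes
are provided and labelled.

## Reference experiment scale

The end-to-end validation trains on 15 phantoms and tests on 5 (64×64×24,
5 000 tiles, 30 epochs) — about five minutes on one CPU core — and
requires mean held-out Dice ≥ 0.80 after thresholding and small-component
removal; measured runs land around 0.90. These sizes were chosen as the
smallest cohort at which every pipeline stage (cohort split,
standardization fit/apply, balanced sampling, training dynamics,
volumetric postprocessing, evaluation) operates away from degenerate
edge cases.
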