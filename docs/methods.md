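# Methods note

Assumptions, parameter defaults, and numerical design choices behind
`myxovision`. The README gives the model equations; this note records *why*
the defaults are what they are and where the implementation makes a judgment
call.

## Scope and scale

The package targets desk-scale, CPU-only operation: synthetic scenes of
256–504 px, GAN smoke training at 64×64 with base width 8. These sizes are a
package design choice so every result — including GAN training — is
reproducible in seconds on one CPU. The architectures and losses scale to
full-size microscopy fields (1024² and up, base width 64) through the same
configuration objects; nothing in the code is specific to the small sizes.

## Preprocessing

- **Rescaling** uses Lanczos resampling (Pillow); output dimensions are
  `round(n·factor)` and the physical pixel size is divided by the factor.
- **CLAHE** is scikit-image's `equalize_adapthist` with tile size 64 px and
  clip limit 0.02. Note the convention: scikit-image normalizes the clip
  limit to [0, 1], whereas OpenCV expresses it as a multiple of the mean
  tile-histogram count (where "2.0" is a common default). 0.02 in the
  scikit-image convention corresponds to a similarly mild clipping. Inputs
  are min–max normalized first, which makes the result invariant to affine
  intensity rescaling of the input.
- **Histogram equalization (HE)** is an in-package binned empirical-CDF
  mapping (256 bins by default): monotone, idempotent up to bin
  quantization, and intentionally *global* — HE is what reveals dim
  inter-aggregate streams, and it is non-invertible, which is why the GAN
  must synthesize the HE channel as a separate output head rather than
  deriving it from the normalized channel.
- **Range scaling** maps the declared intensity range affinely onto the
  target range ([−1, 1] for all GAN and metric work).

## Segmentation

Pipeline: difference-of-Gaussians bandpass (σ_low = 2 px, σ_high = 30 px,
`mode="nearest"` boundary handling) → min–max normalization → Otsu threshold
(256 bins; ties broken toward the lowest maximizing edge) → morphological
cleanup (opening with a radius-3 disk, hole filling, removal of components
below 64 px, closing).

Two deliberate choices:

- **Robust noise floor.** The effective threshold is
  `max(Otsu, median + 3·1.4826·MAD)` of the normalized response. Otsu always
  produces *a* split, even on a structureless histogram; without the floor, a
  pure-noise image percolates into one giant spurious foreground component.
  The floor (a standard robust z-score at 3σ) leaves real scenes untouched —
  their Otsu threshold is far above it — while making noise-only inputs
  return an empty mask. Otsu's criterion itself is implemented exactly and is
  verified against exhaustive between-class-variance search in the tests.
- **Threshold on the bandpassed response** (not raw intensities) by default:
  it removes slow illumination background and pixel noise in one step and
  makes the segmentation invariant to affine intensity rescaling. A
  `threshold_on="raw"` switch is provided for comparison.

## Aggregate matching and confusion

Connected components are 8-connected; centroids are pixel-coordinate means.
Matching is greedy on ascending centroid distance with deterministic
tie-breaks, one-to-one, and a candidate pair is accepted only if the two
pixel sets overlap and the larger area is at most twice the smaller. The
area-ratio gate encodes the rule that an aggregate more than twice the size
of its counterpart cannot be the same aggregate, regardless of position.
Pixel confusion uses the standard TP/FP/FN/TN partition; the label image
palette is TP white, FP orange, FN red, TN black. Precision and recall return
NaN on empty denominators rather than an arbitrary 0 or 1.

## Image metrics

MSE and the *global* SSIM statistic are implemented from their definitions.
Two documented subtleties:

- **SSIM minimum.** The statistic is often described as lying in [0, 1], but
  the formula can be negative for strongly anti-correlated images (the
  covariance term's numerator goes negative). We return the formula's value
  as-is and test that the negative regime exists; the maximum of 1 at
  identity is exact.
- **Global vs. windowed.** The default is the single whole-image statistic;
  a tile-averaged variant (`ssim_windowed`) exists purely for comparison
  with the conventional windowed SSIM.

The equivalent-shift calibration searches whole-pixel self-shifts
d = 1 … min(N_l, N_w)/2, averaging the metric over the four axis directions
on the overlapping region only (no wraparound or padding). If no shift in
range crosses the target (e.g. a constant image, whose self-shift MSE is 0),
the result is reported as infinity and counted as "capped" in movie
summaries rather than silently clamped. The equivalent-noise calibration is
the closed form σ = √MSE (clipping at the range boundary is not modeled);
it is validated by seeded Monte Carlo in the tests.

## Ripple wavelength

The radial spectrum bins the centered DFT magnitude by floor(radius), so
amplitude(k) is the mean over the exact pixel set with radius in [k, k+1) —
no interpolation. A window-3 moving average (2-neighbor ends) suppresses
single-bin fluctuations before peak picking. The cutoff
k_min = ⌈L / 84 μm⌉ rejects gradual large-scale intensity variation: for a
504 μm field, k < 6 would mean λ > 84 μm, longer than rippling produces.

**Raw-bin refinement.** For a near-monochromatic spectrum the moving average
creates an exact tie between the true bin k and its neighbor k−1, and a
lowest-k tie-break would systematically return k−1 (λ biased one bin long).
The estimator therefore uses the smoothed profile to locate the peak
*region*, then pins the selected wave-number to the dominant *unsmoothed*
bin within ±1 of it. This restores exact recovery (e.g. 24 periods over
504 μm → 21.0 μm; 11 periods → 45.8 μm ≈ 46 μm) while retaining smoothing's
robustness on noisy profiles. Rotation of the wave changes the result by at
most one bin (spectral leakage off the integer grid); the default
`peak="global"` takes the strongest smoothed bin above the cutoff, with a
`peak="first-local"` alternative for profiles with a known low-k ridge.

## Synthetic scenes

Generators provide paired phase-like/fluorescence-like images with exact
ground truth, for testing and smoke training only — they are idealizations,
not image simulators:

- **Aggregate scenes**: circular aggregates with a flat core (80% of R) and
  cosine falloff to 1.2 R; the mask support is exactly the half-maximum
  radius R. Optional 3-px-wide streams connect nearest neighbors (excluded
  from the truth mask — streams are not aggregates). The phase rendering
  adds a bright rim (halo) and interior cosine banding (shade-off) so
  intensity deliberately decorrelates from density. Placement enforces a
  minimum spacing (sum of radii + 4 px); when the field is too crowded the
  generator places what fits and records a warning in the truth metadata.
- **Ripple scenes**: plane sinusoids of configurable wavelength and
  orientation; the phase-like channel has 30% of the contrast and twice the
  noise. Wavelengths below the 2-pixel Nyquist limit are rejected.

All randomness flows through one seeded generator per scene; identical
parameters give bit-identical scenes.

## GAN architecture and training

Encoder (7×7 reflect-padded conv, then stride-2 doublings), residual
blocks, and a decoder of upsample stages. Decoder upsampling is
nearest-neighbor followed by a 3×3 convolution rather than a transposed
convolution — a standard, checkerboard-free variant. Branch-point candidates
are defined at decoder-stage boundaries: candidate 0 duplicates every
decoder stage into both heads, the last candidate duplicates only the output
convolution; the default (2) shares two decoder stages. The trunk is updated
by gradients from both heads (tested directly).

Discriminators are multi-scale PatchGANs (4×4 convolutions, LeakyReLU 0.2)
conditioned on the phase image by channel concatenation; the two output
channels get fully independent discriminators. Losses: least-squares
adversarial + L1 feature matching (weight 10, real features detached).
The first head's loss weight decays linearly from 1.0 to a floor of 0.5 over
the first 500 epochs (both endpoint and duration configurable — the floor
avoids silencing a head entirely); the second head's weight is constant at
1.0. Optimization is Adam, learning rate 5×10⁻⁵, betas (0.5, 0.999).

Checkpoints are single files containing configs, all parameters, optimizer
state, and the epoch counter. `resume_training` implements transfer
learning: previously learned parameters are the starting point on a new
pattern class, with a flag to either continue the weight schedule or restart
it.

The autodiff engine beneath all of this (`myxovision.nn`) is a ~300-line
reverse-mode Tensor with im2col convolutions; every operator's gradient is
checked against central finite differences in the test suite.
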