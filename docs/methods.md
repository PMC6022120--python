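# Methods

This note documents the model choices, parameter defaults, numerical
details and known limitations of the `mff` fusion pipeline and its
quality metrics.

## Pipeline model and assumptions

The pipeline assumes N ≥ 2 co-registered, same-size RGB sources of one
static scene differing only in focal plane.  It is a spatial-domain,
selection-style fuser: at each pixel one source is chosen as in-focus
(hard argmax over saliency-derived weights), and the guided refinement
then relaxes the hard decision near boundaries so base and detail layers
blend without halos.  No registration, exposure alignment or denoising is
performed; violations of the co-registration assumption show up as
ghosting, as in any weighted-average fuser.

All internal math is float64 on images scaled to [0, 1].  Integer input
(8/16-bit PNG/TIFF/JPEG) is rescaled by its type maximum on load; output
is clipped to [0, 1] only at the very end, because detail layers are
signed and intermediate clipping would bias the blend.

## Saliency stage

* **Frequency prior**: an isotropic log-Gabor band-pass applied in the
  frequency domain to the three CIELAB channels, with center frequency
  ω₀ = 0.002 cycles/px and bandwidth ratio σ_F = 6.2 — the defaults of the
  frequency/color/location saliency detector this stage follows.  A
  spatial difference-of-Gaussians band-pass (σ 1 → 10 px) is selectable
  for workloads where FFT wrap-around at borders matters.
* **Color prior**: σ_C = 0.25 on per-image min-max normalized a\*/b\*.
  A channel spanning less than 0.01 Lab units is treated as degenerate
  and zeroed: the rounded sRGB→XYZ matrix alone leaves ~3·10⁻³ residual
  chroma on perfectly achromatic input, and min-max normalization would
  amplify that roundoff to full scale.
* **Location prior**: σ_D = 114 px, the same detector's default.  The
  prior is intentionally weak at desk-scale image sizes.
* **Gradient saliency**: Scharr kernels (1/16)[3 10 3]ᵀ[1 0 −1]-style
  pair (y = transpose of x).  The raw ramp response is 2 per unit slope
  (central difference over a 2-px baseline); no kernel renormalization is
  applied because every map is min-max normalized before combination.
* **Chrominance saliency**: the signed product M·N of the opponent
  chrominance channels is rectified to |M·N| so the fractional exponent
  γ = 0.31 stays real-valued.
* All three maps are smoothed with a normalized Gaussian (σ = 2, radius 7,
  replicate padding) and min-max normalized to [0, 1]; the three measures
  have incommensurate physical scales and the multiplicative combination
  W = VS^α·GM^β·CD^γ is only meaningful on a common scale.  Exponent
  defaults α = 1, β = 0.89, γ = 0.31; 0⁰ is defined as 1 so a zero
  exponent disables a map entirely.

Ties in the per-pixel argmax go to the lowest source index
(deterministic, order-stable); the subsequent per-pixel normalization
only redistributes exact ties and assigns uniform 1/N at all-zero pixels.

## Gradient-domain fast guided filter

Window radius ζ₁ = 4, ε = 10⁻⁶ for both refinement passes; subsampling
s = 4; dynamic-range constant L = 9 with λ = (0.001·L)².  The edge-aware
weight is Γ̂_G(k) = (χ(k)+ε)·mean_i[1/(χ(i)+ε)] with
χ = σ_{G,1}·σ_{G,ζ₁}, and the slope target is the sigmoid edge indicator
γ_k = expit(η(χ−μ_χ)), η = 4/(μ_χ−min χ), returning 0.5 uniformly when χ
is constant to machine precision.  The regularizer enters as λ/Γ̂ —
weaker smoothing at edges, the form that actually suppresses halos; a
`multiply` switch (λ·Γ̂) is exposed for comparison.  Guidance is always
the opponent luminance L = 0.06R+0.63G+0.27B of the source, matching the
channel the gradients come from.

Windowed statistics use box-filter accumulation with replicate padding
(O(1) per pixel); the test suite carries an explicit per-window
least-squares oracle (2×2 normal equations solved per window) that the
fast path must reproduce to 10⁻⁸.  The fast variant subsamples input and
guidance by nearest neighbor (array slicing), runs the filter at radius
max(1, round(ζ₁/s)), computes Γ̂ at the subsampled scale, and upsamples
the averaged coefficients ā, b̄ bilinearly before applying them to the
full-resolution guidance.  s = 1 reduces exactly (bit-identically) to the
plain filter.

## Two-scale decomposition, morphology, blending

The base layer uses σ = 5, radius 15 (replicate padding) — large enough
to put focus-dependent texture into the detail layer while keeping
illumination in the base.  Decomposition is exactly invertible by
construction (detail = input − base).

Morphological cleanup of the refined, near-binary weight maps:
threshold 0.5, fill holes in the below-threshold mask, complement, fill
again, then 8-connected area opening at min_area = ⌈0.01·H·W⌉.  Hole
filling is area-bounded by the same min_area: unconditional filling
would delete any in-focus region fully enclosed by the defocused one
(a single pod sharp against a defocused background), while the step's
purpose is only speckle suppression.  Cleanup applies to both the base
and detail weight stacks by default (`morphology.apply_to` selects
base/detail/none).  The second refinement pass filters the base weights
with the source luminance as guidance; a `detail_guidance: base_weights`
switch selects the self-guided alternative reading.

One luminance-derived weight map is shared across R, G, B during
blending, which avoids color fringing at focus boundaries.

## Quality metrics

* **QMI** uses 256-bin joint histograms on 8-bit-quantized luminance;
  entropies and MI in bits (the base cancels in the ratio).  The
  histogram MI estimator carries an upward finite-sample bias of order
  bins²/(2N ln 2); near-zero readings are only meaningful at ≥ 512²
  pixels, and tests of the "noise transfers nothing" property use that
  size.  Constant images (zero entropy) contribute 0 with a warning.
* **QY** uses a 7×7 uniform window, population (ddof 0) moments,
  replicate padding, SSIM stabilizers (0.01², 0.03²) for unit range, the
  0.75 source-agreement branch, λ(w) = s_x/(s_x+s_y) with 0.5 at doubly
  flat windows, and mean aggregation over all windows (bounded by 1).
* **QAB/F** uses unnormalized 3×3 Sobel strength/orientation, orientation
  arctan(s_y/s_x) with ±π/2 at s_x = 0 and 0 at zero gradient, relative
  strength min/max ratio with 0 where either gradient vanishes (no edge
  information to preserve), sigmoid constants Γ_g = 0.9994, K_g = −15,
  σ_g = 0.5, Γ_α = 0.9879, K_α = −22, σ_α = 0.8 (the originating metric's
  published values), and gradient-strength weights w_A = g_A.  A perfect
  copy scores the sigmoid ceiling ≈ 0.9747, not 1.
* Color inputs are reduced to the opponent luminance before all three
  metrics, for consistency with the pipeline's guidance channel.

Metric degradation monotonicity (blurring a perfect fusion must not
raise any metric) is checked against the sharp ground truth as both
references.  Against partially defocused sources the property genuinely
fails: a candidate blurred near the sources' own defocus width resembles
their blurred halves, and QMI/QAB/F rise locally — a property of the
metrics, not an implementation artifact.

## Synthetic fixtures

The generator emulates artificially defocused multi-focus pairs: a sharp
truth image, a binary focus mask, and complementary Gaussian blur
(default σ = 3).  The default "plant-like" truth composes 25 random
elliptical green-yellow blobs (leaves/pods) over a brownish soil-texture
background plus fine global texture, so the gradient focus measure has
structure at every pixel, as real canopy photographs do.  Default study
conditions: 512×512, seeds 1–5, alternating vertical half-plane and
elliptical focus masks, noise-free; sensor noise (seeded Gaussian) and a
feathered mask transition are available but off by default, since the
recovery thresholds are calibrated noise-free.

What the fixtures do not model: depth-dependent (spatially varying) blur,
lens PSF asymmetry, chromatic aberration, exposure differences between
focal slices, and mis-registration.  Passing recovery tests therefore
demonstrates correct mechanics of selection, refinement and blending —
not robustness to those real-world effects.

## Problem sizes

The test suite runs unit tests at 16²–64², oracle comparisons at 16²–32²
(the loop oracles are O(HW·window²)), and the end-to-end study at the
default 512² on five pairs; the full suite completes in well under a
minute on one CPU.  `scripts/acceptance.py` re-runs the five-pair study
from scratch in a few seconds.

## Known limitations

* The argmax decision is global per pixel; scenes where no source is
  sharp anywhere (all-defocused stacks) degrade to picking the least
  blurred source rather than deconvolving.
* The log-Gabor frequency prior is applied via FFT and thus assumes
  periodic boundaries; a few-pixel band at the border can leak energy
  across the frame (the DoG fallback avoids this at some accuracy cost).
* 16-bit color output is written as TIFF; the available PNG encoder
  handles only 8-bit RGB.
* QMI between images with very different histograms is bounded well
  below 2 even for ideal fusion; compare values only across candidates
  for the same source pair.
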