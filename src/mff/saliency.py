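"""Per-source saliency maps driving the fusion weight maps.

Three maps are computed for every source image:

* **VS** — visual saliency, the product of a frequency prior (band-pass
  energy over the CIELAB channels), a color prior (warm colors pop), and a
  location prior (center bias), then Gaussian-smoothed.
* **GM** — gradient-magnitude saliency from the Scharr operator applied to
  the opponent-space luminance, then Gaussian-smoothed.  In a multi-focus
  stack this is the focus measure: in-focus regions carry stronger
  high-frequency content.
* **CD** — chrominance (color-distortion) saliency from the product of the
  two opponent chrominance channels, rectified, then Gaussian-smoothed.

Each smoothed map is min-max normalized to [0, 1] before entering the
weight-map combination, so the three incommensurate scales become
comparable and fractional exponents act as pure importance controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .colorspace import GaussianSpec, gaussian_smooth, rgb_to_cielab, rgb_to_lmn

__all__ = [
    "SaliencyParams",
    "SaliencyBundle",
    "frequency_prior",
    "color_prior",
    "location_prior",
    "visual_saliency_map",
    "scharr_gradients",
    "gradient_saliency_map",
    "chrominance_saliency_map",
    "compute_bundle",
    "minmax_normalize",
]

# Scharr x-derivative kernel; the y kernel is its transpose.
SCHARR_X = np.array(
    [
        [3.0, 0.0, -3.0],
        [10.0, 0.0, -10.0],
        [3.0, 0.0, -3.0],
    ]
) / 16.0


@dataclass(frozen=True)
class SaliencyParams:
    """Parameters of the three saliency priors and their smoothing.

    Defaults for ``sigma_c`` and ``sigma_d`` follow the frequency/color/
    location prior saliency detector the method builds on (0.25 on min-max
    normalized a*/b*; 114 px center-bias width).  The band-pass ``g`` of the
    frequency prior is a log-Gabor filter with center frequency ``omega0``
    (cycles/pixel) and bandwidth ratio ``sigma_f``; a difference-of-Gaussians
    fallback is selectable via ``bandpass="dog"``.
    """

    sigma_c: float = 0.25
    sigma_d: float = 114.0
    bandpass: str = "log-gabor"
    omega0: float = 0.002
    sigma_f: float = 6.2
    dog_sigma_inner: float = 1.0
    dog_sigma_outer: float = 10.0
    smooth: GaussianSpec = field(default_factory=lambda: GaussianSpec(sigma=2.0, radius=7))

    def __post_init__(self) -> None:
        for name in ("sigma_c", "sigma_d", "omega0", "dog_sigma_inner", "dog_sigma_outer"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_f <= 1:
            raise ValueError("sigma_f is a bandwidth ratio and must exceed 1")
        if self.bandpass not in ("log-gabor", "dog"):
            raise ValueError(f"unknown bandpass filter {self.bandpass!r}")


@dataclass(frozen=True)
class SaliencyBundle:
    """The three normalized saliency maps of one source image."""

    vs: np.ndarray
    gm: np.ndarray
    cd: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.vs.shape


def minmax_normalize(p: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant plane maps to zeros."""
    p = np.asarray(p, dtype=float)
    lo, hi = p.min(), p.max()
    if hi - lo == 0:
        return np.zeros_like(p)
    return (p - lo) / (hi - lo)


def _log_gabor_response(plane: np.ndarray, omega0: float, sigma_f: float) -> np.ndarray:
    """Apply an isotropic log-Gabor band-pass in the frequency domain."""
    h, w = plane.shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0  # avoid log(0); the DC gain is forced to zero below
    lg = np.exp(-(np.log(radius / omega0) ** 2) / (2.0 * np.log(sigma_f) ** 2))
    lg[0, 0] = 0.0
    return np.real(np.fft.ifft2(np.fft.fft2(plane) * lg))


def _dog_response(plane: np.ndarray, sigma_inner: float, sigma_outer: float) -> np.ndarray:
    lo = gaussian_smooth(plane, GaussianSpec(sigma=sigma_inner))
    hi = gaussian_smooth(plane, GaussianSpec(sigma=sigma_outer))
    return lo - hi


def frequency_prior(img: np.ndarray, params: SaliencyParams) -> np.ndarray:
    """Band-pass energy over the CIELAB channels.

    ``SF = sqrt((L*g)^2 + (a*g)^2 + (b*g)^2)`` with ``g`` the band-pass
    filter.  The filter has zero DC gain, so constant images map to zero.
    """
    planes = rgb_to_cielab(img)
    if params.bandpass == "log-gabor":
        resp = [_log_gabor_response(p, params.omega0, params.sigma_f) for p in planes]
    else:
        resp = [_dog_response(p, params.dog_sigma_inner, params.dog_sigma_outer) for p in planes]
    return np.sqrt(sum(r**2 for r in resp))


def color_prior(img: np.ndarray, params: SaliencyParams) -> np.ndarray:
    """Warm-color prior ``SC = 1 - exp(-(a'^2 + b'^2) / sigma_c^2)``.

    a* and b* are min-max normalized to [0, 1] per image, so reddish and
    yellowish (warm) pixels score high.  A degenerate (constant) channel
    normalizes to zero.
    """
    _, a, b = rgb_to_cielab(img)
    # a channel spanning < 0.01 Lab units carries no usable chroma signal
    # (the sRGB matrix constants alone leave ~3e-3 residual on gray), so it
    # is treated as degenerate rather than noise-amplified by min-max.
    chroma_eps = 1e-2
    an = minmax_normalize(a) if a.max() - a.min() > chroma_eps else np.zeros_like(a)
    bn = minmax_normalize(b) if b.max() - b.min() > chroma_eps else np.zeros_like(b)
    return 1.0 - np.exp(-(an**2 + bn**2) / params.sigma_c**2)


def location_prior(shape: tuple[int, int], params: SaliencyParams) -> np.ndarray:
    """Center-bias prior ``SD(k) = exp(-|k - c|^2 / sigma_d^2)``."""
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError(f"invalid shape {shape}")
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    y = np.arange(h)[:, None] - cy
    x = np.arange(w)[None, :] - cx
    return np.exp(-(y**2 + x**2) / params.sigma_d**2)


def visual_saliency_map(img: np.ndarray, params: SaliencyParams) -> np.ndarray:
    """Smoothed product of the frequency, color and location priors."""
    sf = frequency_prior(img, params)
    sc = color_prior(img, params)
    sd = location_prior(sf.shape, params)
    return gaussian_smooth(sf * sc * sd, params.smooth)


def scharr_gradients(lum: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scharr partial derivatives (x, y) of a luminance plane.

    The x kernel is ``(1/16) [[3, 0, -3], [10, 0, -10], [3, 0, -3]]``; the y
    kernel is its transpose.  Replicate padding at the borders.
    """
    lum = np.asarray(lum, dtype=float)
    gx = ndimage.correlate(lum, SCHARR_X, mode="nearest")
    gy = ndimage.correlate(lum, SCHARR_X.T, mode="nearest")
    return gx, gy


def gradient_saliency_map(lum: np.ndarray, params: SaliencyParams) -> np.ndarray:
    """Smoothed gradient modulus ``sqrt(gx^2 + gy^2)`` of the luminance."""
    gx, gy = scharr_gradients(lum)
    return gaussian_smooth(np.hypot(gx, gy), params.smooth)


def chrominance_saliency_map(img: np.ndarray, params: SaliencyParams) -> np.ndarray:
    """Smoothed, rectified product of the opponent chrominance channels.

    The raw product ``M * N`` is signed; it is rectified to ``|M * N|`` so
    the downstream fractional exponent is well defined.
    """
    _, m, n = rgb_to_lmn(img)
    return gaussian_smooth(np.abs(m * n), params.smooth)


def compute_bundle(img: np.ndarray, params: SaliencyParams | None = None) -> SaliencyBundle:
    """All three saliency maps of one source, min-max normalized to [0, 1]."""
    params = params or SaliencyParams()
    lum = rgb_to_lmn(img)[0]
    return SaliencyBundle(
        vs=minmax_normalize(visual_saliency_map(img, params)),
        gm=minmax_normalize(gradient_saliency_map(lum, params)),
        cd=minmax_normalize(chrominance_saliency_map(img, params)),
    )
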