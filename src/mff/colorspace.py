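"""Color-space transforms and Gaussian smoothing shared by the saliency stages.

All images are ``float64`` arrays in ``[0, 1]``: color images are ``(H, W, 3)``
in RGB order, single-channel planes are ``(H, W)``.  Integer images are
rescaled on load (see :mod:`mff.io`); every internal computation is floating
point so that the fractional exponents of the weight-map combination stay
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import rgb2lab

__all__ = [
    "GaussianSpec",
    "validate_color_image",
    "rgb_to_cielab",
    "rgb_to_lmn",
    "luminance",
    "gaussian_smooth",
]

# Opponent LMN color space: L is luminance, M and N are the two chrominance
# channels used for the color-distortion saliency.
_LMN_MATRIX = np.array(
    [
        [0.06, 0.63, 0.27],
        [0.30, 0.04, -0.35],
        [0.34, -0.60, 0.17],
    ]
)


@dataclass(frozen=True)
class GaussianSpec:
    """Normalized 2-D Gaussian smoothing kernel.

    Parameters
    ----------
    sigma : float
        Standard deviation in pixels; must be positive.
    radius : int, optional
        Half-width of the truncated kernel.  Defaults to ``ceil(3 * sigma)``
        (3-sigma support).
    """

    sigma: float
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.radius is not None and self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")

    @property
    def effective_radius(self) -> int:
        return self.radius if self.radius is not None else int(np.ceil(3.0 * self.sigma))

    def kernel1d(self) -> np.ndarray:
        """Normalized 1-D Gaussian taps; the 2-D kernel is their outer product."""
        r = self.effective_radius
        x = np.arange(-r, r + 1, dtype=float)
        k = np.exp(-0.5 * (x / self.sigma) ** 2)
        return k / k.sum()


def validate_color_image(img: np.ndarray) -> np.ndarray:
    """Check an (H, W, 3) RGB array in [0, 1] and return it as float64."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]; rescale on load")
    return img


def rgb_to_cielab(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an RGB image to CIELAB planes (L*, a*, b*).

    Uses sRGB primaries and the D65 white point, the near-universal camera
    default.  L* is in [0, 100]; a* and b* are signed opponent channels.
    """
    img = validate_color_image(img)
    lab = rgb2lab(img)
    return lab[..., 0], lab[..., 1], lab[..., 2]


def rgb_to_lmn(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert RGB to the opponent LMN space.

    ``L = 0.06 R + 0.63 G + 0.27 B`` is the luminance used for gradient
    computation and as guided-filter guidance; ``M`` and ``N`` are the
    chrominance channels feeding the color-distortion saliency.
    """
    img = validate_color_image(img)
    lmn = img @ _LMN_MATRIX.T
    return lmn[..., 0], lmn[..., 1], lmn[..., 2]


def luminance(img: np.ndarray) -> np.ndarray:
    """The L channel of the LMN opponent space."""
    return rgb_to_lmn(img)[0]


def gaussian_smooth(plane: np.ndarray, spec: GaussianSpec) -> np.ndarray:
    """Convolve a plane with a normalized, truncated Gaussian.

    Borders are replicate-padded, so constants are preserved exactly.  The
    kernel is separable and the separable passes with replicate padding are
    identical to the full 2-D convolution with replicate padding.
    """
    plane = np.asarray(plane, dtype=float)
    k = spec.kernel1d()
    out = ndimage.correlate1d(plane, k, axis=0, mode="nearest")
    out = ndimage.correlate1d(out, k, axis=1, mode="nearest")
    return out
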