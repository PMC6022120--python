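"""Synthetic multi-focus fixtures with known all-in-focus ground truth.

Real multi-focus stacks have no reference image, so every recovery claim
is tested on synthetic pairs: a sharp ground-truth image is blurred in
complementary regions, producing two sources whose union of in-focus
masks covers the frame.  The default "plant-like" truth composes random
elliptical blobs (leaves/pods) over a textured soil background with fine
texture everywhere, so the gradient-based focus measure has structure to
discriminate on at every pixel, as a real canopy photograph does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import GaussianSpec, gaussian_smooth, validate_color_image

__all__ = [
    "SyntheticPair",
    "make_truth",
    "half_plane_mask",
    "blob_mask",
    "make_multifocus_pair",
    "default_pairs",
]


@dataclass(frozen=True)
class SyntheticPair:
    """Two complementary-blur sources with their ground truth and masks."""

    truth: np.ndarray
    sources: tuple[np.ndarray, ...]
    masks: tuple[np.ndarray, ...]
    blur_sigma: float
    seed: int


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if sigma > 0:
        noise = gaussian_smooth(noise, GaussianSpec(sigma=sigma))
    lo, hi = noise.min(), noise.max()
    return (noise - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def make_truth(kind: str, shape: tuple[int, int], seed: int) -> np.ndarray:
    """Deterministic sharp ground-truth image of the requested kind.

    ``texture``: multi-scale colored noise.  ``plant-like``: elliptical
    green blobs over a brownish textured background plus fine venation
    texture.  ``checker``: an exact 8-px checkerboard.
    """
    h, w = shape
    rng = np.random.default_rng(seed)
    if kind == "checker":
        yy, xx = np.mgrid[0:h, 0:w]
        cells = ((yy // 8 + xx // 8) % 2).astype(float)
        img = np.dstack([0.1 + 0.8 * cells] * 3)
        return validate_color_image(img)
    if kind == "texture":
        channels = [
            0.5 * _smooth_noise(rng, shape, 4.0) + 0.5 * _smooth_noise(rng, shape, 0.0)
            for _ in range(3)
        ]
        img = 0.05 + 0.9 * np.dstack(channels)
        return validate_color_image(img)
    if kind != "plant-like":
        raise ValueError(f"unknown truth kind {kind!r}")

    # soil-like background: brownish base modulated by coarse and fine noise
    coarse = _smooth_noise(rng, shape, 6.0)
    img = np.dstack(
        [
            0.35 + 0.25 * coarse,
            0.28 + 0.20 * coarse,
            0.18 + 0.12 * coarse,
        ]
    )

    # elliptical leaves/pods in green-yellow hues
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    n_blobs = 25
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry = rng.uniform(0.03, 0.12) * h
        rx = rng.uniform(0.02, 0.08) * w
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = ((yy - cy) * ct + (xx - cx) * st) / ry
        v = (-(yy - cy) * st + (xx - cx) * ct) / rx
        inside = u**2 + v**2 <= 1.0
        shade = rng.uniform(0.6, 1.0)
        color = np.array([rng.uniform(0.15, 0.45), rng.uniform(0.45, 0.75), rng.uniform(0.1, 0.3)])
        img[inside] = shade * color

    # fine venation/soil-grain texture everywhere so gradients never vanish
    fine = _smooth_noise(rng, shape, 0.7) - 0.5
    img += 0.12 * fine[..., None]
    return validate_color_image(np.clip(img, 0.0, 1.0))


def half_plane_mask(shape: tuple[int, int], orientation: str = "vertical") -> np.ndarray:
    """Binary mask: True on the left (or top) half of the frame."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    if orientation == "vertical":
        mask[:, : w // 2] = True
    elif orientation == "horizontal":
        mask[: h // 2, :] = True
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return mask


def blob_mask(shape: tuple[int, int], seed: int) -> np.ndarray:
    """Binary mask: True inside one random ellipse covering ~15-40% of the frame."""
    h, w = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy = rng.uniform(0.35, 0.65) * h
    cx = rng.uniform(0.35, 0.65) * w
    ry = rng.uniform(0.25, 0.4) * h
    rx = rng.uniform(0.25, 0.4) * w
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _blur_color(img: np.ndarray, sigma: float) -> np.ndarray:
    spec = GaussianSpec(sigma=sigma)
    return np.dstack([gaussian_smooth(img[..., c], spec) for c in range(3)])


def make_multifocus_pair(
    truth: np.ndarray,
    mask: np.ndarray,
    blur_sigma: float = 3.0,
    seed: int = 0,
    transition_px: float = 0.0,
    noise_sigma: float = 0.0,
) -> SyntheticPair:
    """Complementary-blur pair from a sharp truth image.

    Source 1 is sharp where ``mask`` is True and defocused (Gaussian blur of
    width ``blur_sigma``) elsewhere; source 2 is the complement.  An optional
    feathered transition band of width ``transition_px`` softens the seam,
    and optional Gaussian sensor noise (off by default) is seeded.
    """
    truth = validate_color_image(truth)
    if blur_sigma <= 0:
        raise ValueError("blur_sigma must be positive")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != truth.shape[:2]:
        raise ValueError("mask shape must match the truth image")
    blurred = _blur_color(truth, blur_sigma)

    m = mask.astype(float)
    if transition_px > 0:
        m = gaussian_smooth(m, GaussianSpec(sigma=transition_px))
    sources = []
    for weight in (m, 1.0 - m):
        src = weight[..., None] * truth + (1.0 - weight[..., None]) * blurred
        if noise_sigma > 0:
            rng = np.random.default_rng(seed + len(sources))
            src = src + rng.normal(0.0, noise_sigma, src.shape)
        sources.append(np.clip(src, 0.0, 1.0))
    return SyntheticPair(
        truth=truth,
        sources=tuple(sources),
        masks=(mask, ~mask),
        blur_sigma=float(blur_sigma),
        seed=int(seed),
    )


def default_pairs(
    seeds=(1, 2, 3, 4, 5),
    shape: tuple[int, int] = (512, 512),
    blur_sigma: float = 3.0,
) -> list[SyntheticPair]:
    """The default fixture set: plant-like truths, alternating half-plane
    and elliptical focus masks, complementary blur, noise-free."""
    pairs = []
    for i, seed in enumerate(seeds):
        truth = make_truth("plant-like", shape, seed)
        mask = half_plane_mask(shape) if i % 2 == 0 else blob_mask(shape, seed)
        pairs.append(make_multifocus_pair(truth, mask, blur_sigma=blur_sigma, seed=seed))
    return pairs
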