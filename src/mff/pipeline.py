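"""End-to-end multi-focus fusion pipeline.

Each source is split into a base layer (Gaussian-smoothed) and a detail
layer (residual).  Saliency-derived, binarized weight maps are refined by
two passes of the fast gradient-domain guided filter — one pass for the
base-layer weights, a second for the detail-layer weights — cleaned up
morphologically, renormalized, and used to blend the base and detail
layers of all sources into the fused image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .colorspace import GaussianSpec, gaussian_smooth, luminance, validate_color_image
from .gdfgf import GDFGFParams, fast_gdgif
from .saliency import SaliencyParams, compute_bundle
from .weighting import ExponentParams, argmax_binarize, combine_saliencies, normalize_weights

__all__ = [
    "TwoScale",
    "RefinedWeights",
    "MorphParams",
    "FusionConfig",
    "FusionResult",
    "two_scale_decompose",
    "morphological_cleanup",
    "refine_weights",
    "blend",
    "fuse",
]


@dataclass(frozen=True)
class TwoScale:
    """Base/detail decomposition; ``base + detail`` reconstructs the input."""

    base: np.ndarray
    detail: np.ndarray


@dataclass(frozen=True)
class RefinedWeights:
    """Refined, renormalized weight stacks for the base and detail layers."""

    w_base: np.ndarray
    w_detail: np.ndarray


@dataclass(frozen=True)
class MorphParams:
    """Morphological cleanup of near-binary weight maps.

    ``threshold`` binarizes the map; connected components of the in-focus
    mask smaller than ``min_area`` pixels are dropped and holes are filled.
    ``min_area=None`` defaults to 1% of the image area.
    """

    threshold: float = 0.5
    min_area: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly inside (0, 1)")
        if self.min_area is not None and self.min_area < 1:
            raise ValueError("min_area must be a positive pixel count")

    def effective_min_area(self, shape: tuple[int, int]) -> int:
        if self.min_area is not None:
            return self.min_area
        return math.ceil(0.01 * shape[0] * shape[1])


@dataclass(frozen=True)
class FusionConfig:
    """Full parameter set of the fusion pipeline (reference defaults)."""

    exponents: ExponentParams = field(default_factory=ExponentParams)
    saliency: SaliencyParams = field(default_factory=SaliencyParams)
    filter_pass1: GDFGFParams = field(default_factory=lambda: GDFGFParams(zeta1=4, eps=1e-6))
    filter_pass2: GDFGFParams = field(default_factory=lambda: GDFGFParams(zeta1=4, eps=1e-6))
    morph: MorphParams = field(default_factory=MorphParams)
    decomposition: GaussianSpec = field(default_factory=lambda: GaussianSpec(sigma=5.0, radius=15))
    # second refinement pass guidance: "source" filters the refined base
    # weights with the source luminance (the formula reading); "base_weights"
    # uses the refined base weight map itself as guidance (the textual one).
    detail_guidance: str = "source"
    # which refined stacks receive morphological cleanup
    morph_apply_to: str = "both"

    def __post_init__(self) -> None:
        if self.detail_guidance not in ("source", "base_weights"):
            raise ValueError("detail_guidance must be 'source' or 'base_weights'")
        if self.morph_apply_to not in ("both", "base", "detail", "none"):
            raise ValueError("morph_apply_to must be both/base/detail/none")


@dataclass(frozen=True)
class FusionResult:
    """Fused image plus per-stage diagnostic maps."""

    fused: np.ndarray
    weights: np.ndarray
    refined: RefinedWeights
    bundles: tuple


def two_scale_decompose(img: np.ndarray, spec: GaussianSpec | None = None) -> TwoScale:
    """Split into Gaussian base and residual detail, exactly reconstructing."""
    spec = spec or GaussianSpec(sigma=5.0, radius=15)
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        base = gaussian_smooth(img, spec)
    elif img.ndim == 3:
        base = np.dstack([gaussian_smooth(img[..., c], spec) for c in range(img.shape[2])])
    else:
        raise ValueError(f"expected a 2-D plane or (H, W, C) image, got shape {img.shape}")
    return TwoScale(base=base, detail=img - base)


def _fill_small_holes(mask: np.ndarray, max_area: int) -> np.ndarray:
    """Fill enclosed holes smaller than ``max_area`` pixels (4-connected)."""
    holes = ndimage.binary_fill_holes(mask) & ~mask
    labels, n_labels = ndimage.label(holes)
    if n_labels:
        sizes = np.bincount(labels.ravel())
        small = sizes < max_area
        small[0] = False
        mask = mask | small[labels]
    return mask


def morphological_cleanup(w: np.ndarray, morph: MorphParams | None = None) -> np.ndarray:
    """Remove small holes and islands from a near-binary weight map.

    Threshold, fill small holes in the below-threshold mask, complement,
    fill small holes again, then drop 8-connected components smaller than
    ``min_area``.  Hole filling is area-bounded by the same ``min_area``:
    unconditional filling would delete any in-focus region fully enclosed
    by the defocused one (e.g. a single seedpod in front of background),
    while the cleanup's purpose is only to suppress small speckle.
    Returns a float 0/1 map.
    """
    morph = morph or MorphParams()
    w = np.asarray(w, dtype=float)
    if w.min() < 0 or w.max() > 1:
        raise ValueError("weight map must lie in [0, 1]")
    min_area = morph.effective_min_area(w.shape)
    mask = w < morph.threshold
    mask = _fill_small_holes(mask, min_area)
    comp = ~mask
    comp = _fill_small_holes(comp, min_area)
    # area opening: drop 8-connected components below the minimum area
    labels, n_labels = ndimage.label(comp, structure=np.ones((3, 3), dtype=bool))
    if n_labels:
        sizes = np.bincount(labels.ravel())
        small = sizes < min_area
        small[0] = False
        comp = comp & ~small[labels]
    return comp.astype(float)


def refine_weights(
    stack: np.ndarray, sources: Sequence[np.ndarray], cfg: FusionConfig | None = None
) -> RefinedWeights:
    """Two-pass guided refinement of the weight stack plus morphology.

    Pass 1 filters each source's weight map with the source luminance as
    guidance, giving the base-layer weights; pass 2 re-filters those for the
    detail layer.  Both stacks are then cleaned up morphologically (per
    config) and renormalized to a per-pixel partition of unity.
    """
    cfg = cfg or FusionConfig()
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] != len(sources):
        raise ValueError("weight stack count must match the number of sources")
    w_base, w_detail = [], []
    for wn, src in zip(stack, sources):
        guide = luminance(src)
        wb = fast_gdgif(wn, guide, cfg.filter_pass1)
        guide2 = wb if cfg.detail_guidance == "base_weights" else guide
        wd = fast_gdgif(wb, guide2, cfg.filter_pass2)
        w_base.append(np.clip(wb, 0.0, 1.0))
        w_detail.append(np.clip(wd, 0.0, 1.0))
    w_base = np.stack(w_base)
    w_detail = np.stack(w_detail)
    if cfg.morph_apply_to in ("both", "base"):
        w_base = np.stack([morphological_cleanup(w, cfg.morph) for w in w_base])
    if cfg.morph_apply_to in ("both", "detail"):
        w_detail = np.stack([morphological_cleanup(w, cfg.morph) for w in w_detail])
    return RefinedWeights(
        w_base=normalize_weights(w_base), w_detail=normalize_weights(w_detail)
    )


def blend(decomps: Sequence[TwoScale], rw: RefinedWeights) -> np.ndarray:
    """Weighted sums of base and detail layers; fused image clipped to [0, 1].

    A single luminance-derived weight map is shared across the color
    channels, which avoids color fringing at focus boundaries.
    """
    if len(decomps) != rw.w_base.shape[0]:
        raise ValueError("decomposition count must match the weight stacks")
    base = sum(w[..., None] * d.base for w, d in zip(rw.w_base, decomps))
    detail = sum(w[..., None] * d.detail for w, d in zip(rw.w_detail, decomps))
    return np.clip(base + detail, 0.0, 1.0)


def fuse(sources: Sequence[np.ndarray], cfg: FusionConfig | None = None) -> FusionResult:
    """Fuse two or more co-registered multi-focus sources.

    Deterministic for fixed inputs and configuration: saliency bundles →
    weight combination → per-pixel argmax → guided refinement → two-scale
    blending.
    """
    cfg = cfg or FusionConfig()
    if len(sources) < 2:
        raise ValueError("need at least two source images")
    sources = [validate_color_image(s) for s in sources]
    shape = sources[0].shape
    if any(s.shape != shape for s in sources):
        raise ValueError("all sources must share identical dimensions")

    bundles = tuple(compute_bundle(s, cfg.saliency) for s in sources)
    raw = combine_saliencies(bundles, cfg.exponents)
    binary = normalize_weights(argmax_binarize(raw))
    refined = refine_weights(binary, sources, cfg)
    decomps = [two_scale_decompose(s, cfg.decomposition) for s in sources]
    fused = blend(decomps, refined)
    return FusionResult(fused=fused, weights=binary, refined=refined, bundles=bundles)
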