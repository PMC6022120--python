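"""No-reference fusion quality metrics QMI, QY and QAB/F.

All three score a fused image ``f`` against its two sources without any
ground truth:

* **QMI** — normalized mutual information transfer,
  ``2 * (I(X,F)/(H(X)+H(F)) + I(Y,F)/(H(Y)+H(F)))``, from 256-bin
  histograms; 2 when the fused image is an exact copy of both sources.
* **QY** — structural-similarity preservation: in windows where the two
  sources agree (``SSIM(x,y|w) >= 0.75``) a variance-weighted mix of
  ``SSIM(x,f|w)`` and ``SSIM(y,f|w)``, otherwise the better of the two;
  averaged over all windows.
* **QAB/F** — edge-information preservation: Sobel gradient strength and
  orientation of the fused image relative to each source, mapped through
  sigmoids and aggregated with gradient-strength weights.

Color images are converted to the opponent-space luminance before scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .colorspace import luminance as _rgb_luminance

__all__ = [
    "EdgeMetricConstants",
    "MetricReport",
    "to_luminance",
    "qmi",
    "qy",
    "qabf",
    "evaluate_fusion",
]


@dataclass(frozen=True)
class EdgeMetricConstants:
    """Sigmoid constants of the edge-preservation metric (published defaults)."""

    gamma_g: float = 0.9994
    k_g: float = -15.0
    sigma_g: float = 0.5
    gamma_a: float = 0.9879
    k_a: float = -22.0
    sigma_a: float = 0.8


@dataclass(frozen=True)
class MetricReport:
    """The (QMI, QY, QAB/F) triple for one fused image."""

    qmi: float
    qy: float
    qabf: float

    def to_dict(self) -> dict:
        return asdict(self)


def to_luminance(img: np.ndarray) -> np.ndarray:
    """Pass through 2-D planes; reduce RGB images to the opponent luminance."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 2:
        return img
    return _rgb_luminance(img)


def _quantize(p: np.ndarray) -> np.ndarray:
    """8-bit quantization of a [0, 1]-ish plane for histogram statistics."""
    return np.clip(np.round(np.asarray(p, dtype=float) * 255.0), 0, 255).astype(np.intp)


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    joint = np.zeros((256, 256))
    np.add.at(joint, (_quantize(a).ravel(), _quantize(b).ravel()), 1.0)
    pj = joint / joint.sum()
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    nz = pj > 0
    return float((pj[nz] * np.log2(pj[nz] / np.outer(pa, pb)[nz])).sum())


def qmi(x: np.ndarray, y: np.ndarray, f: np.ndarray) -> float:
    """Normalized mutual-information transfer from both sources to ``f``."""
    x, y, f = (to_luminance(p) for p in (x, y, f))
    if not x.shape == y.shape == f.shape:
        raise ValueError("all images must share one shape")
    hf = _entropy(np.bincount(_quantize(f).ravel(), minlength=256))
    total = 0.0
    for src in (x, y):
        hs = _entropy(np.bincount(_quantize(src).ravel(), minlength=256))
        denom = hf + hs
        if denom == 0:
            warnings.warn("constant images: zero entropy, contribution set to 0")
            continue
        total += _mutual_information(src, f) / denom
    return 2.0 * total


def _ssim_maps(a: np.ndarray, b: np.ndarray, window: int) -> np.ndarray:
    """Per-window SSIM with a uniform window and replicate padding."""
    c1, c2 = 0.01**2, 0.03**2  # standard stabilizers for unit dynamic range
    mean = lambda p: ndimage.uniform_filter(p, size=window, mode="nearest")
    ma, mb = mean(a), mean(b)
    va = mean(a * a) - ma**2
    vb = mean(b * b) - mb**2
    cab = mean(a * b) - ma * mb
    return ((2 * ma * mb + c1) * (2 * cab + c2)) / ((ma**2 + mb**2 + c1) * (va + vb + c2))


def qy(x: np.ndarray, y: np.ndarray, f: np.ndarray, window: int = 7) -> float:
    """Structural-similarity preservation of ``f`` with respect to ``x, y``."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    x, y, f = (to_luminance(p) for p in (x, y, f))
    if not x.shape == y.shape == f.shape:
        raise ValueError("all images must share one shape")
    mean = lambda p: ndimage.uniform_filter(p, size=window, mode="nearest")
    sx = np.maximum(mean(x * x) - mean(x) ** 2, 0.0)
    sy = np.maximum(mean(y * y) - mean(y) ** 2, 0.0)
    ssim_xy = _ssim_maps(x, y, window)
    ssim_xf = _ssim_maps(x, f, window)
    ssim_yf = _ssim_maps(y, f, window)
    denom = sx + sy
    lam = np.where(denom > 0, sx / np.where(denom > 0, denom, 1.0), 0.5)
    mixed = lam * ssim_xf + (1.0 - lam) * ssim_yf
    best = np.maximum(ssim_xf, ssim_yf)
    return float(np.mean(np.where(ssim_xy >= 0.75, mixed, best)))


def _sobel_strength_orientation(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sx = ndimage.sobel(p, axis=1, mode="nearest")
    sy = ndimage.sobel(p, axis=0, mode="nearest")
    g = np.hypot(sx, sy)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.arctan(sy / sx)
    alpha = np.where(sx == 0, np.where(sy == 0, 0.0, np.sign(sy) * np.pi / 2), alpha)
    return g, alpha


def qabf(
    a: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    consts: EdgeMetricConstants | None = None,
) -> float:
    """Edge-information preservation of ``f`` with respect to sources ``a, b``."""
    consts = consts or EdgeMetricConstants()
    a, b, f = (to_luminance(p) for p in (a, b, f))
    if not a.shape == b.shape == f.shape:
        raise ValueError("all images must share one shape")
    gf, af = _sobel_strength_orientation(f)

    def preservation(gs: np.ndarray, als: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(gs > gf, gf / gs, gs / gf)
        rel = np.where((gs == 0) | (gf == 0), 0.0, rel)  # no edge to preserve
        ori = 1.0 - np.abs(als - af) / (np.pi / 2)
        qg = consts.gamma_g / (1.0 + np.exp(consts.k_g * (rel - consts.sigma_g)))
        qa = consts.gamma_a / (1.0 + np.exp(consts.k_a * (ori - consts.sigma_a)))
        return qg * qa

    ga, aa = _sobel_strength_orientation(a)
    gb, ab = _sobel_strength_orientation(b)
    qaf = preservation(ga, aa)
    qbf = preservation(gb, ab)
    denom = (ga + gb).sum()
    if denom == 0:
        warnings.warn("both sources are gradient-free; QAB/F set to 0")
        return 0.0
    return float((qaf * ga + qbf * gb).sum() / denom)


def evaluate_fusion(
    a: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    window: int = 7,
    consts: EdgeMetricConstants | None = None,
) -> MetricReport:
    """Compute the full (QMI, QY, QAB/F) report for a fused image."""
    return MetricReport(
        qmi=qmi(a, b, f), qy=qy(a, b, f, window=window), qabf=qabf(a, b, f, consts=consts)
    )
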