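"""Combine saliency maps into per-source weight maps and normalize them.

The weight of source ``n`` at pixel ``k`` is ``VS^alpha * GM^beta * CD^gamma``
on the normalized saliency maps; a per-pixel argmax then assigns each pixel
to the single most salient source, and normalization restores a per-pixel
partition of unity (which only redistributes exact ties after the argmax).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .saliency import SaliencyBundle

__all__ = [
    "ExponentParams",
    "combine_saliencies",
    "argmax_binarize",
    "normalize_weights",
]


@dataclass(frozen=True)
class ExponentParams:
    """Relative-importance exponents of the VS, GM and CD maps.

    Defaults are the reference setting ``alpha=1, beta=0.89, gamma=0.31``;
    an exponent of zero ignores the corresponding map (``0**0 == 1``).
    """

    alpha: float = 1.0
    beta: float = 0.89
    gamma: float = 0.31

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("exponents must be nonnegative")
        if self.alpha == self.beta == self.gamma == 0:
            raise ValueError("at least one exponent must be positive")


def combine_saliencies(
    bundles: Sequence[SaliencyBundle], exps: ExponentParams | None = None
) -> np.ndarray:
    """Per-source weights ``VS^alpha * GM^beta * CD^gamma`` as an (N, H, W) stack."""
    exps = exps or ExponentParams()
    if not bundles:
        raise ValueError("need at least one saliency bundle")
    shape = bundles[0].shape
    if any(b.shape != shape for b in bundles):
        raise ValueError("all saliency bundles must share one shape")
    weights = []
    for b in bundles:
        if min(b.vs.min(), b.gm.min(), b.cd.min()) < 0:
            raise ValueError("saliency maps must be nonnegative (rectify upstream)")
        weights.append(b.vs**exps.alpha * b.gm**exps.beta * b.cd**exps.gamma)
    return np.stack(weights)


def argmax_binarize(stack: np.ndarray) -> np.ndarray:
    """One-hot per-pixel winner map; ties go to the lowest source index."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("expected an (N, H, W) stack with N >= 2")
    winner = np.argmax(stack, axis=0)  # argmax picks the lowest index on ties
    out = np.zeros_like(stack)
    n_idx = np.arange(stack.shape[0])[:, None, None]
    out[:] = (winner[None] == n_idx).astype(float)
    return out


def normalize_weights(stack: np.ndarray) -> np.ndarray:
    """Per-pixel division by the sum; all-zero pixels get the uniform 1/N."""
    stack = np.asarray(stack, dtype=float)
    if stack.min() < 0:
        raise ValueError("weights must be nonnegative")
    total = stack.sum(axis=0)
    n = stack.shape[0]
    out = np.where(total[None] > 0, stack / np.where(total[None] > 0, total[None], 1.0), 1.0 / n)
    return out
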