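"""Image reading and writing.

Loaders accept PNG/TIFF/JPEG in 8- or 16-bit and emit float RGB arrays in
[0, 1]; writers quantize to 8-bit PNG by default, with a 16-bit option for
pipelines where 8-bit quantization is too coarse.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .colorspace import validate_color_image

__all__ = ["load_image", "save_image"]


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as a float RGB array in [0, 1].

    Grayscale input is replicated to three channels; an alpha channel is
    dropped.  8-/16-bit integer data are rescaled by their type maximum.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 2:
        arr = np.dstack([arr] * 3)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
        if arr.max() > 1.0:  # float TIFFs sometimes carry 0..255
            arr = arr / 255.0
    return validate_color_image(arr)


def save_image(path: str | Path, img: np.ndarray, bit_depth: int = 8) -> None:
    """Write an image (RGB or single plane) as 8-bit PNG/TIFF or 16-bit TIFF.

    16-bit color output requires a ``.tif``/``.tiff`` path: the available
    PNG backend only handles 8-bit RGB.
    """
    path = Path(path)
    img = np.asarray(img, dtype=float)
    img = np.clip(img, 0.0, 1.0)
    if bit_depth == 8:
        data = np.round(img * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("16-bit output requires a .tif/.tiff path")
        data = np.round(img * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(path, data)
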