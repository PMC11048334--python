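"""Image reading and writing (PNG/TIFF/JPEG, 8-bit)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InputError
from .preprocess import BinaryImage


def read_image(path) -> np.ndarray:
    """Read a micrograph as uint8 grayscale (H, W) or RGB (H, W, 3).

    RGBA images are flattened onto their colour channels; 16-bit images
    are rescaled to 8-bit.
    """
    img = iio.imread(Path(path))
    if img.dtype == np.uint16:
        img = (img // 257).astype(np.uint8)
    elif img.dtype != np.uint8:
        img = np.clip(np.rint(np.asarray(img, dtype=np.float64)), 0, 255).astype(
            np.uint8
        )
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    if img.ndim not in (2, 3):
        raise InputError(f"unsupported image layout {img.shape} in {path}")
    return img


def write_mask(mask: BinaryImage, path) -> None:
    """Write a binary wall/void mask as 8-bit PNG (0 = wall, 255 = void)."""
    iio.imwrite(Path(path), np.where(mask.mask, 255, 0).astype(np.uint8))


def read_mask(path, threshold_used: int = 127) -> BinaryImage:
    """Read a mask written by :func:`write_mask` back into a BinaryImage."""
    img = read_image(path)
    if img.ndim == 3:
        img = img[..., 0]
    return BinaryImage(mask=img > 127, threshold_used=threshold_used)
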