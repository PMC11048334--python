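"""Micrograph preprocessing: smoothing, grayscale conversion and Otsu binarization.

The measurement chain turns a stained wood cross-section photograph into a
binary wall/void mask:

1. Gaussian smoothing of the colour image (denoising; binarization is very
   sensitive to pixel noise),
2. conversion to 8-bit grayscale (ITU-R BT.601 luma weights),
3. a global threshold from Otsu's method, computed per image from the
   bimodal gray-level histogram (dark mode = cell walls, light mode =
   lumens and intercellular voids),
4. thresholding: pixels above the threshold are void, pixels at or below
   it are wall.

All functions operate on plain numpy arrays: RGB images are ``(H, W, 3)``
uint8, grayscale images ``(H, W)`` uint8, with rows = tangential direction
and columns = radial direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateHistogramError, InputError, ParameterError

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Default standard deviation (pixels) of the Gaussian denoising kernel.
DEFAULT_SIGMA = 2.0


@dataclass(frozen=True)
class BinaryImage:
    """A wall/void mask plus the threshold that produced it.

    ``mask`` is boolean, ``True`` for void (lumen) pixels and ``False`` for
    cell-wall pixels.  ``threshold_used`` is the gray level t such that
    source pixels > t were classified as void.
    """

    mask: np.ndarray
    threshold_used: int

    def __post_init__(self) -> None:
        if self.mask.ndim != 2:
            raise InputError("binary mask must be 2-D")
        if not (0 <= self.threshold_used <= 254):
            raise ParameterError(
                f"threshold {self.threshold_used} outside [0, 254]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def void_fraction(self) -> float:
        """Overall porosity of the mask (void pixels / all pixels)."""
        return float(self.mask.mean())


def _check_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img)
    if img.size == 0:
        raise InputError(f"{name} is empty")
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 3:
        return img
    raise InputError(
        f"{name} must be (H, W) grayscale or (H, W, 3) RGB, got shape {img.shape}"
    )


def gaussian_smooth(img: np.ndarray, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Smooth an RGB or grayscale image with a normalized Gaussian kernel.

    The kernel is truncated at radius ``ceil(3*sigma)`` and borders are
    handled by reflection.  RGB images are smoothed per channel.  The
    result is rounded and clipped back to uint8.
    """
    img = _check_image(img)
    if not (sigma > 0):
        raise ParameterError(f"sigma must be positive, got {sigma}")
    radius = math.ceil(3 * sigma)
    out = np.empty_like(img, dtype=np.float64)
    if img.ndim == 2:
        ndimage.gaussian_filter(
            img.astype(np.float64), sigma, output=out, mode="reflect", radius=radius
        )
    else:
        for c in range(3):
            ndimage.gaussian_filter(
                img[..., c].astype(np.float64),
                sigma,
                output=out[..., c],
                mode="reflect",
                radius=radius,
            )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale with BT.601 luma weights.

    Grayscale input is passed through unchanged (already one channel).
    """
    img = _check_image(img)
    if img.ndim == 2:
        return img.astype(np.uint8)
    w = np.asarray(LUMA_WEIGHTS)
    gray = img.astype(np.float64) @ w
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def gray_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin histogram of an 8-bit grayscale image.

    ``counts[i]`` is the number of pixels with gray value i; the counts sum
    to the pixel count of the image.
    """
    img = _check_image(img, "grayscale image")
    if img.ndim != 2:
        raise InputError("gray_histogram expects a single-channel image")
    return np.bincount(img.ravel().astype(np.int64), minlength=256)[:256]


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's global threshold from a 256-bin gray-level histogram.

    Returns the t in [0, 254] that minimizes the weighted within-class
    variance sigma_w^2 = w1*s1^2 + w2*s2^2 of the split {<= t} vs {> t}
    (equivalently, maximizes the between-class variance).  Only splits with
    both classes non-empty are considered; ties are broken by the smallest
    t so the result is deterministic.

    Raises :class:`DegenerateHistogramError` when fewer than two gray
    levels are populated, since no valid wall/void split exists.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise InputError(f"histogram must have 256 bins, got shape {hist.shape}")
    if np.any(hist < 0):
        raise InputError("histogram counts must be non-negative")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "histogram has fewer than two populated gray levels; "
            "no threshold separates walls from voids"
        )
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)

    # Cumulative class mass and class mean numerator for the lower class
    # {<= t}; between-class variance w1*w2*(mu1 - mu2)^2 is maximized.
    w1 = np.cumsum(hist)[:-1]                 # t = 0..254
    m1 = np.cumsum(hist * levels)[:-1]
    w2 = total - w1
    m_total = float((hist * levels).sum())

    valid = (w1 > 0) & (w2 > 0)
    mu1 = np.where(valid, m1 / np.where(w1 > 0, w1, 1), 0.0)
    mu2 = np.where(valid, (m_total - m1) / np.where(w2 > 0, w2, 1), 0.0)
    between = np.where(valid, w1 * w2 * (mu1 - mu2) ** 2, -np.inf)
    # argmax takes the first (smallest) t on ties
    return int(np.argmax(between))


def binarize(img: np.ndarray, t: int, *, invert: bool = False) -> BinaryImage:
    """Threshold a grayscale image into a void/wall mask.

    Pixels with gray value > t become void (light lumens), pixels <= t
    become wall (dark stained walls).  ``invert=True`` flips the polarity
    for images where walls are the light class.
    """
    img = _check_image(img, "grayscale image")
    if img.ndim != 2:
        raise InputError("binarize expects a single-channel image")
    t = int(t)
    if not (0 <= t <= 254):
        raise ParameterError(f"threshold must be in [0, 254], got {t}")
    mask = img > t
    if invert:
        mask = ~mask
    return BinaryImage(mask=mask, threshold_used=t)


def preprocess(
    img: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    *,
    invert: bool = False,
) -> BinaryImage:
    """Full preprocessing chain: smooth, grayscale, Otsu, binarize.

    Set ``sigma`` to 0 or None to skip smoothing.  The computed Otsu
    threshold is logged for every run.
    """
    img = _check_image(img)
    if sigma:
        img = gaussian_smooth(img, sigma)
    gray = to_grayscale(img)
    t = otsu_threshold(gray_histogram(gray))
    logger.info("Otsu threshold: %d (sigma=%s, invert=%s)", t, sigma, invert)
    return binarize(gray, t, invert=invert)
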