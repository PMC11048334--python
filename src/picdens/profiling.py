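"""The virtual porosity sensor: windowed radial scans of a binary mask.

A "virtual sensor" is a one-pixel-thick scanning line spanning a fixed
number of tangential rows (the scan-line length, default 1000 px).  At each
radial pixel position it records the porosity Por: the ratio of void
pixels to the total number of pixels on the line.  Advancing the line one
pixel at a time across a ring yields a porosity profile.

To mitigate local disturbances (rays, outsized vessels, preparation
defects), the scan is repeated in several tangentially overlapping windows
(default: 1000-px window moved in 200-px steps, giving five windows on a
1800-px-tall image) and the per-window profiles are averaged pixelwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError
from .preprocess import BinaryImage

#: Default scan-line length (tangential window height), pixels.
DEFAULT_WINDOW = 1000
#: Default tangential step between successive scan windows, pixels.
DEFAULT_STEP = 200


@dataclass(frozen=True)
class ScanArea:
    """One tangential scan window: rows [offset, offset + height)."""

    tangential_offset: int
    window_height: int

    def __post_init__(self) -> None:
        if self.window_height < 1:
            raise ParameterError("window_height must be >= 1")
        if self.tangential_offset < 0:
            raise ParameterError("tangential_offset must be >= 0")

    @property
    def rows(self) -> slice:
        return slice(self.tangential_offset, self.tangential_offset + self.window_height)


@dataclass(frozen=True)
class PorosityProfile:
    """Porosity values along the radial axis.

    ``values[k]`` is the void fraction at radial pixel ``origin + k``.
    ``scan_area`` records provenance: the window that produced the profile,
    or the string ``"averaged"`` for a window-mean profile.
    """

    values: np.ndarray
    origin: int = 0
    scan_area: ScanArea | str = "averaged"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise InputError("profile values must be a non-empty 1-D sequence")
        if np.any(v < 0) or np.any(v > 1):
            raise InputError("porosity values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size

    @property
    def radial_positions(self) -> np.ndarray:
        """Absolute radial pixel index of each value."""
        return self.origin + np.arange(self.values.size)

    def slice(self, start: int, end: int) -> "PorosityProfile":
        """Restrict to the half-open radial pixel interval [start, end)."""
        if not (self.origin <= start < end <= self.origin + len(self)):
            raise InputError(
                f"interval [{start}, {end}) outside profile "
                f"[{self.origin}, {self.origin + len(self)})"
            )
        return PorosityProfile(
            self.values[start - self.origin : end - self.origin],
            origin=start,
            scan_area=self.scan_area,
        )


@dataclass(frozen=True)
class ProfileSet:
    """Per-window porosity profiles plus their pixelwise mean."""

    per_area: list[PorosityProfile] = field(default_factory=list)
    averaged: PorosityProfile = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.per_area:
            raise InputError("profile set needs at least one scan-area profile")
        n = len(self.per_area[0])
        origin = self.per_area[0].origin
        for p in self.per_area:
            if len(p) != n or p.origin != origin:
                raise InputError("all per-area profiles must share length and origin")


def make_scan_areas(
    image_height: int,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[ScanArea]:
    """Tile the tangential extent with overlapping scan windows.

    Offsets run 0, step, 2*step, ... while the window still fits.  If the
    image is shorter than the window, a single full-height window is
    returned with a warning (the scan-line length is then the image
    height).
    """
    if window < 1 or step < 1:
        raise ParameterError("window and step must be positive")
    if image_height < 1:
        raise InputError("image height must be >= 1")
    if image_height < window:
        warnings.warn(
            f"image height {image_height} px is shorter than the scan window "
            f"{window} px; using one full-height window",
            stacklevel=2,
        )
        return [ScanArea(0, image_height)]
    n = (image_height - window) // step + 1
    return [ScanArea(i * step, window) for i in range(n)]


def scan_profile(
    mask: BinaryImage,
    area: ScanArea,
    radial_range: tuple[int, int] | None = None,
) -> PorosityProfile:
    """Scan one window of a binary mask, column by column.

    For each radial pixel in ``radial_range`` (half-open, default the full
    image width) the porosity is the number of void pixels in that column
    within the window rows, divided by the window height.  Every value is
    therefore an exact ratio of two integer counts.
    """
    h, w = mask.shape
    if area.tangential_offset + area.window_height > h:
        raise InputError(
            f"scan area rows [{area.tangential_offset}, "
            f"{area.tangential_offset + area.window_height}) exceed image height {h}"
        )
    start, end = radial_range if radial_range is not None else (0, w)
    if not (0 <= start < end <= w):
        raise InputError(f"radial range [{start}, {end}) outside image width {w}")
    block = mask.mask[area.rows, start:end]
    counts = block.sum(axis=0, dtype=np.int64)
    values = counts / area.window_height
    return PorosityProfile(values, origin=start, scan_area=area)


def profile_set(
    mask: BinaryImage,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    radial_range: tuple[int, int] | None = None,
) -> ProfileSet:
    """Scan all overlapping windows and average the profiles pixelwise.

    The averaged profile is the arithmetic mean of the per-window profiles
    at each radial position (not a single count over the union of windows;
    the two differ because windows overlap unevenly).
    """
    areas = make_scan_areas(mask.shape[0], window, step)
    profiles = [scan_profile(mask, a, radial_range) for a in areas]
    mean_values = np.mean([p.values for p in profiles], axis=0)
    averaged = PorosityProfile(
        mean_values, origin=profiles[0].origin, scan_area="averaged"
    )
    return ProfileSet(per_area=profiles, averaged=averaged)


def profile_correlation_table(pset: ProfileSet) -> list[float]:
    """Pearson r of each per-window profile against the averaged profile.

    Quantifies the tangential coherence of the measurement: high values
    mean the windows see the same radial structure, i.e. a common signal
    rather than local disturbances.  A window with zero variance yields
    ``nan`` for its entry (undefined correlation).
    """
    avg = pset.averaged.values
    if len(avg) < 3:
        raise InputError("profiles must have length >= 3 for a correlation")
    if len(pset.per_area) < 2:
        raise InputError("need at least two scan-area profiles")
    out = []
    avg_c = avg - avg.mean()
    denom_avg = float(np.sqrt((avg_c**2).sum()))
    for p in pset.per_area:
        v = p.values - p.values.mean()
        denom = float(np.sqrt((v**2).sum())) * denom_avg
        if denom == 0.0:
            out.append(float("nan"))
        else:
            out.append(float((v * avg_c).sum() / denom))
    return out
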