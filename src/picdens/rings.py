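"""Per-ring statistics and per-specimen annual series.

Growth-ring boundaries are user-supplied annotations (year label plus a
half-open radial pixel interval per ring).  For each ring, the averaged
porosity profile restricted to the ring interval yields four annual
parameters: ring width (interval length, optionally scaled to physical
units), and the maximum, mean and minimum porosity within the ring.

Profiles of rings of different widths are compared on a common support by
"compression": linear resampling onto a fixed number of points over the
relative (0..1) ring position, shortest-profile length by convention when
averaging a year across specimens.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InputError, ParameterError
from .profiling import PorosityProfile


@dataclass(frozen=True)
class RingAnnotation:
    """One annotated growth ring on a specimen image."""

    specimen_id: str
    year: int
    start_px: int
    end_px: int
    source_image: str = ""

    def __post_init__(self) -> None:
        if self.end_px <= self.start_px:
            raise InputError(
                f"ring {self.specimen_id}/{self.year}: end {self.end_px} "
                f"<= start {self.start_px}"
            )

    @property
    def width_px(self) -> int:
        return self.end_px - self.start_px


@dataclass(frozen=True)
class RingRecord:
    """Annual parameters of one ring: width and porosity extremes/mean."""

    specimen_id: str
    year: int
    ring_width_px: int
    por_max: float
    por_mean: float
    por_min: float
    profile: PorosityProfile
    ring_width_um: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.por_min <= self.por_mean <= self.por_max <= 1.0):
            raise DataError(
                f"ring {self.specimen_id}/{self.year}: porosity ordering "
                f"min <= mean <= max violated "
                f"({self.por_min}, {self.por_mean}, {self.por_max})"
            )


@dataclass(frozen=True)
class SpecimenSeries:
    """Chronologically ordered ring records of one specimen."""

    specimen_id: str
    records: tuple[RingRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError(f"specimen {self.specimen_id}: empty series")
        years = [r.year for r in self.records]
        if years != sorted(set(years)):
            raise DataError(
                f"specimen {self.specimen_id}: years not strictly increasing"
            )

    @property
    def years(self) -> list[int]:
        return [r.year for r in self.records]

    def parameter(self, name: str) -> pd.Series:
        """One annual parameter (RW, MEAN_Por, MAX_Por or MIN_Por) as a
        year-indexed series."""
        attr = {
            "RW": "ring_width_px",
            "MEAN_Por": "por_mean",
            "MAX_Por": "por_max",
            "MIN_Por": "por_min",
        }[name]
        return pd.Series(
            [getattr(r, attr) for r in self.records],
            index=pd.Index(self.years, name="year"),
            name=f"{self.specimen_id}:{name}",
            dtype=float,
        )


def ring_stats(
    profile: PorosityProfile,
    ann: RingAnnotation,
    scale_um_per_px: float | None = None,
) -> RingRecord:
    """Per-ring statistics from the averaged porosity profile.

    Max/mean/min porosity are taken over the profile restricted to the
    ring's radial interval; the ring width is the interval length in
    pixels (times the scale, if given, for micrometres).
    """
    ring = profile.slice(ann.start_px, ann.end_px)
    v = ring.values
    # guard the min <= mean <= max invariant against float round-off
    mean = min(max(float(v.mean()), float(v.min())), float(v.max()))
    return RingRecord(
        specimen_id=ann.specimen_id,
        year=ann.year,
        ring_width_px=ann.width_px,
        por_max=float(v.max()),
        por_mean=mean,
        por_min=float(v.min()),
        profile=ring,
        ring_width_um=ann.width_px * scale_um_per_px if scale_um_per_px else None,
    )


def build_series(
    annotations: list[RingAnnotation],
    profiles: dict[str, PorosityProfile],
    scale_um_per_px: float | None = None,
) -> list[SpecimenSeries]:
    """Assemble per-specimen series from annotations and averaged profiles.

    ``profiles`` maps specimen_id to that specimen's averaged porosity
    profile (covering all annotated rings).  Validates the annotation
    invariants: no duplicate (specimen, year), no overlapping intervals,
    years increasing with radial position.
    """
    by_spec: dict[str, list[RingAnnotation]] = defaultdict(list)
    for ann in annotations:
        by_spec[ann.specimen_id].append(ann)

    out = []
    for spec_id in sorted(by_spec):
        anns = sorted(by_spec[spec_id], key=lambda a: a.start_px)
        if spec_id not in profiles:
            raise DataError(f"no profile for annotated specimen {spec_id!r}")
        seen_years = set()
        prev_end = None
        prev_year = None
        for a in anns:
            if a.year in seen_years:
                raise DataError(f"duplicate ring {spec_id}/{a.year}")
            seen_years.add(a.year)
            if prev_end is not None and a.start_px < prev_end:
                raise DataError(
                    f"specimen {spec_id}: ring {a.year} interval "
                    f"[{a.start_px}, {a.end_px}) overlaps previous ring "
                    f"ending at {prev_end}"
                )
            if prev_year is not None and a.year <= prev_year:
                raise DataError(
                    f"specimen {spec_id}: years must increase with radial "
                    f"position (year {a.year} after {prev_year})"
                )
            prev_end, prev_year = a.end_px, a.year
        records = tuple(
            ring_stats(profiles[spec_id], a, scale_um_per_px) for a in anns
        )
        out.append(SpecimenSeries(spec_id, records))
    return out


def compress_profile(profile: PorosityProfile, target_length: int) -> PorosityProfile:
    """Resample a ring profile to ``target_length`` points by linear
    interpolation over relative (0..1) ring position.

    Endpoints are preserved exactly; at equal length the profile is
    returned unchanged, so compression is idempotent.
    """
    if target_length < 2:
        raise ParameterError(f"target_length must be >= 2, got {target_length}")
    n = len(profile)
    if n < 2:
        raise ParameterError("profile must have length >= 2 to resample")
    if target_length == n:
        return profile
    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, target_length)
    return PorosityProfile(
        np.interp(x_new, x_old, profile.values),
        origin=0,
        scan_area="averaged",
    )


def mean_annual_profile(records: list[RingRecord]) -> PorosityProfile:
    """Mean intra-ring profile of one year across specimens.

    All ring profiles are compressed to the shortest length present that
    year, then averaged pixelwise.
    """
    if not records:
        raise InputError("no ring records for this year")
    target = min(len(r.profile) for r in records)
    target = max(target, 2)
    compressed = [compress_profile(r.profile, target) for r in records]
    return PorosityProfile(
        np.mean([c.values for c in compressed], axis=0),
        origin=0,
        scan_area="averaged",
    )


# ---------------------------------------------------------------------------
# CSV schemas

RINGS_CSV_COLUMNS = ["specimen_id", "year", "image", "start_px", "end_px"]
SERIES_CSV_COLUMNS = [
    "specimen_id", "year", "ring_width_px", "por_max", "por_mean", "por_min",
]


def read_ring_annotations(path) -> list[RingAnnotation]:
    """Read ring annotations from a CSV with columns
    specimen_id, year, image, start_px, end_px."""
    df = pd.read_csv(path)
    missing = set(RINGS_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"annotation file {path} missing columns {sorted(missing)}")
    return [
        RingAnnotation(
            specimen_id=str(row.specimen_id),
            year=int(row.year),
            start_px=int(row.start_px),
            end_px=int(row.end_px),
            source_image=str(row.image),
        )
        for row in df.itertuples()
    ]


def write_ring_annotations(annotations: list[RingAnnotation], path) -> None:
    pd.DataFrame(
        [
            {
                "specimen_id": a.specimen_id,
                "year": a.year,
                "image": a.source_image,
                "start_px": a.start_px,
                "end_px": a.end_px,
            }
            for a in annotations
        ],
        columns=RINGS_CSV_COLUMNS,
    ).to_csv(path, index=False)


def series_to_frame(series: list[SpecimenSeries]) -> pd.DataFrame:
    """Flatten specimen series into a long table (SERIES.csv layout)."""
    rows = [
        {
            "specimen_id": s.specimen_id,
            "year": r.year,
            "ring_width_px": r.ring_width_px,
            "por_max": r.por_max,
            "por_mean": r.por_mean,
            "por_min": r.por_min,
        }
        for s in series
        for r in s.records
    ]
    return pd.DataFrame(rows, columns=SERIES_CSV_COLUMNS)
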