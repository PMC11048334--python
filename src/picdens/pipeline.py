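"""End-to-end convenience: micrograph(s) -> binary mask -> porosity
profiles -> ring series -> chronology statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as chron
from .preprocess import DEFAULT_SIGMA, preprocess
from .profiling import DEFAULT_STEP, DEFAULT_WINDOW, ProfileSet, profile_set
from .rings import RingAnnotation, SpecimenSeries, build_series
from .synthetic import SiteRender


def image_profiles(
    image: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    *,
    invert: bool = False,
) -> ProfileSet:
    """Binarize a micrograph and scan it into per-window and averaged
    porosity profiles."""
    mask = preprocess(image, sigma, invert=invert)
    return profile_set(mask, window, step)


def specimens_to_series(
    images: dict[str, np.ndarray],
    annotations: list[RingAnnotation],
    sigma: float = DEFAULT_SIGMA,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[SpecimenSeries]:
    """Run the measurement chain on a cohort of specimen panoramas."""
    profiles = {
        spec_id: image_profiles(img, sigma, window, step).averaged
        for spec_id, img in images.items()
    }
    return build_series(annotations, profiles)


def site_to_series(
    site: SiteRender,
    sigma: float = DEFAULT_SIGMA,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[SpecimenSeries]:
    """Measure a rendered synthetic cohort end to end."""
    images = {s.specimen_id: s.image for s in site.specimens}
    annotations = [a for s in site.specimens for a in s.annotations]
    return specimens_to_series(images, annotations, sigma, window, step)


def parameter_series(
    series: list[SpecimenSeries], parameter: str
) -> dict[str, pd.Series]:
    """Extract one annual parameter from every specimen series."""
    return {s.specimen_id: s.parameter(parameter) for s in series}


def site_statistics(series: list[SpecimenSeries]) -> dict:
    """The standard chronology analysis of a measured cohort.

    Returns mean inter-series correlations per parameter, the site
    chronologies, and the parameter correlation matrix with p-values.
    """
    interseries = {}
    chronologies = {}
    for p in chron.PARAMETERS:
        per_spec = parameter_series(series, p)
        if len(per_spec) >= 2:
            interseries[p] = chron.interseries_correlation(per_spec)
        chronologies[p] = chron.site_chronology(per_spec)["value"]
    r, pvals, sig = chron.parameter_correlation_matrix(chronologies)
    return {
        "interseries": interseries,
        "chronologies": chronologies,
        "param_r": r,
        "param_p": pvals,
        "param_significant": sig,
    }
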