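"""Chronology statistics: Pearson correlations, inter-series coherence,
site chronologies and significance testing.

Annual series (ring width and porosity parameters) are compared with
pairwise Pearson correlations on their common years, with two-tailed
significance from the t transform t = r*sqrt((n-2)/(1-r^2)), df = n-2.
The mean inter-series correlation of a parameter — the average pairwise r
among specimen series — measures the strength of the common external
signal driving that parameter.  A site chronology is the per-year mean of
the specimen series, with sample depth recorded.

Missing years are handled by pairwise-complete overlap, never by
imputation.  Correlations need at least ``MIN_OVERLAP`` common years;
pairs below it are dropped with a logged warning.  p-values are reported
raw (no multiple-testing correction).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, InsufficientOverlapError

logger = logging.getLogger(__name__)

#: Annual parameters measured per ring.
PARAMETERS = ("RW", "MEAN_Por", "MAX_Por", "MIN_Por")

#: Minimum number of common years for any correlation.
MIN_OVERLAP = 3


@dataclass(frozen=True)
class CorrelationResult:
    """A Pearson correlation with its overlap size and two-tailed p."""

    r: float
    n_overlap: int
    p_two_tailed: float


def pearson(x: pd.Series, y: pd.Series) -> CorrelationResult:
    """Pearson product-moment correlation on the common years of two
    year-indexed annual series.

    Significance is a two-tailed t-test with df = n - 2.  Raises
    :class:`InsufficientOverlapError` below ``MIN_OVERLAP`` common years
    and :class:`InputError` if either series is constant on the overlap
    (correlation undefined).
    """
    x = pd.Series(x).dropna()
    y = pd.Series(y).dropna()
    common = x.index.intersection(y.index)
    n = len(common)
    if n < MIN_OVERLAP:
        raise InsufficientOverlapError(
            f"only {n} common years; need at least {MIN_OVERLAP}"
        )
    xv = x.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(np.sqrt((xc**2).sum()))
    sy = float(np.sqrt((yc**2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise InputError("zero variance on the overlap; correlation undefined")
    r = float((xc * yc).sum() / (sx * sy))
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, n_overlap=n, p_two_tailed=p)


def interseries_correlation(
    series: dict[str, pd.Series],
    *,
    method: str = "pairwise",
) -> float:
    """Mean inter-series correlation of one parameter across specimens.

    ``method="pairwise"`` (default): arithmetic mean of Pearson r over all
    specimen pairs with sufficient overlap.  ``method="leave_one_out"``:
    the dendrochronological rbar convention — each series correlated with
    the mean of all the others, then averaged.

    Pairs (or specimens) with insufficient overlap or zero variance are
    excluded with a logged warning; if none remain, raises
    :class:`InputError`.
    """
    if len(series) < 2:
        raise InputError("need at least two specimen series")
    rs: list[float] = []
    if method == "pairwise":
        for (ida, a), (idb, b) in itertools.combinations(series.items(), 2):
            try:
                rs.append(pearson(a, b).r)
            except (InsufficientOverlapError, InputError) as exc:
                logger.warning("dropping pair (%s, %s): %s", ida, idb, exc)
    elif method == "leave_one_out":
        frame = pd.DataFrame(series)
        for col in frame.columns:
            others = frame.drop(columns=col).mean(axis=1)
            try:
                rs.append(pearson(frame[col], others).r)
            except (InsufficientOverlapError, InputError) as exc:
                logger.warning("dropping specimen %s: %s", col, exc)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not rs:
        raise InputError("no specimen pair with sufficient overlap")
    return float(np.mean(rs))


def site_chronology(series: dict[str, pd.Series]) -> pd.DataFrame:
    """Site chronology of one parameter: per-year mean over the specimens
    present that year, with sample depth.

    Returns a frame indexed by year with columns ``value`` (mean) and
    ``depth`` (number of specimens contributing).
    """
    if not series:
        raise InputError("no series given")
    frame = pd.DataFrame(series).sort_index()
    return pd.DataFrame(
        {"value": frame.mean(axis=1), "depth": frame.notna().sum(axis=1)}
    )


def parameter_correlation_matrix(
    chronologies: dict[str, pd.Series],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Correlation matrix among parameter chronologies (RW vs porosity
    statistics), with two-tailed p-values and a significance mask.

    Returns ``(r, p, significant)`` frames, symmetric with unit diagonal
    (p = 0 on the diagonal by the |r| = 1 convention).
    """
    names = list(chronologies)
    if len(names) < 2:
        raise InputError("need at least two chronologies")
    r = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    p = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        res = pearson(chronologies[a], chronologies[b])
        r.loc[a, b] = r.loc[b, a] = res.r
        p.loc[a, b] = p.loc[b, a] = res.p_two_tailed
    return r, p, p < alpha
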