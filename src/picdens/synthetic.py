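"""Synthetic wood cross-sections with known ground truth.

Generates micrograph-like images of angiosperm wood — light vessel lumens
(ellipses) on a dark stained cell-wall matrix, plus Gaussian pixel noise —
together with the exact porosity target that produced them.  Three
archetypes cover the anatomical range:

``ring_porous``
    Large earlywood vessels (high porosity plateau) with a sharp
    transition to dense latewood with small vessels, porosity several
    times lower.
``semi_ring_porous``
    The same contrast but a gradual, ring-wide transition of vessel size
    and porosity.
``diffuse_porous``
    Vessels of one size spread evenly across the ring; porosity declines
    gently and drops in a dense terminal band at the ring boundary.

Vessels are laid out on tangential rows whose radial phases follow a
golden-ratio (low-discrepancy) sequence with random jitter, and the local
vessel spacing is set so that vessel area per unit area equals the target
porosity P(x).  The realized column void fraction therefore tracks P(x)
closely (it is P convolved with the vessel chord profile plus small
residual placement noise).  Rows are spaced so vessels never overlap,
keeping realized porosity additive.

Multi-year specimens concatenate rings radially; a cohort of specimens
shares an annual signal: each specimen's ring-level porosity shift is
``sigma_por * (sqrt(s)*z_year + sqrt(1-s)*eps)`` with z the common
standard-normal signal and eps specimen noise, so the expected
inter-series correlation of the porosity parameters equals the signal
share s.  Ring widths are drawn independently per specimen, carrying no
common signal.

All randomness comes from ``numpy.random.Generator`` (PCG64): the same
seed reproduces images bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GenerationError, ParameterError
from .rings import RingAnnotation, write_ring_annotations

_GOLDEN = 0.6180339887498949


@dataclass(frozen=True)
class WoodArchetype:
    """Anatomical parameters of a synthetic wood type.

    Porosities are void-area fractions in (0, 1); radii are tangential
    vessel semi-axes in pixels.  ``transition_center``/``transition_width``
    position the early-to-latewood porosity transition as fractions of the
    ring width.  ``terminal_band``: relative width of the dense band at
    the ring boundary (diffuse-porous habit; 0 disables it).
    ``hf_amplitude``/``hf_period``: optional sinusoidal porosity
    oscillation (relative amplitude, period in pixels; off by default).
    """

    kind: str
    porosity_early: float
    porosity_late: float
    radius_early: float
    radius_late: float
    transition_center: float = 0.35
    transition_width: float = 0.06
    terminal_band: float = 0.0
    radial_slope: float = 0.0
    hf_amplitude: float = 0.0
    hf_period: float = 30.0
    wall_rgb: tuple[int, int, int] = (88, 48, 98)
    lumen_rgb: tuple[int, int, int] = (228, 221, 232)
    noise_sigma: float = 8.0
    # Relative amplitude and correlation length (px) of an optional
    # smooth brightness texture of lumens (uneven illumination, mounting
    # medium, cell contents); off by default.
    lumen_texture: float = 0.0
    texture_scale: float = 15.0

    @property
    def max_radius(self) -> float:
        return max(self.radius_early, self.radius_late)

    @property
    def row_spacing(self) -> float:
        """Tangential spacing of vessel rows; guarantees no vertical
        overlap at the largest tangential semi-axis (r/sqrt(e_min))."""
        return 2.0 * self.max_radius / math.sqrt(_ECC_LO) + 2.0


RING_POROUS = WoodArchetype(
    kind="ring_porous",
    porosity_early=0.50,
    porosity_late=0.15,
    radius_early=9.0,
    radius_late=5.0,
    transition_center=0.35,
    transition_width=0.09,
)

SEMI_RING_POROUS = WoodArchetype(
    kind="semi_ring_porous",
    porosity_early=0.45,
    porosity_late=0.18,
    radius_early=8.0,
    radius_late=5.0,
    transition_center=0.5,
    transition_width=0.22,
)

DIFFUSE_POROUS = WoodArchetype(
    kind="diffuse_porous",
    porosity_early=0.31,
    porosity_late=0.15,
    radius_early=6.5,
    radius_late=6.5,
    transition_center=0.88,
    transition_width=0.035,
    terminal_band=0.12,
    radial_slope=-0.04,
)

ARCHETYPES = {
    a.kind: a for a in (RING_POROUS, SEMI_RING_POROUS, DIFFUSE_POROUS)
}


def archetype(name: str) -> WoodArchetype:
    """Look up a preset archetype by kind name."""
    try:
        return ARCHETYPES[name]
    except KeyError:
        raise ParameterError(
            f"unknown archetype {name!r}; choose from {sorted(ARCHETYPES)}"
        ) from None


def low_contrast(arch: WoodArchetype) -> WoodArchetype:
    """A hard-mode variant: weak stain contrast and strong pixel noise,
    stressing the threshold selection."""
    return dataclasses.replace(
        arch,
        wall_rgb=(118, 100, 122),
        lumen_rgb=(168, 158, 172),
        noise_sigma=16.0,
    )


def porosity_target(
    arch: WoodArchetype, width_px: int, delta: float = 0.0
) -> np.ndarray:
    """Target porosity P(x) for each radial pixel of a ring.

    A logistic early-to-latewood transition, an optional linear radial
    slope, an optional dense terminal band, an optional high-frequency
    sinusoid, plus a uniform additive shift ``delta`` (the annual
    anomaly).  Values are clipped to stay renderable at the low end.
    """
    if width_px < 30:
        raise ParameterError(f"ring width must be >= 30 px, got {width_px}")
    x = np.arange(width_px, dtype=np.float64)
    rel = x / width_px
    tw = max(arch.transition_width * width_px, 1.0)
    late_weight = 1.0 / (
        1.0 + np.exp(-(x - arch.transition_center * width_px) / (tw / 4.0))
    )
    p = arch.porosity_early + (arch.porosity_late - arch.porosity_early) * late_weight
    if arch.radial_slope:
        p = p + arch.radial_slope * rel
    if arch.terminal_band > 0:
        band = 1.0 / (
            1.0
            + np.exp(
                -(rel - (1.0 - arch.terminal_band))
                / (arch.terminal_band / 3.0)
            )
        )
        p = p + (arch.porosity_late - p) * band
    if arch.hf_amplitude:
        p = p * (1.0 + arch.hf_amplitude * np.sin(2.0 * np.pi * x / arch.hf_period))
    return np.clip(p + delta, 0.02, 0.95)


def vessel_radii(arch: WoodArchetype, width_px: int) -> np.ndarray:
    """Tangential vessel semi-axis at each radial pixel (early-to-late
    logistic, matching the porosity transition)."""
    x = np.arange(width_px, dtype=np.float64)
    tw = max(arch.transition_width * width_px, 1.0)
    late_weight = 1.0 / (
        1.0 + np.exp(-(x - arch.transition_center * width_px) / (tw / 4.0))
    )
    return arch.radius_early + (arch.radius_late - arch.radius_early) * late_weight


# Vessel aspect range: each vessel is an area-preserving ellipse with
# radial semi-axis r*sqrt(e) and tangential semi-axis r/sqrt(e), slightly
# compressed radially as in real cross-sections.  Keeping the area at
# pi*r^2 regardless of shape keeps the porosity budget exact.
_ECC_LO, _ECC_HI = 0.93, 1.0

# Random jitter of each vessel row's radial phase, as a fraction of the
# local vessel spacing.
_PHASE_JITTER = 0.02


def feasible_porosity_max(arch: WoodArchetype, radius: float) -> float:
    """Largest porosity renderable at a given vessel radius (densest
    packing with the minimum in-row spacing)."""
    return (
        math.pi * radius * radius
        / ((2.0 * radius + 1.0) * arch.row_spacing)
    )


def _check_feasible(arch: WoodArchetype, p: np.ndarray, r: np.ndarray) -> None:
    pmax = math.pi * r * r / ((2.0 * r + 1.0) * arch.row_spacing)
    if np.any(p > pmax):
        worst = int(np.argmax(p - pmax))
        raise GenerationError(
            f"target porosity {p[worst]:.3f} at radial pixel {worst} exceeds "
            f"the maximum {pmax[worst]:.3f} renderable with vessel radius "
            f"{r[worst]:.1f} px"
        )


def _stamp_ellipse(void, cx, cy, rx, ry, col_lo, col_hi):
    h = void.shape[0]
    x0 = max(col_lo, int(math.floor(cx - rx)))
    x1 = min(col_hi - 1, int(math.ceil(cx + rx)))
    y0 = max(0, int(math.floor(cy - ry)))
    y1 = min(h - 1, int(math.ceil(cy + ry)))
    if x0 > x1 or y0 > y1:
        return
    xs = (np.arange(x0, x1 + 1) - cx) / rx
    ys = (np.arange(y0, y1 + 1) - cy) / ry
    inside = ys[:, None] ** 2 + xs[None, :] ** 2 <= 1.0
    void[y0 : y1 + 1, x0 : x1 + 1] |= inside


def _chord_smooth(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Convolve a porosity target with the local vessel chord profile.

    A vessel of radial semi-axis r spreads its area over columns with
    chord weights sqrt(1 - (u/r)^2); the realized column porosity is the
    placement density convolved with this kernel."""
    out = np.empty_like(p)
    n = p.size
    for i in range(n):
        half = max(int(math.ceil(r[i])), 1)
        u = np.arange(-half, half + 1, dtype=np.float64)
        w = np.sqrt(np.clip(1.0 - (u / max(r[i], 1.0)) ** 2, 0.0, None))
        idx = np.clip(i + np.arange(-half, half + 1), 0, n - 1)
        out[i] = float((p[idx] * w).sum() / w.sum())
    return out


def _deconvolved(p: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Pre-compensate a porosity target for chord smoothing by van
    Cittert deconvolution (fixed-point steps e <- e + (p - chord*e)),
    with the total correction capped so sharp transitions are not
    over-sharpened."""
    p_eff = p.copy()
    for _ in range(4):
        p_eff = p_eff + (p - _chord_smooth(p_eff, r))
    corr = np.clip(p_eff - p, -0.5 * p, 0.5 * p)
    return np.clip(p + corr, 0.015, None)


def _render_ring_mask(
    void: np.ndarray,
    col0: int,
    p: np.ndarray,
    r: np.ndarray,
    arch: WoodArchetype,
    rng: np.random.Generator,
    p_eff: np.ndarray | None = None,
) -> None:
    """Place vessels for a ring (or whole panorama) into the void mask
    columns [col0, col0 + len(p)).

    Vessel centers are placed by inverting the cumulative target density,
    so the local vessel area per unit area tracks P(x) without lag; the
    target is first sharpened by deconvolution against the vessel chord
    kernel (``p_eff``; computed here if not supplied), since rasterized
    vessels spread their area over ~2r columns.  The placement walk
    extends one vessel diameter past both edges (drawing clipped to the
    target's columns) so edge columns are not porosity-starved.
    """
    _check_feasible(arch, p, r)
    height = void.shape[0]
    width = p.size
    sy = arch.row_spacing
    pad = int(math.ceil(2.0 * arch.max_radius + 2.0))

    # The deconvolution may overshoot at sharp transitions; clip it to
    # the packing ceiling rather than reject.
    ceiling = 0.98 * math.pi * r * r / ((2.0 * r + 1.0) * arch.row_spacing)
    if p_eff is None:
        p_eff = _deconvolved(p, r)
    p_eff = np.minimum(p_eff, ceiling)

    # Extended domain [-pad, width+pad) with edge-clamped targets.
    ext = np.concatenate([np.full(pad, p_eff[0]), p_eff, np.full(pad, p_eff[-1])])
    r_ext = np.concatenate([np.full(pad, r[0]), r, np.full(pad, r[-1])])
    xs = np.arange(ext.size, dtype=np.float64) - pad

    # Vessel linear density (vessels per radial pixel per row) and its
    # cumulative integral.  Each row places its vessels at the quantiles
    # of this shared field, offset by a golden-ratio phase sequence:
    # every row realizes the target density exactly while the phases stay
    # stratified across rows, so per-column porosity tracks p_eff with
    # minimal ripple.
    lam = ext * sy / (math.pi * r_ext**2)
    cum = np.cumsum(lam)
    cum -= cum[0]
    # Round up: quantile targets past the integral clamp onto the far
    # edge of the padded domain and are clipped away, while rounding down
    # would leave the ring tail short of vessels.
    n_vessels = int(math.ceil(cum[-1]))

    n_rows = int(math.ceil(height / sy)) + 1
    phase0 = rng.random()
    for k in range(n_rows):
        cy = (k + 0.5) * sy + rng.uniform(-0.5, 0.5)
        if cy - arch.max_radius > height:
            break
        phase = (phase0 + k * _GOLDEN
                 + rng.uniform(-_PHASE_JITTER, _PHASE_JITTER)) % 1.0
        centers = np.interp(phase + np.arange(n_vessels), cum, xs)
        radii = np.interp(centers, xs, r_ext)
        shapes = np.sqrt(rng.uniform(_ECC_LO, _ECC_HI, n_vessels))
        for cx, rad, sq in zip(centers, radii, shapes):
            # area-preserving ellipse: shape varies, porosity budget exact
            _stamp_ellipse(void, col0 + cx, cy, rad * sq, rad / sq, col0, col0 + width)


def _to_rgb(
    void: np.ndarray, arch: WoodArchetype, rng: np.random.Generator
) -> np.ndarray:
    from scipy import ndimage

    wall = np.asarray(arch.wall_rgb, dtype=np.float32)
    lumen = np.asarray(arch.lumen_rgb, dtype=np.float32)
    img = np.where(void[..., None], lumen, wall)
    if arch.lumen_texture > 0:
        field = ndimage.gaussian_filter(
            rng.standard_normal(void.shape, dtype=np.float32),
            arch.texture_scale,
        )
        sd = float(field.std())
        if sd > 0:
            field /= sd
        mod = np.where(void, 1.0 + arch.lumen_texture * field, 1.0)
        img = img * mod[..., None].astype(np.float32)
    if arch.noise_sigma > 0:
        img = img + arch.noise_sigma * rng.standard_normal(
            img.shape, dtype=np.float32
        )
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class RingTruth:
    """Ground truth for one rendered ring."""

    year: int
    width_px: int
    delta: float
    porosity: np.ndarray  # target P(x), one value per radial pixel

    @property
    def por_max(self) -> float:
        return float(self.porosity.max())

    @property
    def por_mean(self) -> float:
        return float(self.porosity.mean())

    @property
    def por_min(self) -> float:
        return float(self.porosity.min())


def render_ring(
    arch: WoodArchetype,
    width_px: int = 300,
    window_height: int = 1800,
    *,
    delta: float = 0.0,
    year: int = 0,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, RingTruth]:
    """Render a single growth ring as an RGB micrograph.

    Returns the image (``window_height`` x ``width_px`` x 3, uint8) and
    the ground truth (target porosity per radial pixel).  The same seed
    renders the identical image.
    """
    rng = np.random.default_rng(rng)
    p = porosity_target(arch, width_px, delta)
    r = vessel_radii(arch, width_px)
    void = np.zeros((window_height, width_px), dtype=bool)
    _render_ring_mask(void, 0, p, r, arch, rng)
    img = _to_rgb(void, arch, rng)
    return img, RingTruth(year=year, width_px=width_px, delta=delta, porosity=p)


@dataclass(frozen=True)
class SpecimenRender:
    """One rendered specimen: panorama image, ring annotations, truth."""

    specimen_id: str
    image: np.ndarray
    annotations: tuple[RingAnnotation, ...]
    rings: tuple[RingTruth, ...]


def _safe_delta_band(arch: WoodArchetype, width_px: int) -> tuple[float, float]:
    """Range of additive porosity anomalies that keeps the ring
    renderable (after deconvolution the densest zone must stay below the
    packing ceiling) and above a floor of 0.03."""
    p = porosity_target(arch, width_px, 0.0)
    r = vessel_radii(arch, width_px)
    pmax = math.pi * r * r / ((2.0 * r + 1.0) * arch.row_spacing)
    hi = float(np.min(0.97 * pmax - p)) - 5e-3
    lo = float(0.03 - np.min(p))
    return lo, hi


def render_specimen(
    arch: WoodArchetype,
    n_years: int = 30,
    *,
    specimen_id: str = "S01",
    start_year: int = 1991,
    signal: np.ndarray | None = None,
    signal_share: float = 0.5,
    sigma_por: float = 0.04,
    mean_ring_width: int = 150,
    width_cv: float = 0.12,
    window_height: int = 600,
    rng: np.random.Generator | int | None = None,
) -> SpecimenRender:
    """Render a multi-year specimen panorama with known annual anomalies.

    ``signal`` is the cohort's common standard-normal annual series (one
    value per year); each ring's porosity shift is
    ``sigma_por * (sqrt(s)*signal + sqrt(1-s)*noise)`` so porosity
    parameters carry an inter-series correlation of ``signal_share``
    across specimens sharing the signal.  Ring widths are independent
    draws around ``mean_ring_width`` and carry no common signal.
    """
    if n_years < 2:
        raise ParameterError("a specimen needs at least 2 years")
    if not (0.0 <= signal_share <= 1.0):
        raise ParameterError("signal_share must be in [0, 1]")
    rng = np.random.default_rng(rng)
    if signal is None:
        signal = rng.standard_normal(n_years)
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size != n_years:
        raise ParameterError("signal length must equal n_years")

    eps = rng.standard_normal(n_years)
    anomalies = sigma_por * (
        math.sqrt(signal_share) * signal + math.sqrt(1.0 - signal_share) * eps
    )

    widths = np.rint(
        np.clip(
            rng.normal(mean_ring_width, width_cv * mean_ring_width, n_years),
            max(30, 0.5 * mean_ring_width),
            1.6 * mean_ring_width,
        )
    ).astype(int)

    lo, hi = _safe_delta_band(arch, int(widths.min()))
    anomalies = np.clip(anomalies, lo, hi)

    total = int(widths.sum())
    void = np.zeros((window_height, total), dtype=bool)
    annotations = []
    truths = []
    col = 0
    # One continuous porosity/radius field over the whole panorama: the
    # vessel field is rendered in a single pass so vessels straddle ring
    # boundaries naturally instead of being cut at a seam.  The chord
    # deconvolution is applied ring by ring (edge-clamped) so the
    # boundary discontinuity itself is not over-sharpened.
    p_parts, r_parts, eff_parts = [], [], []
    for i in range(n_years):
        w = int(widths[i])
        year = start_year + i
        p = porosity_target(arch, w, float(anomalies[i]))
        rr = vessel_radii(arch, w)
        p_parts.append(p)
        r_parts.append(rr)
        eff_parts.append(_deconvolved(p, rr))
        annotations.append(
            RingAnnotation(
                specimen_id=specimen_id,
                year=year,
                start_px=col,
                end_px=col + w,
                source_image=f"{specimen_id}.png",
            )
        )
        truths.append(
            RingTruth(year=year, width_px=w, delta=float(anomalies[i]), porosity=p)
        )
        col += w
    _render_ring_mask(
        void, 0, np.concatenate(p_parts), np.concatenate(r_parts), arch, rng,
        p_eff=np.concatenate(eff_parts),
    )
    img = _to_rgb(void, arch, rng)
    return SpecimenRender(
        specimen_id=specimen_id,
        image=img,
        annotations=tuple(annotations),
        rings=tuple(truths),
    )


@dataclass(frozen=True)
class SiteRender:
    """A cohort of specimens sharing one annual signal."""

    archetype: WoodArchetype
    specimens: tuple[SpecimenRender, ...]
    signal: np.ndarray
    signal_share: float
    sigma_por: float
    start_year: int

    def manifest(self) -> dict:
        """Ground truth sufficient to recompute every expected pipeline
        output without the images."""
        return {
            "archetype": self.archetype.kind,
            "signal_share": self.signal_share,
            "sigma_por": self.sigma_por,
            "signal": [float(v) for v in self.signal],
            "start_year": self.start_year,
            "specimens": {
                s.specimen_id: [
                    {
                        "year": t.year,
                        "width_px": t.width_px,
                        "delta": t.delta,
                        "por_max": t.por_max,
                        "por_mean": t.por_mean,
                        "por_min": t.por_min,
                    }
                    for t in s.rings
                ]
                for s in self.specimens
            },
        }

    def save(self, out_dir) -> None:
        """Write PNG panoramas, a RINGS.csv annotation file and a
        truth.json manifest."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        annotations = []
        for s in self.specimens:
            iio.imwrite(out / f"{s.specimen_id}.png", s.image)
            annotations.extend(s.annotations)
        write_ring_annotations(annotations, out / "RINGS.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def render_site(
    arch: WoodArchetype,
    n_specimens: int = 12,
    n_years: int = 30,
    *,
    signal_share: float = 0.5,
    sigma_por: float = 0.04,
    mean_ring_width: int = 150,
    window_height: int = 600,
    start_year: int = 1991,
    rng: np.random.Generator | int | None = None,
) -> SiteRender:
    """Render a cohort of specimens with a shared annual signal."""
    if n_specimens < 1:
        raise ParameterError("need at least one specimen")
    rng = np.random.default_rng(rng)
    signal = rng.standard_normal(n_years)
    specimens = []
    for i in range(n_specimens):
        specimens.append(
            render_specimen(
                arch,
                n_years,
                specimen_id=f"S{i + 1:02d}",
                start_year=start_year,
                signal=signal,
                signal_share=signal_share,
                sigma_por=sigma_por,
                mean_ring_width=mean_ring_width,
                window_height=window_height,
                rng=rng,
            )
        )
    return SiteRender(
        archetype=arch,
        specimens=tuple(specimens),
        signal=signal,
        signal_share=signal_share,
        sigma_por=sigma_por,
        start_year=start_year,
    )
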