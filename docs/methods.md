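# Methods

## The measurement model

A stained wood cross-section photographed in transmitted light is, to a
good approximation, a two-phase image: dark lignified cell walls and
light voids (cell lumens and intercellular spaces). Pixel-contrast
densitometry exploits this: after classifying every pixel into one of
the two phases, the void *area fraction* of any region — the porosity —
is a direct structural analogue of (inverse) wood density, without the
wood-matter-density calibration that converting to g/cm³ would require.
The package stops at porosity; no density conversion is applied.

The classification chain is: Gaussian smoothing → grayscale → global
Otsu threshold → binary mask. Smoothing is applied per RGB channel
*before* grayscale conversion; its purpose is noise suppression, since
global thresholding is sensitive to single-pixel outliers. The Otsu
threshold minimizes the weighted within-class variance
ω₁σ₁² + ω₂σ₂² over all 255 splits of the 256-bin histogram, with both
classes required non-empty and ties broken by the smallest threshold so
runs are deterministic. Images with a single populated gray level are
rejected (no wall/void split exists) rather than silently classified.
Walls are the dark class (≤ t) by default; a polarity flag handles
negative-stained material.

The porosity profile is produced by a *virtual sensor*: a one-pixel-wide
scanning line spanning a fixed number of tangential rows. Each profile
value is an exact ratio of two integer counts (void pixels on the line /
line length), which the tests exploit: profile values are compared
*exactly* against independent tallies. Scanning is repeated in
overlapping tangential windows and the per-window profiles averaged
pixelwise. The averaged profile is defined as the mean of window
profiles, not a single count over the union of rows — the two differ
because overlapping windows weight interior rows more heavily, and the
per-window reading is what the window-coherence analysis (correlating
each window against the average) requires.

## Coordinate and data conventions

Radial growth direction = image columns, increasing from pith to bark;
tangential = rows. Ring annotations are 0-based half-open pixel
intervals `[start, end)` with strictly increasing years along the
radius; they are user-supplied (no automatic boundary detection).
Porosities are unitless fractions in [0, 1]; widths are pixels, with an
optional µm/px scale. Profiles of different rings are compared after
*compression*: linear interpolation onto a fixed number of points over
relative ring position (endpoints preserved; idempotent at equal
length). When a year is averaged across specimens, profiles are
compressed to the shortest profile present that year.

## Statistics

All series comparisons use Pearson correlation on pairwise-complete
overlapping years (minimum 3; pairs below the minimum are dropped with a
logged warning, never imputed). Significance is the two-tailed t-test
with t = r·√((n−2)/(1−r²)), df = n−2; p-values are reported raw, without
multiple-testing correction. The mean inter-series correlation of a
parameter is the arithmetic mean of pairwise r between specimen series
(the leave-one-out "rbar" convention — each series against the mean of
the others — is available behind a flag). Site chronologies are per-year
arithmetic means over the specimens present, with sample depth recorded.

## The synthetic-wood generator

The generator is the package's ground-truth instrument: it renders
images whose expected porosity profile is known exactly, so every
pipeline stage can be validated end to end.

**Targets.** Each archetype defines a porosity target P(x) over relative
ring position: ring-porous (earlywood plateau 0.50, logistic transition
to 0.15 latewood, vessel radii 9→5 px), semi-ring-porous (0.45→0.18,
gradual transition, radii 8→5 px), diffuse-porous (0.31 with a −0.04
linear decline, a dense terminal band at 0.15 over the last 12 %, radius
6.5 px). An optional sinusoidal modulation emulates high-frequency
vessel-row alternation (off by default). Annual anomalies shift P(x)
additively: for specimen i and year y,
δ_iy = σ_por·(√s·z_y + √(1−s)·ε_iy) with z the cohort-common
standard-normal signal, ε specimen noise, σ_por = 0.04 and s the
common-signal share — so the expected inter-series correlation of every
porosity parameter equals s. Ring widths are drawn independently per
specimen (mean 150 px, CV 0.12 by default) and carry no common signal.
Anomalies are clipped to the band renderable by the vessel geometry;
with the default archetypes the clip is ≥ ±2.5σ_por and essentially
never binds.

**Rendering.** Vessels are area-preserving ellipses (semi-axes r√e,
r/√e with e ∈ [0.93, 1]) on tangential rows spaced so vessels never
overlap. Within a row, vessel centers sit at the quantiles of a shared
cumulative density field λ(x) = P_eff(x)·s_y/(πr(x)²), with per-row
phases following a golden-ratio low-discrepancy sequence plus small
jitter: each row realizes the target density exactly while phases stay
stratified across rows, keeping the per-column ripple of the realized
porosity small (σ ≈ 0.01 at 1800 rows). P_eff is the target sharpened by
a capped van Cittert deconvolution against the local vessel chord
kernel, compensating the fact that a rasterized vessel spreads its area
over ~2r columns. Multi-ring specimens are rendered as one continuous
vessel field (deconvolution applied ring-wise), so ring boundaries have
no clipped-vessel seams. Intensities: walls ≈ (88, 48, 98) RGB, lumens
≈ (228, 221, 232), i.i.d. Gaussian pixel noise σ = 8 by default; a
low-contrast preset and an optional smooth lumen-brightness texture
stress the thresholding. All randomness comes from numpy's PCG64; a
fixed seed reproduces images bit for bit.

**What the generator does *not* emulate** — and hence what passing tests
do not establish about real material: rays and axial parenchyma,
non-elliptical or collapsed cells, staining gradients and mounting
artifacts, skewed or wavy ring boundaries (rings are scanned as-is, with
no deskewing), crossdating errors in the annotations, and any optical
point-spread beyond the hard two-tone rendering. Results on real
micrographs depend additionally on section preparation quality, which
the multi-window averaging mitigates but cannot remove.

## Numerical choices and degenerate inputs

* Otsu: smallest optimal threshold on ties; degenerate histograms raise.
* Thresholding polarity is recorded with every mask (`threshold_used`).
* Smoothing kernel truncated at radius ⌈3σ⌉, reflective borders; output
  rounded and clipped to uint8.
* Images shorter than the scan window fall back to one full-height
  window with a warning.
* Zero-variance profiles yield NaN window correlations (flagged, not
  raised); zero-variance annual series raise on correlation.
* Per-ring mean porosity is clamped into [min, max] to guard the
  ordering invariant against float round-off.
* Correlations require ≥ 3 overlapping years; excluded pairs are logged.

## Validation design and problem sizes

The published correlation tables for this method were computed from
photographs that are available only on request, so validation is
property-based on synthetic material. Sizes were chosen to keep the full
validation run at a few minutes on one CPU while leaving the statistics
well-resolved:

* Threshold optimality: 1000 random histograms vs exhaustive search.
* Porosity exactness: 100 random masks, every value vs an integer tally.
* Window coherence and profile recovery: one 300×1800 px ring per
  archetype at the default 1000/200 scan geometry.
* Ring-statistic recovery: a diffuse-porous cohort of 12 specimens ×
  30 years, 140 px mean ring width, 2500 px panoramas (700/450 scans);
  worst-case per-ring error vs target max/mean/min porosity ≤ ±0.03.
* Inter-series recovery: 20 replicate cohorts at each signal share
  s ∈ {0, 0.25, 0.5, 0.75} at reduced geometry (90 px rings, 260 px
  height) — measurement attenuation at this scale is ≈ 0.005, an order
  of magnitude below the ±0.1 tolerance.
* Test calibration: 10 000 Gaussian-null pairs at n = 20.

The diffuse-porous archetype is used for the cohort studies because its
porosity levels sit far below the vessel-packing ceiling, leaving the
most headroom for annual anomalies.

## Known limitations

* The Otsu contour sits at ≈ 0.44 of the wall–lumen contrast (the void
  class is the smaller one), which dilates voids slightly; with
  earlywood-sized vessels this biases recovered earlywood porosity by up
  to ≈ +0.02 in ring-porous cohorts. It is a property of the method, not
  of the generator, and would apply to real material as well.
* Per-ring MAX_Por is an extreme statistic of a noisy profile and is
  biased upward by ~1–2 ripple standard deviations; MIN_Por conversely.
* Compression by linear interpolation assumes intra-ring structure
  scales with relative position; strongly asymmetric growth would
  violate this.
* No detrending/standardization is applied to chronologies, and no
  earlywood/latewood boundary criterion is implemented.
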