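# picdens — pixel-contrast densitometry for angiosperm wood

`picdens` turns micrographs of stained wood cross-sections into
quantitative intra-ring **porosity profiles** and multi-specimen annual
chronologies. It targets quantitative wood anatomists and
dendroecologists working with shrubs and broadleaved trees, where
classical X-ray densitometry is impractical: instead of measuring mass
attenuation, the method classifies every pixel of a cross-section photo
as **cell wall** (dark, stained) or **void** (light lumens and
intercellular spaces) and measures the void fraction directly.

## Method

1. **Binarization.** The photograph is Gaussian-smoothed (default
   σ = 2 px), converted to 8-bit grayscale (BT.601 luma), and split by a
   per-image global threshold from **Otsu's method**, which minimizes the
   weighted within-class variance of the bimodal gray-level histogram

   σ²_w(t) = ω₁(t)·σ₁²(t) + ω₂(t)·σ₂²(t),

   where ω₁, ω₂ are the class shares and σ₁, σ₂ the class standard
   deviations of the split {≤ t} vs {> t}. Pixels above the threshold
   are void, pixels at or below it are wall.

2. **Virtual sensor.** A one-pixel-thick scanning line of fixed length
   (default 1000 px) advances radially one pixel at a time; at each
   position the porosity is

   Por(x) = (void pixels on the line) / (total pixels on the line).

   The scan is repeated in overlapping tangential windows (default
   1000-px window, 200-px step — five windows on a 1800-px-tall image)
   and the per-window profiles are averaged pixelwise, suppressing local
   disturbances (rays, outsized vessels, preparation defects).

3. **Ring statistics and chronologies.** User-supplied ring annotations
   (year + radial pixel interval) cut the averaged profile into rings;
   each ring yields RW (width), MEAN_Por, MAX_Por and MIN_Por. Specimen
   series are compared with Pearson correlations on pairwise-complete
   years (two-tailed t-test, df = n−2), summarized as mean inter-series
   correlations per parameter, site chronologies with sample depth, and a
   parameter correlation matrix with a p < 0.05 significance mask.

4. **Synthetic wood.** A first-class generator renders ring-porous,
   semi-ring-porous and diffuse-porous cross-sections — elliptical vessel
   lumens on a dark wall matrix with pixel noise — with exact ground
   truth (target porosity per radial pixel, per-ring statistics, and a
   controllable common annual signal across specimens), so the whole
   chain is testable without reference photographs.

## Worked example

```python
import picdens as pdn

img, truth = pdn.render_ring(pdn.RING_POROUS, width_px=300,
                             window_height=1800, rng=2)
mask = pdn.preprocess(img)                      # smooth + Otsu
pset = pdn.profile_set(mask, window=1000, step=200)
avg = pset.averaged.values
print(avg[:60].mean(), avg[-100:].mean())
print(pdn.profile_correlation_table(pset))
```

prints (examples/porosity_profile.py):

```
earlywood porosity (first 60 px):  0.512
latewood porosity (last 100 px):   0.149
window-vs-averaged Pearson r: [0.999, 1.0, 0.999, 1.0, 0.999]
correlation with the generator's ground truth: 1.000
```

The earlywood/latewood contrast (0.51 vs 0.15) is the ring-porous
signature; the five window profiles agree with the averaged profile at
r ≈ 1, i.e. the measurement reflects ring structure, not the choice of
scanning area. `examples/` contains one runnable script per capability
(binarization, profiling, ring statistics, chronology statistics, site
simulation); each prints the numbers it computes and what they mean.

A thin CLI mirrors the library:

```bash
picdens simulate --archetype ring_porous --specimens 12 --years 30 --seed 42 --out FIX/
picdens binarize FIX/S01.png --sigma 2.0 --out mask.png
picdens profile mask.png --window 1000 --step 200 --rings FIX/RINGS.csv --out profiles.csv
picdens measure FIX --rings FIX/RINGS.csv --out SERIES.csv
picdens stats SERIES.csv --out STATS/
```

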