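"""Cohort-level analysis: inter-series correlations and chronologies.

Renders a cohort of 8 specimens sharing half of their annual porosity
variability (signal share 0.5), measures every panorama, and reproduces
the standard dendro-style statistics: mean inter-series correlation per
parameter, site chronologies, and the parameter correlation matrix with
two-tailed significance.
"""

import picdens as pdn

site = pdn.render_site(
    pdn.DIFFUSE_POROUS, n_specimens=8, n_years=25,
    signal_share=0.5, mean_ring_width=100, window_height=400, rng=11,
)
series = pdn.site_to_series(site, window=200, step=100)
stats = pdn.site_statistics(series)

print("mean inter-series correlations (common external signal strength):")
for p, r in stats["interseries"].items():
    print(f"  {p:9s} {r:+.3f}")
# Porosity parameters were generated with a common-signal share of 0.5,
# so their inter-series r is near 0.5; ring widths were drawn
# independently, so RW sits near 0.

chron = stats["chronologies"]["MEAN_Por"]
print(f"\nsite chronology of MEAN_Por: {len(chron)} years, "
      f"range {chron.min():.3f}-{chron.max():.3f}")

r = stats["param_r"]
sig = stats["param_significant"]
print("\nparameter correlation matrix (r, * = p < 0.05):")
cols = list(r.columns)
print("          " + " ".join(f"{c:>9s}" for c in cols))
for a in cols:
    cells = [
        f"{r.loc[a, b]:+.2f}{'*' if (a != b and sig.loc[a, b]) else ' ':1s}"
        for b in cols
    ]
    print(f"{a:>9s} " + " ".join(f"{c:>9s}" for c in cells))
# MAX/MEAN/MIN porosity chronologies correlate strongly with each other
# (they share the same annual anomaly) and not with ring width.
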