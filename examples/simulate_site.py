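"""Generate a synthetic study site on disk (images + annotations + truth).

Equivalent to:
    picdens simulate --archetype ring_porous --specimens 4 --years 10 \
        --seed 42 --out FIXTURES/

The output directory contains one PNG panorama per specimen, a RINGS.csv
annotation table and a truth.json manifest sufficient to recompute every
expected pipeline output without re-reading the images.
"""

import json
import sys
from pathlib import Path

import picdens as pdn

out = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("FIXTURES")
site = pdn.render_site(
    pdn.RING_POROUS, n_specimens=4, n_years=10,
    signal_share=0.5, mean_ring_width=120, window_height=600, rng=42,
)
site.save(out)

manifest = json.loads((out / "truth.json").read_text())
n_rings = sum(len(v) for v in manifest["specimens"].values())
print(f"wrote {len(site.specimens)} panoramas, {n_rings} annotated rings -> {out}/")
print(f"archetype: {manifest['archetype']}, common-signal share "
      f"{manifest['signal_share']}")
first = manifest["specimens"]["S01"][0]
print(f"first ring of S01: year {first['year']}, width {first['width_px']} px, "
      f"target mean porosity {first['por_mean']:.3f}")
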