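import numpy as np
import pytest

import picdens as pdn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240223)


@pytest.fixture(scope="session")
def rendered_singles():
    """One default-geometry ring per archetype with its ground truth and
    measured profile set (shared across profile-level tests)."""
    out = {}
    for arch in (pdn.RING_POROUS, pdn.SEMI_RING_POROUS, pdn.DIFFUSE_POROUS):
        img, truth = pdn.render_ring(arch, 300, 1800, rng=101)
        pset = pdn.image_profiles(img)
        out[arch.kind] = (img, truth, pset)
    return out


@pytest.fixture(scope="session")
def small_site():
    """A small rendered cohort for series/statistics tests."""
    site = pdn.render_site(
        pdn.DIFFUSE_POROUS,
        n_specimens=4,
        n_years=8,
        signal_share=0.5,
        mean_ring_width=80,
        window_height=300,
        rng=7,
    )
    series = pdn.site_to_series(site, window=150, step=75)
    return site, series
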