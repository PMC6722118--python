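import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mosaicquant.synthetic_data import ImageSpec, generate_core_image

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# small-core geometry reused across tests to keep rendering fast
SMALL = dict(width_px=256, height_px=256, n_myocytes=40)


@pytest.fixture(scope="session")
def default_core():
    """One mid-mosaicism core: (spec, rgb, ground_truth, exclusion_mask)."""
    spec = ImageSpec(**SMALL, true_mosaic_fraction=0.2, seed=7)
    rgb, gt, excl = generate_core_image(spec)
    return spec, rgb, gt, excl


@pytest.fixture(scope="session")
def fixture_cores():
    """Cores across the mosaicism range, keyed by target fraction."""
    out = {}
    for i, frac in enumerate([0.01, 0.1, 0.35, 0.7, 0.92]):
        spec = ImageSpec(**SMALL, true_mosaic_fraction=frac, seed=60 + i)
        out[frac] = (spec, *generate_core_image(spec))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
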