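import numpy as np
import pytest

from amytrans.phantom import PhantomConfig, generate_cohort, make_tissue_map


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_tissue():
    """Tissue map on the full template grid (fixed rng state)."""
    return make_tissue_map(PhantomConfig(), np.random.default_rng(0))


@pytest.fixture(scope="session")
def tiny_phantom_config():
    """Small-grid phantom configuration for fast pipeline tests."""
    return PhantomConfig(grid_shape=(48, 40, 40),
                         counts={"YHC": 2, "EHC": 1, "MCI": 2, "AD": 2, "FTD": 1},
                         psf_fwhm_mm=4.0, noise_sd=0.03, seed=42)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_phantom_config):
    return generate_cohort(tiny_phantom_config)
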