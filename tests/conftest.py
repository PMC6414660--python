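import numpy as np
import pytest

from renoquant.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def test_cfg() -> PhantomConfig:
    """Default test-scale phantom configuration."""
    return PhantomConfig.test_scale(seed=101)


@pytest.fixture(scope="session")
def phantom0(test_cfg):
    """One default phantom (noise and PSF on)."""
    return generate_phantom(test_cfg, 0)


@pytest.fixture(scope="session")
def clean_phantom():
    """A phantom with count noise and PSF blur disabled."""
    cfg = PhantomConfig.test_scale(seed=101, psf_fwhm_mm=0.0, noise_scale=0.0)
    return generate_phantom(cfg, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
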