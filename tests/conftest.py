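import numpy as np
import pytest

from granulekit.simulate import KineticTruth, SimulationConfig


@pytest.fixture
def clean_config():
    """Noise-free, PSF-free acquisition: rendered values are exact."""
    return SimulationConfig(seed=0, pixel_size_nm=100.0, psf_sigma_px=0.0,
                            poisson=False, gaussian_sigma=0.0)


@pytest.fixture
def blurred_config():
    """Noise-free but with a realistic PSF."""
    return SimulationConfig(seed=0, pixel_size_nm=100.0, psf_sigma_px=1.0,
                            poisson=False, gaussian_sigma=0.0)


@pytest.fixture
def cytoplasmic_truth():
    """Kinetics of the condensed cytoplasmic granule regime (43.6% mobile)."""
    return KineticTruth(mobile_fraction=0.436, rate_per_s=np.log(2) / 10.5,
                        bleach_depth=0.8, n_pre=5)
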