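import numpy as np
import pytest

from optoquant.preprocess import gaussian_psf
from optoquant.simulate import HotspotSpec, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def structured_image(rng):
    """A smooth, feature-rich image suitable for registration tests."""
    from scipy.ndimage import gaussian_filter
    img = gaussian_filter(rng.random((64, 64)), 3.0)
    return 1000.0 * (1.0 + img)


@pytest.fixture
def psf_small():
    return gaussian_psf(1.5)


def make_single_hotspot_config(lambda_um=0.74, quantal_size=0.05,
                               image_shape=(40, 40), n_frames=20,
                               stim_time=1.0, psf_sigma_um=0.0,
                               f0_mean=2000.0, f0_cv=0.0, noise=False,
                               tau_rise=0.0, tau_off=8.96, seed=0,
                               **kw):
    """One centred release site, one stimulus; noise and blur optional."""
    px = 0.1625
    center = ((image_shape[0] // 2 + 0.5) * px, (image_shape[1] // 2 + 0.5) * px)
    spec = HotspotSpec(center_um=center, lambda_um=lambda_um,
                       quantal_size=quantal_size)
    return SimulationConfig(
        image_shape=image_shape, pixel_size_um=px, frame_rate=10.0,
        n_frames=n_frames, stim_times=(stim_time,), hotspots=[spec],
        f0_mean=f0_mean, f0_cv=f0_cv, tau_rise=tau_rise, tau_off=tau_off,
        psf_sigma_um=psf_sigma_um, read_noise=2.0 if noise else 0.0,
        poisson_noise=noise, seed=seed, **kw)
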