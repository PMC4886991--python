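import numpy as np
import pytest

import stillgrid as sg

HEWL_CELL = (79.0, 79.0, 38.0, 90.0, 90.0, 90.0)
WAVELENGTH = 1.3
D_MIN = 3.5


@pytest.fixture(scope="session")
def detector():
    return sg.default_geometry()


@pytest.fixture(scope="session")
def crystal():
    return sg.random_crystal(HEWL_CELL, (500, 500), (0.002, 0.002),
                             rng_seed=3)


@pytest.fixture(scope="session")
def noisy_frame(crystal, detector):
    frame, manifest = sg.render_still(crystal, detector, background_mean=50,
                                      d_min=D_MIN, rng_seed=7)
    return frame, manifest


@pytest.fixture(scope="session")
def clean_frame(crystal, detector):
    """Noise-free frame: deterministic expectation image, zero background."""
    frame, manifest = sg.render_still(crystal, detector, background_mean=0,
                                      d_min=D_MIN, rng_seed=7,
                                      poisson_noise=False, spot_sigma_px=1.0,
                                      mean_intensity=5000,
                                      intensity_spread=0.2)
    return frame, manifest
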