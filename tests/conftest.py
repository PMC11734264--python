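import warnings

import numpy as np
import pytest

import fdfwi as fw
from fdfwi.fwi import InversionConfig


@pytest.fixture(autouse=True)
def _quiet_regime_warnings():
    """Silence the expected df >> f_low/2 and points-per-wavelength warnings."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*f_low/2.*")
        warnings.filterwarnings("ignore", message=".*points per wavelength.*")
        yield


@pytest.fixture(scope="session")
def tiny_setup():
    """A minimal solvable scene: 40x40 grid, 8-element ring, smooth model.

    Shared by forward-modeling and inversion unit tests; PML thickness 8 to
    leave a usable interior.
    """
    rng = np.random.default_rng(7)
    from scipy.ndimage import gaussian_filter

    h = 1e-3
    grid = fw.centered_grid(40, 40, h)
    ring = fw.make_ring_array(0.018, 8, center=(0.0, 0.0))
    cs = 1480 + 60 * gaussian_filter(rng.standard_normal(grid.shape), 2)
    att = np.abs(0.3 + 0.2 * gaussian_filter(rng.standard_normal(grid.shape), 2))
    truth = fw.AcousticModel(cs, att, grid)
    config = InversionConfig(pml=fw.PMLConfig(thickness=8), self_receive_exclusion=1)
    return {"grid": grid, "ring": ring, "truth": truth, "config": config, "f0": 250e3}


@pytest.fixture(scope="session")
def tiny_observed(tiny_setup):
    obs = fw.simulate_channel_spectra(
        tiny_setup["truth"],
        tiny_setup["ring"],
        None,
        [tiny_setup["f0"]],
        pml=tiny_setup["config"].pml,
        source_stencil="bilinear",
    )
    return obs
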