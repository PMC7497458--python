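import numpy as np
import pytest

import petsr


@pytest.fixture(scope="session")
def default_truth():
    """Default rodent-scale beating phantom (16 frames, 5% contraction)."""
    return petsr.make_beating_phantom(petsr.PhantomConfig())


@pytest.fixture(scope="session")
def noiseless_gated(default_truth):
    """Default phantom degraded without count noise (PSF 1.5 mm, factor 2)."""
    return petsr.degrade_sequence(
        default_truth, petsr.PSFModel(1.5), 2, noise_model="none"
    )


@pytest.fixture(scope="session")
def small_truth():
    """Coarse phantom for fast end-to-end tests (same FOV, 0.2 mm/px)."""
    return petsr.make_beating_phantom(
        petsr.PhantomConfig(grid_size=64, spacing_hr=0.2, n_frames=4)
    )


@pytest.fixture(scope="session")
def speckle_pair():
    """A speckle image and a copy translated by 3.0 px in x (sub-pixel clean)."""
    from scipy import ndimage

    rng = np.random.default_rng(0)
    base = ndimage.gaussian_filter(rng.standard_normal((200, 200)), 1.5)
    base = (base - base.min()) / np.ptp(base)
    shifted = ndimage.shift(base, (0.0, 3.0), order=3, mode="nearest")
    ref = petsr.Image2D(base[20:180, 20:180], 0.1)
    tmpl = petsr.Image2D(shifted[20:180, 20:180], 0.1)
    return ref, tmpl
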