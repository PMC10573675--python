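import numpy as np
import pytest

from lithovol.phantom import PhantomSpec, StoneSpec, simulate_phantom
from lithovol.volumetry import HUVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20230928)


@pytest.fixture
def random_hu_volume(rng):
    """A 20^3 grid of HU values spanning soft tissue to dense stone."""
    vox = rng.uniform(-100, 2000, size=(20, 20, 20))
    return HUVolume(voxels=vox, spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def clean_sphere_phantom():
    """Noise- and blur-free 12 mm sphere at 0.5 mm spacing; truth 904.78 mm^3."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 40),
        spacing_mm=(0.5, 0.5, 0.5),
        stones=(StoneSpec("sphere", (9.75, 9.75, 9.75), (12.0, 12.0, 12.0), 1100.0),),
        background_hu_sd=0.0,
        blur_sigma_mm=0.0,
        noise_sd_hu=0.0,
        seed=7,
    )
    return simulate_phantom(spec)
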