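import numpy as np
import pytest

from dasypop.scene import MultispectralScene, SolarGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_scene(blue, green, red, nir, pixel_size=2.5, altitude=68.68, azimuth=180.0, pan=None):
    return MultispectralScene(
        blue=np.asarray(blue, dtype=float),
        green=np.asarray(green, dtype=float),
        red=np.asarray(red, dtype=float),
        nir=np.asarray(nir, dtype=float),
        pan=pan,
        pixel_size=pixel_size,
        solar=SolarGeometry(altitude, azimuth),
    )


@pytest.fixture
def random_scene(rng):
    shape = (16, 16)
    return make_scene(*[rng.uniform(0, 255, shape) for _ in range(4)])


@pytest.fixture
def solar():
    return SolarGeometry(68.68, 180.0)
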