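import numpy as np
import pytest

from domescope.scene import ScenePars, generate_scene, random_dome_specs


@pytest.fixture(scope="session")
def small_dome_scene():
    """A compact dome scene shared by reconstruction tests: 192 um field,
    one 40 um dome (apex 32 um), 10 planes of 5 um."""
    specs = (((96.0, 96.0), 40.0, 32.0),)
    pars = ScenePars(
        field_size_um=192.0, n_planes=10, dome_specs=specs, seed=42
    )
    gt, surface, ideal = generate_scene(pars)
    return pars, gt, surface, ideal


@pytest.fixture(scope="session")
def textured_image():
    """The brightfield channel of a flat scene — texture with no objects."""
    pars = ScenePars(field_size_um=96.0, n_planes=2, seed=7)
    _, _, ideal = generate_scene(pars)
    return ideal["brightfield"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
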