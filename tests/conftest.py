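import numpy as np
import pytest

from microleak.synthetic import SceneSpec, generate_cross_section


@pytest.fixture(scope="session")
def default_scene():
    """A smooth noiseless scene with 400 px of dye along a curved interface."""
    spec = SceneSpec()
    image, truth = generate_cross_section(spec)
    return spec, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
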