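import numpy as np
import pytest

from cvdscale import gen_hue_ramp, gen_random_scale, load_scale


@pytest.fixture(scope="session")
def fu_scale():
    """The bundled 21-colour water-colour scale (illuminant E)."""
    return load_scale("forel-ule")


@pytest.fixture(scope="session")
def ramp_scale():
    return gen_hue_ramp(21)


@pytest.fixture(scope="session")
def random_scale():
    return gen_random_scale(8, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
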