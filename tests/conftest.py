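import numpy as np
import pytest

from thzwater.water_models import load_model


@pytest.fixture(scope="session")
def spce():
    return load_model("spce")


@pytest.fixture(scope="session")
def swm4():
    return load_model("swm4ndp")


@pytest.fixture(scope="session")
def amoeba():
    return load_model("amoeba14")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
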