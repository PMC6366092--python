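import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import admap

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def uniform_table():
    return admap.make_table("uniform", seed=1)


@pytest.fixture(scope="session")
def two_class_table():
    return admap.make_table("two-class", seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, n):
    return "".join(rng.choice(list(admap.stats.AA_ORDER), size=n))
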