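import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ideapop as ip

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def symmetric_games():
    return {name: ip.make_symmetric_game(name)
            for name in ("coexistence", "dominance", "coordination", "neutral")}


@pytest.fixture(scope="session")
def matching_pennies():
    return ip.make_asymmetric_game("matching_pennies")


@pytest.fixture(scope="session")
def hyperbolic():
    return ip.make_asymmetric_game("hyperbolic")


@pytest.fixture(scope="session")
def asym_dominance():
    return ip.make_asymmetric_game("asym_dominance")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
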