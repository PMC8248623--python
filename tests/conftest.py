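import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def _render(shape, seed, density=0.06, sigma=1.2):
    from tfmsm.synthetic import _render_spots

    rs = np.random.default_rng(seed)
    n = int(density * shape[0] * shape[1])
    xy = rs.uniform(low=0.0, high=[shape[1], shape[0]], size=(n, 2))
    return _render_spots(shape, xy, sigma)


@pytest.fixture(scope="session")
def base_beads():
    return _render((256, 256), seed=7)
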