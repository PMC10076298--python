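import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study():
    """20x20-macro synthetic study area shared by the slower tests."""
    import warnings

    from landsys.pipeline import make_study
    from landsys.synth import FixtureSpec

    spec = FixtureSpec(seed=11, micro_shape=(660, 660), n_cover_types=4, block_factor=33)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # interval 0: on a 400-cell macro map the regression needs every cell
        return make_study(spec, interval=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
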