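import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppsatten import build_default_grid, default_cs_truth, make_default_anchors

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return build_default_grid()


@pytest.fixture(scope="session")
def cs_truth():
    return default_cs_truth()


@pytest.fixture(scope="session")
def ouh_truth():
    return make_default_anchors("OUH-like")


@pytest.fixture(scope="session")
def uas_truth():
    return make_default_anchors("UAS-like")


@pytest.fixture(scope="session")
def fine_angles():
    return np.arange(0.0, 360.0, 0.25)


@pytest.fixture(scope="session")
def ouh_study():
    """25-replicate synthetic study of the OUH-like site, seeds 1-25."""
    from ppsatten import run_replicate_study

    return run_replicate_study("OUH-like", n_replicates=25, base_seed=1)


@pytest.fixture(scope="session")
def uas_study():
    from ppsatten import run_replicate_study

    return run_replicate_study("UAS-like", n_replicates=25, base_seed=1)
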