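import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_mesh():
    """162-vertex icosphere at head scale (oracle-sized: < 500 vertices)."""
    from thalatarget.geometry import make_mesh

    return make_mesh(2, 50.0)


@pytest.fixture(scope="session")
def small_truth():
    """Desk-scale study truth on the 162-vertex mesh (fast unit tests)."""
    from thalatarget.synth import make_default_study

    return make_default_study(subdivisions=2)


@pytest.fixture(scope="session")
def default_truth():
    """Full default study geometry (2562-vertex cortex, 16^3 grid)."""
    from thalatarget.synth import make_default_study

    return make_default_study()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
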