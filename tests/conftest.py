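import pytest
from hypothesis import HealthCheck, settings

from mamsbayes import ArmState, BetaPrior, DesignParams

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: first-stage counts of the motivating three-arm trial: (responses, enrolled)
STAGE1_COUNTS = {"A": (15, 40), "B": (13, 40), "C": (16, 40)}


@pytest.fixture(scope="session")
def stage1_counts():
    return dict(STAGE1_COUNTS)


@pytest.fixture(scope="session")
def case_params():
    """Case-study design: p0=0.3, delta=0, delta*=0.15, gammas (0.9, 0.1, 0.9)."""
    return DesignParams(min_enrollment=0)


@pytest.fixture
def uniform_states(stage1_counts):
    u = BetaPrior(1.0, 1.0)
    return [
        ArmState(arm, u, n=n, y=y, is_control=(arm == "A"))
        for arm, (y, n) in stage1_counts.items()
    ]
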