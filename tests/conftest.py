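import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dvhtox import DVHCurve, SynthConfig, generate_cohort

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


def make_step_curve(total_cc: float = 10.0, edge_gy: float = 50.0,
                    max_gy: float = 80.0, bin_gy: float = 0.1) -> DVHCurve:
    """Uniform-dose structure: full volume up to the edge dose, zero beyond."""
    dose = np.arange(int(round(max_gy / bin_gy)) + 1) * bin_gy
    vol = np.where(dose <= edge_gy + 1e-12, total_cc, 0.0)
    return DVHCurve("brain", dose, vol)


def make_linear_curve(bin_gy: float = 0.1) -> DVHCurve:
    """V(d) = 20 - 0.25 d cc on [0, 80] Gy (strictly decreasing)."""
    dose = np.arange(int(round(80.0 / bin_gy)) + 1) * bin_gy
    return DVHCurve("brain", dose, 20.0 - 0.25 * dose)


@pytest.fixture
def step_curve() -> DVHCurve:
    return make_step_curve()


@pytest.fixture
def linear_curve() -> DVHCurve:
    return make_linear_curve()


@pytest.fixture(scope="session")
def cohort2000():
    """Default-condition synthetic cohort, shared across calibration tests."""
    return generate_cohort(SynthConfig(n_patients=2000, seed=0))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SynthConfig(n_patients=40, seed=7))
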