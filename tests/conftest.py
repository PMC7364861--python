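import numpy as np
import pytest

from hpamass import (
    MINUTES_PER_DAY,
    ModelParameters,
    ScenarioConfig,
    make_variant,
    prolonged_stress_protocol,
    simulate,
)
from hpamass.metrics import timeline_for_variant


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def full_model(params):
    return make_variant("full_mass", params)


@pytest.fixture(scope="session")
def stress_protocol():
    """Step input u=4 for 90 days, then back to basal u=1."""
    return prolonged_stress_protocol(u_stress=4.0, duration_days=90.0)


@pytest.fixture(scope="session")
def fig3_trajectory(params, full_model, stress_protocol):
    """Full-model prolonged-stress run, 300 simulated days."""
    config = ScenarioConfig(
        variant="full_mass",
        params=params,
        protocol=stress_protocol,
        t_start=0.0,
        t_end=300.0 * MINUTES_PER_DAY,
    )
    return simulate(full_model, config)


@pytest.fixture(scope="session")
def test_schedule():
    return np.arange(1.0, 300.0, 3.0)


@pytest.fixture(scope="session")
def full_timeline(test_schedule):
    """Response timeline + phases for the full model under prolonged stress."""
    return timeline_for_variant("full_mass", test_days=test_schedule)


@pytest.fixture(scope="session")
def variant_timelines(test_schedule):
    """Timelines for the constant-mass alternatives under the same stress."""
    out = {}
    for vid in ("classic", "gr_resistance", "slow_clearance", "slow_input"):
        out[vid] = timeline_for_variant(vid, test_days=test_schedule)
    return out
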