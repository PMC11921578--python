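import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from fepbias import SimulationConfig, simulate_cohort
from fepbias.config import ContaminationConfig

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_participants=60, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def contaminated_config() -> SimulationConfig:
    return SimulationConfig(
        n_participants=80,
        seed=7,
        contamination=ContaminationConfig(
            bot_rate=0.05,
            inattentive_rate=0.05,
            fast_guess_rate=0.05,
            nonresponse_rate=0.05,
        ),
    )


@pytest.fixture(scope="session")
def contaminated_cohort(contaminated_config):
    return simulate_cohort(contaminated_config)


def make_trial_frame(rows) -> pd.DataFrame:
    """Build a trial log from (pid, idx, side, rt, is_check, top) tuples."""
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "trial_index",
            "chosen_side",
            "rt_ms",
            "is_attention_check",
            "left_vf_on_top",
        ],
    ).assign(emotion="happy", check_passed=True)
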