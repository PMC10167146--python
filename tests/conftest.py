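import numpy as np
import pandas as pd
import pytest

from pdec.design import TrialSpec
from pdec.io_formats import SAMPLE_COLUMNS, SampleTable
from pdec.simulate import SimulationConfig, TargetTrajectory


@pytest.fixture
def traj() -> TargetTrajectory:
    return TargetTrajectory()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def trial() -> TrialSpec:
    return TrialSpec(trial_index=0, cue_label="2", cue_onset_ms=0, isi_ms=4000)


def quiet_config(**overrides) -> SimulationConfig:
    """Deterministic pursuit: no noise, no endogenous or scheduled events."""
    base = dict(pos_noise_sd=0.0, pupil_noise_sd=0.0, catchup_trigger_dva=99.0,
                anticipatory_rate_hz=0.0, micro_rate_hz=0.0, blink_rate_hz=0.0,
                interocular_offset_dva=0.0)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def make_quiet_config():
    return quiet_config


def stationary_table(n: int = 2000, x: float = 0.0, y: float = 0.0,
                     pd_mm: float = 4.0) -> SampleTable:
    """A motionless, fully valid binocular recording."""
    df = pd.DataFrame({
        "time_ms": np.arange(n), "xl": x, "yl": y, "xr": x, "yr": y,
        "pdl": pd_mm, "pdr": pd_mm, "valid_l": True, "valid_r": True,
    }, columns=SAMPLE_COLUMNS)
    return SampleTable(df)


@pytest.fixture
def make_stationary():
    return stationary_table
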