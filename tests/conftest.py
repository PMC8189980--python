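import numpy as np
import pytest

from plight_gaze import (
    CohortConfig,
    ParticipantProfile,
    ScreenGeometry,
    TD_PRESET,
    TrialSetConfig,
    generate_walker,
    make_trial_set,
    simulate_participant,
)
from plight_gaze.gaze_synth import GazeRecording


@pytest.fixture(scope="session")
def geometry():
    return ScreenGeometry()


@pytest.fixture(scope="session")
def walker():
    return generate_walker(4.0, 120.0, gait_period_frames=100, n_points=15, seed=1)


@pytest.fixture(scope="session")
def small_scenes(walker, geometry):
    cfg = TrialSetConfig(n_trials=10, n_blocks=1, trials_per_block=10, seed=3)
    return make_trial_set(cfg, [walker], geometry)


@pytest.fixture(scope="session")
def full_scenes(walker, geometry):
    cfg = TrialSetConfig(seed=3)
    return make_trial_set(cfg, [walker], geometry)


@pytest.fixture(scope="session")
def td_profile():
    return ParticipantProfile("td-000", "td", age=20.0, gender="male")


@pytest.fixture(scope="session")
def td_recording(td_profile, small_scenes, geometry):
    return simulate_participant(td_profile, small_scenes, TD_PRESET, geometry, seed=5)


def make_recording(t_ms, x, y, valid=None, pid="p0"):
    """Hand-built monocular-identical recording for constructed fixtures."""
    t_ms = np.asarray(t_ms, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    valid = np.ones(len(t_ms), bool) if valid is None else np.asarray(valid, bool)
    x = np.where(valid, x, np.nan)
    y = np.where(valid, y, np.nan)
    return GazeRecording(
        participant_id=pid,
        t_ms=t_ms,
        lx_px=x.copy(),
        ly_px=y.copy(),
        rx_px=x.copy(),
        ry_px=y.copy(),
        l_valid=valid.copy(),
        r_valid=valid.copy(),
    )
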