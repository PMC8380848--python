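"""Shared fixtures: small environments and short sessions for fast tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from openworld_gaze.config import EnvironmentConfig, NavConfig, StudyConfig
from openworld_gaze.session import simulate_session
from openworld_gaze.world import build_environment


def short_nav_config() -> NavConfig:
    """~90 s sessions with an early, compact math epoch."""
    return NavConfig(
        mean_duration_s=90.0, sd_duration_s=4.0, math_onset_s=30.0,
        math_pause_range_s=(1.0, 1.5), math_response_s=2.0,
        math_break_range_s=(3.0, 5.0), math_number_audio_s=0.5,
    )


def small_env_config() -> EnvironmentConfig:
    return EnvironmentConfig(path_length_m=300.0, n_targets_per_condition=5,
                             n_other=30, n_trail_markers=4)


@pytest.fixture(scope="session")
def small_env():
    return build_environment(small_env_config(), seed=5)


@pytest.fixture(scope="session")
def short_session(small_env):
    """One short synthetic session (humvee condition) reused read-only."""
    return simulate_session(small_env, "humvee", seed=11,
                            nav_config=short_nav_config())


@pytest.fixture(scope="session")
def default_env():
    return build_environment(EnvironmentConfig(), seed=1)


def make_samples(x, y, valid=None, rate=300.0):
    """Assemble a minimal sample table from position arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if valid is None:
        valid = np.ones(n, dtype=int)
    return pd.DataFrame({
        "t_s": np.arange(n) / rate,
        "x_deg": x,
        "y_deg": y,
        "valid": np.asarray(valid, dtype=np.int8),
        "object_id": np.full(n, "", dtype=object),
        "obs_x_m": np.zeros(n),
        "obs_y_m": np.zeros(n),
        "obs_z_m": np.full(n, 1.7),
        "gaze_distance_m": np.full(n, 10.0),
    })


def random_walk_samples(seed: int, n: int = 1500, rate: float = 300.0,
                        n_saccades: int = 4, gap_spec=((400, 30), (900, 80)),
                        noise_sd: float = 0.03):
    """Fixation noise + embedded ballistic jumps + invalid gaps.

    Returns a sample table suitable for oracle-equivalence testing.
    """
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    y = np.zeros(n)
    pos = np.array([0.0, 0.0])
    i = 0
    jump_at = sorted(rng.choice(np.arange(50, n - 80), size=n_saccades,
                                replace=False))
    cursor = 0
    for j in jump_at:
        x[cursor:j] = pos[0]
        y[cursor:j] = pos[1]
        dur = int(rng.integers(5, 14))
        target = pos + rng.uniform(-8, 8, 2)
        phase = (np.arange(dur) + 1) / dur
        prof = 0.5 * (1 - np.cos(np.pi * phase))
        x[j:j + dur] = pos[0] + (target[0] - pos[0]) * prof[:max(0, min(dur, n - j))]
        y[j:j + dur] = pos[1] + (target[1] - pos[1]) * prof[:max(0, min(dur, n - j))]
        pos = target
        cursor = min(j + dur, n)
    x[cursor:] = pos[0]
    y[cursor:] = pos[1]
    x += rng.normal(0, noise_sd, n)
    y += rng.normal(0, noise_sd, n)
    valid = np.ones(n, dtype=int)
    for start, length in gap_spec:
        valid[start:start + length] = 0
    return make_samples(x, y, valid, rate)


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig()
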