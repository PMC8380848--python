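"""Navigation trajectory and dual-task (math) schedule simulation.

The observer traverses the full trail at a baseline speed drawn so that the
session lasts about 11-12 minutes, with multiplicative log-AR(1) speed noise.
From the 8-minute mark a concurrent auditory summation task runs (three
trials of 3-4 spoken digits with pauses, a verbal response after each, and
8-30 s breaks); the navigation speed is multiplied by the dual-task
multiplier for its duration.  Positions are sampled on the same grid as the
gaze stream so collision distances can be computed per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigError, NavConfig
from .world import Environment


@dataclass
class NavTrajectory:
    """Observer kinematics on the gaze-sample grid.

    positions[:, 0] is arc length along the trail; [:, 1] lateral offset;
    [:, 2] eye height.  ``math_task_interval`` is a half-open ``[start, end)``
    window in seconds (clipped to the session if the subject finishes early).
    """

    times: np.ndarray
    positions: np.ndarray
    speeds: np.ndarray
    math_task_interval: tuple[float, float]
    math_completed: bool

    @property
    def duration_s(self) -> float:
        return len(self.times) / self.rate_hz

    @property
    def rate_hz(self) -> float:
        return 1.0 / (self.times[1] - self.times[0])


def sample_math_schedule(cfg: NavConfig, rng: np.random.Generator) -> float:
    """Draw the total length (s) of the summation-task schedule.

    Each trial plays 3-4 digits (audio ~1 s each) separated by 3-4 s pauses
    and ends with a response window; trials are separated by 8-30 s breaks.
    The epoch ends at the end of the third response.
    """
    total = 0.0
    lo_n, hi_n = cfg.math_numbers_per_trial
    for trial in range(cfg.math_n_trials):
        n_num = int(rng.integers(lo_n, hi_n + 1))
        total += n_num * cfg.math_number_audio_s
        total += (n_num - 1) * rng.uniform(*cfg.math_pause_range_s)
        total += cfg.math_response_s
        if trial < cfg.math_n_trials - 1:
            total += rng.uniform(*cfg.math_break_range_s)
    return total


def simulate_navigation(env: Environment, nav_config: NavConfig | None = None,
                        seed: int = 0, rate_hz: float = 300.0) -> NavTrajectory:
    """Simulate one subject's traversal of the trail.

    The session ends when the full path length has been covered (determinism:
    bit-identical output for fixed config and seed).
    """
    cfg = nav_config or NavConfig()
    cfg.validate()
    if not (0.0 < cfg.dual_task_speed_multiplier <= 1.0):
        raise ConfigError("dual_task_speed_multiplier must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    dt = 1.0 / rate_hz
    t_nominal = max(60.0, rng.normal(cfg.mean_duration_s, cfg.sd_duration_s))
    v0 = env.path_length_m / t_nominal

    math_len = sample_math_schedule(cfg, rng)
    math_start = cfg.math_onset_s
    math_end = math_start + math_len

    # horizon generous enough to always cover the path
    n_max = int(np.ceil((t_nominal * 1.8 + 120.0) * rate_hz))
    t = np.arange(n_max) * dt

    # log-AR(1) multiplicative speed noise
    rho = np.exp(-dt / cfg.speed_noise_tau_s)
    innov_sd = cfg.speed_noise_sd * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, n_max)
    g = np.empty(n_max)
    g[0] = rng.normal(0.0, cfg.speed_noise_sd)
    # AR(1) recursion via scipy-free filtering: iterative cumulative form
    # g[i] = rho * g[i-1] + eps[i]
    powers = rho ** np.arange(n_max)
    g = g[0] * powers + _ar1_filter(eps, rho)

    mult = np.where((t >= math_start) & (t < math_end),
                    cfg.dual_task_speed_multiplier, 1.0)
    v = v0 * mult * np.exp(g)

    dist = np.cumsum(v) * dt
    covered = np.searchsorted(dist, env.path_length_m)
    n = int(min(max(covered + 1, int(60 * rate_hz)), n_max))

    times = t[:n]
    speeds = v[:n]
    pos = np.empty((n, 3))
    pos[:, 0] = np.concatenate(([0.0], dist[:n - 1]))
    pos[:, 1] = 0.0
    pos[:, 2] = cfg.eye_height_m

    duration = n * dt
    completed = duration >= math_end
    interval = (min(math_start, duration), min(math_end, duration))
    return NavTrajectory(times=times, positions=pos, speeds=speeds,
                         math_task_interval=interval, math_completed=completed)


def _ar1_filter(eps: np.ndarray, rho: float) -> np.ndarray:
    """Causal AR(1) filter y[i] = rho*y[i-1] + eps[i] (y[-1] = 0), O(n)."""
    # cumulative trick: y[i] = sum_j rho^(i-j) eps[j]; computed stably in blocks
    out = np.empty_like(eps)
    acc = 0.0
    # chunked python loop would be slow at 300 Hz x 20 min; use scipy-style
    # recursion in numpy via frompyfunc accumulate on float pairs is slower;
    # a simple compiled-free approach: iterate in blocks of 4096 with vector math
    block = 4096
    powers = rho ** np.arange(block + 1)
    for start in range(0, len(eps), block):
        e = eps[start:start + block]
        m = len(e)
        # y[k] = rho^(k+1)*acc + sum_{j<=k} rho^(k-j) e[j]
        conv = np.cumsum(e / powers[:m]) * powers[:m]
        y = powers[1:m + 1] * acc + conv
        out[start:start + m] = y
        acc = y[-1]
    return out
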