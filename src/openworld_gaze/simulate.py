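"""Synthetic gaze-stream generation with exported ground truth.

One session is a 300 Hz cyclopean gaze stream (degrees of visual angle)
generated event-first: a Markov scheduler alternates fixations with
transitions (saccades, blinks, dropouts), choosing each fixation's gaze
object among the objects currently visible from the observer's trail
position.  Object choice is weighted by surface area and proximity, with
multipliers implementing the target preference (more selections, longer
refixation bursts, closer approach) and the dual-task modifiers (elevated
blink rate, shorter bursts) inside the math epoch.  Saccades follow a main
sequence through an amplitude-dependent duration and a raised-cosine
velocity profile; fixations carry slow drift (pursuit/optokinetic residue)
plus white position noise.  Per-sample gaze-ray collisions are emitted with
a configurable contamination probability so the downstream dominance rule
has something to filter.

All scheduling is done in integer sample counts, so event intervals tile the
session exactly and the stream is bit-identical for a fixed (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SKY_ID, TERRAIN_ID, ConfigError, GazeConfig
from .navigate import NavTrajectory
from .world import Environment

SAMPLE_COLUMNS = [
    "t_s", "x_deg", "y_deg", "valid", "object_id",
    "obs_x_m", "obs_y_m", "obs_z_m", "gaze_distance_m",
]
TRUTH_COLUMNS = [
    "event_type", "t_on_s", "t_off_s", "object_id",
    "amplitude_deg", "peak_vel_deg_s",
]


@dataclass
class GroundTruthLog:
    """Time-ordered true events emitted by the simulator (detector oracle)."""

    events: pd.DataFrame

    def of_type(self, *etypes: str) -> pd.DataFrame:
        return self.events[self.events["event_type"].isin(etypes)]

    @property
    def fixations(self) -> pd.DataFrame:
        return self.of_type("fixation")

    @property
    def saccades(self) -> pd.DataFrame:
        return self.of_type("saccade")


def _n_samples(duration_s: float, rate: float) -> int:
    return max(1, int(round(duration_s * rate)))


class _Scheduler:
    """Stateful event scheduler for one session (internal)."""

    def __init__(self, env: Environment, traj: NavTrajectory,
                 cfg: GazeConfig, rng: np.random.Generator,
                 condition: str | None):
        self.cfg = cfg
        self.rng = rng
        self.rate = cfg.sampling_rate_hz
        self.pathpos = traj.positions[:, 0]
        self.ms_start, self.ms_end = traj.math_task_interval

        lab = env.labelable
        self.obj_ids = lab["object_id"].to_numpy(dtype=object)
        self.obj_pos = lab["path_position_m"].to_numpy(dtype=float)
        self.obj_lat = lab["lateral_offset_m"].to_numpy(dtype=float)
        self.obj_vis = lab["max_visibility_range_m"].to_numpy(dtype=float)
        area = lab["surface_area_m2"].to_numpy(dtype=float)
        self.w_area = area ** cfg.area_exponent
        if condition is not None:
            tset = set(env.target_ids(condition))
            self.is_target = np.array(
                [oid in tset for oid in self.obj_ids], dtype=bool)
        else:
            self.is_target = np.zeros(len(self.obj_ids), dtype=bool)
        # deliberate search: each assigned target gets one queued inspection
        # when it first comes into view (subjects actively find and count)
        self._inspection_decided = np.zeros(len(self.obj_ids), dtype=bool)
        self._inspection_queue: list[int] = []

    def in_math(self, i: int) -> bool:
        t = i / self.rate
        return self.ms_start <= t < self.ms_end

    def visible(self, i: int) -> np.ndarray:
        """Indices of objects visible from sample ``i`` (ahead-biased)."""
        cur = self.pathpos[min(i, len(self.pathpos) - 1)]
        rel = self.obj_pos - cur
        d = np.hypot(rel, self.obj_lat)
        return np.nonzero((rel >= -0.3 * self.obj_vis) & (d <= self.obj_vis))[0]

    def distance(self, i: int, j: int) -> float:
        cur = self.pathpos[min(i, len(self.pathpos) - 1)]
        return float(np.hypot(self.obj_pos[j] - cur, self.obj_lat[j]))

    def pop_inspection(self, i: int) -> int | None:
        """Queue newly visible assigned targets; pop the nearest pending one.

        Emulates the deliberate search-and-count behaviour: when a target
        first enters the visible range it is inspected with probability
        ``target_inspection_prob`` at the next opportunity.
        """
        cfg = self.cfg
        vis = self.visible(i)
        new = vis[self.is_target[vis] & ~self._inspection_decided[vis]]
        for j in new:
            self._inspection_decided[j] = True
            if self.rng.random() < cfg.target_inspection_prob:
                self._inspection_queue.append(int(j))
        while self._inspection_queue:
            j = self._inspection_queue[0]
            if self.distance(i, j) <= self.obj_vis[j]:
                self._inspection_queue.pop(0)
                return j
            # target passed out of view before being inspected
            self._inspection_queue.pop(0)
        return None

    def choose_object(self, i: int) -> int | None:
        """Sample the next gaze object, or None for background."""
        cfg, rng = self.cfg, self.rng
        if rng.random() < cfg.background_prob:
            return None
        vis = self.visible(i)
        if len(vis) == 0:
            return None
        cur = self.pathpos[min(i, len(self.pathpos) - 1)]
        d = np.hypot(self.obj_pos[vis] - cur, self.obj_lat[vis])
        decay = np.where(self.is_target[vis],
                         cfg.target_distance_decay_m, cfg.distance_decay_m)
        w = self.w_area[vis] * np.exp(-d / decay)
        w = np.where(self.is_target[vis], w * cfg.target_weight_mult, w)
        tot = w.sum()
        if tot <= 0:
            return None
        return int(vis[rng.choice(len(vis), p=w / tot)])

    def burst_length(self, j: int | None, i: int) -> int:
        """Number of consecutive fixations planned on object ``j`` (None =
        background terrain/sky scanning run)."""
        cfg = self.cfg
        if j is None:
            mean = cfg.background_burst_mean
        else:
            mean = cfg.burst_mean
            if self.is_target[j]:
                mean *= cfg.target_burst_mult
        if self.in_math(i):
            mean *= cfg.math_burst_mult
        mean = max(1.0, mean)
        # shifted Poisson: mean preserved, much tighter than geometric
        return 1 + int(self.rng.poisson(mean - 1.0))


def simulate_gaze(env: Environment, traj: NavTrajectory,
                  gaze_config: GazeConfig | None = None, seed: int = 0,
                  condition: str | None = None,
                  ) -> tuple[pd.DataFrame, GroundTruthLog]:
    """Simulate the 300 Hz gaze-sample stream for one session.

    Returns the sample table (``SAMPLE_COLUMNS``) and the matching ground
    truth log.  ``condition`` activates the target-preference multipliers for
    that condition's 15 target instances.
    """
    cfg = gaze_config or GazeConfig()
    cfg.validate()
    rate = cfg.sampling_rate_hz
    if abs(rate - traj.rate_hz) > 1e-6:
        raise ConfigError("gaze sampling rate must match trajectory rate")
    rng = np.random.default_rng(seed)
    sched = _Scheduler(env, traj, cfg, rng, condition)

    n_total = len(traj.times)
    events: list[tuple[str, int, int, object, float, float]] = []
    # per-fixation synthesis info: (i_on, i_off, cx, cy, ux, uy, obj_idx|None,
    #                               bg_id, bg_dist, contaminant, contam_dist)
    fix_info: list[tuple] = []
    sacc_info: list[tuple] = []  # (i_on, i_off, x0, y0, x1, y1)

    gx = rng.uniform(-5.0, 5.0)
    gy = rng.uniform(-2.0, 2.0)
    i = 0
    cur_obj: int | None = sched.choose_object(0)
    burst_left = sched.burst_length(cur_obj, 0) - 1

    def fixation_duration(on_target: bool = False) -> float:
        if rng.random() < cfg.short_fixation_prob:
            return rng.uniform(0.050, 0.0997)
        d = cfg.fixation_median_s * np.exp(rng.normal(0.0, cfg.fixation_sigma))
        if on_target:
            # target inspections accrue dwell mostly through extra
            # fixations; individual ones are marginally shorter
            d *= cfg.target_dwell_factor
        return float(np.clip(d, 0.100, cfg.fixation_max_s))

    def background_id() -> str:
        return TERRAIN_ID if rng.random() < cfg.terrain_share else SKY_ID

    def terrain_distance() -> float:
        return cfg.terrain_distance_median_m * np.exp(rng.normal(0.0, 0.5))

    while i < n_total:
        # ---- fixation on cur_obj ----------------------------------------
        on_target = cur_obj is not None and bool(sched.is_target[cur_obj])
        m = min(_n_samples(fixation_duration(on_target), rate), n_total - i)
        i_on, i_off = i, i + m
        drift_speed = rng.uniform(0.0, cfg.drift_speed_max_deg_s)
        drift_ang = rng.normal(0.0, 0.6) + (0.0 if rng.random() < 0.5 else np.pi)
        ux = drift_speed * np.cos(drift_ang)
        uy = drift_speed * 0.4 * np.sin(drift_ang)
        if cur_obj is None:
            bg = background_id()
            bg_dist = terrain_distance() if bg == TERRAIN_ID else cfg.sky_distance_m
            obj_label = bg
            fix_info.append((i_on, i_off, gx, gy, ux, uy, None, bg, bg_dist,
                             None, 0.0))
        else:
            obj_label = sched.obj_ids[cur_obj]
            # single contaminant per fixation: mostly background, sometimes a
            # neighbouring object (position directly behind / gaze error)
            if rng.random() < 0.7:
                contaminant, c_dist = TERRAIN_ID, terrain_distance()
            else:
                vis = sched.visible(i_on)
                vis = vis[vis != cur_obj]
                if len(vis):
                    cj = int(rng.choice(vis))
                    contaminant, c_dist = sched.obj_ids[cj], sched.distance(i_on, cj)
                else:
                    contaminant, c_dist = TERRAIN_ID, terrain_distance()
            fix_info.append((i_on, i_off, gx, gy, ux, uy, cur_obj, "", 0.0,
                             contaminant, c_dist))
        events.append(("fixation", i_on, i_off, obj_label, np.nan, np.nan))
        gx += ux * m / rate
        gy += uy * m / rate
        i = i_off
        if i >= n_total:
            break

        # ---- decide next fixation target --------------------------------
        if burst_left > 0 and (
                cur_obj is None
                or sched.distance(i, cur_obj) <= sched.obj_vis[cur_obj]):
            next_obj = cur_obj
            burst_left -= 1
            refix = cur_obj is not None
        else:
            next_obj = sched.pop_inspection(i)
            if next_obj is None:
                next_obj = sched.choose_object(i)
            burst_left = sched.burst_length(next_obj, i) - 1
            refix = False

        # ---- transition event -------------------------------------------
        u = rng.random()
        p_blink = cfg.blink_prob_per_boundary * (
            cfg.math_blink_mult if sched.in_math(i) else 1.0)
        p_ds = cfg.dropout_short_prob
        p_dl = cfg.dropout_long_prob
        if u < p_blink:
            dur = float(np.clip(
                cfg.blink_median_s * np.exp(rng.normal(0.0, cfg.blink_sigma)),
                *cfg.blink_range_s))
            m = min(_n_samples(dur, rate), n_total - i)
            events.append(("gap", i, i + m, "", np.nan, np.nan))
            i += m
            # small post-blink displacement, no saccade event
            gx += rng.normal(0.0, 1.5)
            gy += rng.normal(0.0, 0.8)
        elif u < p_blink + p_ds:
            m = min(_n_samples(rng.uniform(*cfg.dropout_short_range_s), rate),
                    n_total - i)
            events.append(("gap", i, i + m, "", np.nan, np.nan))
            i += m
        elif u < p_blink + p_ds + p_dl:
            m = min(_n_samples(rng.uniform(*cfg.dropout_long_range_s), rate),
                    n_total - i)
            events.append(("gap", i, i + m, "", np.nan, np.nan))
            i += m
        else:
            # saccade toward the next fixation center
            if refix:
                amp = cfg.refix_amp_median_deg * np.exp(
                    rng.normal(0.0, cfg.refix_amp_sigma))
            else:
                amp = cfg.new_target_amp_median_deg * np.exp(
                    rng.normal(0.0, cfg.new_target_amp_sigma))
            amp = float(np.clip(amp, *cfg.amp_range_deg))
            if rng.random() < cfg.angle_horizontal_weight:
                base = 0.0 if rng.random() < 0.5 else 180.0
                ang = np.deg2rad(base + rng.normal(0.0, cfg.angle_horizontal_sd_deg))
            else:
                ang = rng.uniform(-np.pi, np.pi)
            nx = _reflect(gx + amp * np.cos(ang), cfg.gaze_extent_x_deg)
            ny = _reflect(gy + amp * np.sin(ang), cfg.gaze_extent_y_deg)
            disp = float(np.hypot(nx - gx, ny - gy))
            disp = max(disp, 0.05)
            dur = (cfg.saccade_d0_s + cfg.saccade_d1_s_per_deg * disp)
            dur *= np.exp(rng.normal(0.0, cfg.saccade_dur_jitter))
            dur = float(np.clip(dur, *cfg.saccade_dur_range_s))
            m = min(_n_samples(dur, rate), n_total - i)
            peak = np.pi * disp / (2.0 * (m / rate))
            events.append(("saccade", i, i + m, "", disp, peak))
            sacc_info.append((i, i + m, gx, gy, nx, ny))
            gx, gy = nx, ny
            i += m
        cur_obj = next_obj

    samples = _synthesize_samples(n_total, traj, cfg, rng, fix_info,
                                  sacc_info, sched)
    truth = _truth_frame(events, rate)
    return samples, truth


def _reflect(v: float, bound: float) -> float:
    """Reflect ``v`` into [-bound, bound]."""
    if v > bound:
        v = 2 * bound - v
    if v < -bound:
        v = -2 * bound - v
    return float(np.clip(v, -bound, bound))


def _synthesize_samples(n_total: int, traj: NavTrajectory, cfg: GazeConfig,
                        rng: np.random.Generator, fix_info: list,
                        sacc_info: list, sched: _Scheduler) -> pd.DataFrame:
    rate = cfg.sampling_rate_hz
    x = np.full(n_total, np.nan)
    y = np.full(n_total, np.nan)
    valid = np.zeros(n_total, dtype=bool)
    obj = np.full(n_total, "", dtype=object)
    gdist = np.full(n_total, np.nan)
    pathpos = traj.positions[:, 0]

    for (i_on, i_off, cx, cy, ux, uy, oidx, bg, bg_dist,
         contaminant, c_dist) in fix_info:
        m = i_off - i_on
        tt = np.arange(m) / rate
        sl = slice(i_on, i_off)
        x[sl] = cx + ux * tt
        y[sl] = cy + uy * tt
        valid[sl] = True
        if oidx is None:
            obj[sl] = bg
            gdist[sl] = bg_dist
        else:
            # per-sample distance to the fixated object's anchor point
            d = np.hypot(sched.obj_pos[oidx] - pathpos[sl],
                         sched.obj_lat[oidx])
            obj[sl] = sched.obj_ids[oidx]
            gdist[sl] = d
            if cfg.contamination_prob > 0 and contaminant is not None:
                mask = rng.random(m) < cfg.contamination_prob
                if mask.any():
                    idx = np.nonzero(mask)[0] + i_on
                    obj[idx] = contaminant
                    gdist[idx] = c_dist

    for (i_on, i_off, x0, y0, x1, y1) in sacc_info:
        m = i_off - i_on
        phase = (np.arange(m) + 1.0) / m
        prof = 0.5 * (1.0 - np.cos(np.pi * phase))
        sl = slice(i_on, i_off)
        x[sl] = x0 + (x1 - x0) * prof
        y[sl] = y0 + (y1 - y0) * prof
        valid[sl] = True
        obj[sl] = TERRAIN_ID
        gdist[sl] = cfg.terrain_distance_median_m

    noise = rng.normal(0.0, cfg.position_noise_sd_deg, (2, n_total))
    x = np.where(valid, x + noise[0], np.nan)
    y = np.where(valid, y + noise[1], np.nan)
    obj[~valid] = ""

    return pd.DataFrame({
        "t_s": traj.times,
        "x_deg": x,
        "y_deg": y,
        "valid": valid.astype(np.int8),
        "object_id": obj,
        "obs_x_m": traj.positions[:, 0],
        "obs_y_m": traj.positions[:, 1],
        "obs_z_m": traj.positions[:, 2],
        "gaze_distance_m": np.where(valid, gdist, np.nan),
    })


def _truth_frame(events: list, rate: float) -> GroundTruthLog:
    rows = []
    for etype, i_on, i_off, obj_label, amp, peak in events:
        if i_off <= i_on:
            continue
        if etype == "gap":
            dur = (i_off - i_on) / rate
            etype = "blink" if 0.050 <= dur <= 0.500 else "dropout"
        rows.append((etype, i_on / rate, i_off / rate, obj_label, amp, peak))
    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return GroundTruthLog(events=df)
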