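"""Adaptive velocity-threshold detection of saccades, fixations, and gaps.

The detector follows the adaptive (median-dispersion) velocity-threshold
family of algorithms: gaze velocity is computed with a 5-sample central
difference, per-component thresholds are six times a median-based dispersion
of the velocity series, suprathreshold runs of at least 12 ms become
saccades, inter-saccadic intervals of at least 50 ms become fixations
(qualifying at >= 100 ms), and invalid-sample gaps are classified as blinks
(50-500 ms) or dropouts (anything else).  When two saccades fall within the
minimum fixation duration of each other, only the larger is kept.

All rules operate on integer sample counts so that event boundaries are
reproducible and exactly comparable with a brute-force reference scan.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DetectionParams

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "event_type", "t_on_s", "t_off_s", "duration_s", "amplitude_deg",
    "peak_vel_deg_s", "angle_deg", "qualifying", "object_id",
    "mean_distance_m", "i_on", "i_off",
]


class DetectionError(ValueError):
    """Raised when the sample stream cannot support detection."""


@dataclass
class VelocitySeries:
    """Component velocities aligned to samples, with a defined-mask.

    Velocity is undefined (masked) wherever the 5-sample window crosses a
    stream edge or an invalid sample.
    """

    times: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    defined: np.ndarray
    valid: np.ndarray  # raw per-sample validity of the input stream
    dt: float


def _min_samples(duration_s: float, rate: float) -> int:
    """Smallest run length (in samples) whose duration >= duration_s."""
    return int(np.ceil(duration_s * rate - 1e-9))


def _max_samples(duration_s: float, rate: float) -> int:
    return int(np.floor(duration_s * rate + 1e-9))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of maximal True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    stops = np.nonzero(d == -1)[0] + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        stops = np.concatenate((stops, [len(mask)]))
    return list(zip(starts.tolist(), stops.tolist()))


def compute_velocity(samples: pd.DataFrame,
                     params: DetectionParams | None = None) -> VelocitySeries:
    """5-sample central-difference velocity of the gaze position trace.

    v_n = (x_{n+2} + x_{n+1} - x_{n-1} - x_{n-2}) / (6 * dt), masked where the
    window touches a stream edge or an invalid sample.
    """
    params = params or DetectionParams()
    t = samples["t_s"].to_numpy(dtype=float)
    if len(t) < 5:
        raise DetectionError("stream shorter than the velocity window")
    dt = float(np.median(np.diff(t)))
    x = samples["x_deg"].to_numpy(dtype=float)
    y = samples["y_deg"].to_numpy(dtype=float)
    valid = samples["valid"].to_numpy().astype(bool)
    n = len(t)

    vx = np.full(n, np.nan)
    vy = np.full(n, np.nan)
    denom = 6.0 * dt
    vx[2:-2] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / denom
    vy[2:-2] = (y[4:] + y[3:-1] - y[1:-3] - y[:-4]) / denom

    # window fully valid: all of n-2..n+2 valid
    ok = np.zeros(n, dtype=bool)
    v = valid.astype(np.int8)
    win = v[:-4] + v[1:-3] + v[2:-2] + v[3:-1] + v[4:]
    ok[2:-2] = win == 5
    ok &= np.isfinite(vx) & np.isfinite(vy)
    if ok.sum() < 5:
        raise DetectionError("fewer than 5 samples with defined velocity")
    return VelocitySeries(times=t, vx=vx, vy=vy, defined=ok, valid=valid, dt=dt)


def estimate_thresholds(vel: VelocitySeries,
                        params: DetectionParams | None = None,
                        ) -> tuple[float, float]:
    """Per-component saccade thresholds.

    With the default ``median_estimator='dispersion'`` the dispersion is the
    median-based estimator sigma = sqrt(median(v^2) - median(v)^2); with
    ``'literal'`` it is median(|v|).  The threshold is ``velocity_factor``
    times the dispersion, floored at ``threshold_floor``.
    """
    params = params or DetectionParams()
    etas = []
    for v in (vel.vx[vel.defined], vel.vy[vel.defined]):
        if params.median_estimator == "dispersion":
            sig2 = np.median(v**2) - np.median(v) ** 2
            sigma = float(np.sqrt(max(sig2, 0.0)))
        else:
            sigma = float(np.median(np.abs(v)))
        eta = params.velocity_factor * sigma
        if sigma <= 0.0:
            warnings.warn("degenerate (zero-dispersion) velocity series; "
                          "using the threshold floor", stacklevel=2)
            logger.warning("threshold floor applied (sigma = 0)")
        etas.append(max(eta, params.threshold_floor))
    return etas[0], etas[1]


def detect_saccades(vel: VelocitySeries, eta: tuple[float, float],
                    params: DetectionParams | None = None) -> pd.DataFrame:
    """Saccades as maximal suprathreshold runs, with the largest-saccade rule.

    A sample is suprathreshold when (vx/eta_x)^2 + (vy/eta_y)^2 > 1.  Runs of
    at least the minimum saccade duration become events; within each
    contiguous valid segment, pairs separated by less than the minimum
    fixation duration are reduced to the larger-amplitude member (iterated
    left-to-right; earlier wins amplitude ties).
    """
    params = params or DetectionParams()
    ex, ey = eta
    if ex <= 0 or ey <= 0:
        raise DetectionError("thresholds must be positive")
    rate = 1.0 / vel.dt
    n_min = _min_samples(params.min_saccade_dur, rate)
    gap_min = _min_samples(params.min_fixation_dur, rate)

    crit = np.zeros(len(vel.times), dtype=bool)
    with np.errstate(invalid="ignore"):
        crit[vel.defined] = ((vel.vx[vel.defined] / ex) ** 2
                             + (vel.vy[vel.defined] / ey) ** 2) > 1.0

    sacc = []
    for i_on, i_off in _runs(crit):
        if i_off - i_on >= n_min:
            sacc.append((i_on, i_off))
    sacc = _largest_saccade_rule(sacc, vel, gap_min)

    rows = []
    x = _positions(vel)
    for i_on, i_off in sacc:
        dx = x[0][i_off - 1] - x[0][i_on]
        dy = x[1][i_off - 1] - x[1][i_on]
        amp = float(np.hypot(dx, dy))
        speed = np.hypot(vel.vx[i_on:i_off], vel.vy[i_on:i_off])
        peak = float(np.nanmax(speed))
        rows.append({
            "event_type": "saccade",
            "t_on_s": vel.times[i_on],
            "t_off_s": _t_off(vel, i_off),
            "duration_s": (i_off - i_on) * vel.dt,
            "amplitude_deg": amp,
            "peak_vel_deg_s": peak,
            "angle_deg": float(np.degrees(np.arctan2(dy, dx))),
            "qualifying": True,
            "object_id": "",
            "mean_distance_m": np.nan,
            "i_on": i_on,
            "i_off": i_off,
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _positions(vel: VelocitySeries) -> tuple[np.ndarray, np.ndarray]:
    # positions reconstructed lazily: stored on the series by detect_events;
    # fall back to integrating velocity is wrong, so require attachment.
    if not hasattr(vel, "_x"):
        raise DetectionError("VelocitySeries lacks attached positions; "
                             "use detect_events or attach_positions")
    return vel._x  # type: ignore[attr-defined]


def attach_positions(vel: VelocitySeries, samples: pd.DataFrame) -> VelocitySeries:
    vel._x = (samples["x_deg"].to_numpy(dtype=float),  # type: ignore[attr-defined]
              samples["y_deg"].to_numpy(dtype=float))
    return vel


def _t_off(vel: VelocitySeries, i_off: int) -> float:
    if i_off < len(vel.times):
        return float(vel.times[i_off])
    return float(vel.times[-1] + vel.dt)


def _largest_saccade_rule(sacc: list[tuple[int, int]], vel: VelocitySeries,
                          gap_min: int) -> list[tuple[int, int]]:
    """Keep only the larger of two saccades closer than the minimum fixation
    duration, iterating left-to-right until stable.  Pairs split by an
    invalid gap are never merged (a blink separates them)."""
    if not hasattr(vel, "_x"):
        raise DetectionError("positions not attached")
    x, y = vel._x  # type: ignore[attr-defined]

    def amplitude(run: tuple[int, int]) -> float:
        i_on, i_off = run
        return float(np.hypot(x[i_off - 1] - x[i_on], y[i_off - 1] - y[i_on]))

    changed = True
    while changed:
        changed = False
        out: list[tuple[int, int]] = []
        k = 0
        while k < len(sacc):
            if k + 1 < len(sacc):
                gap_lo, gap_hi = sacc[k][1], sacc[k + 1][0]
                same_segment = vel.valid[gap_lo:gap_hi].all()
                if same_segment and (gap_hi - gap_lo) < gap_min:
                    a0, a1 = amplitude(sacc[k]), amplitude(sacc[k + 1])
                    out.append(sacc[k] if a0 >= a1 else sacc[k + 1])
                    k += 2
                    changed = True
                    continue
            out.append(sacc[k])
            k += 1
        sacc = out
    return sacc


def classify_gaps(samples: pd.DataFrame,
                  params: DetectionParams | None = None) -> pd.DataFrame:
    """Each maximal invalid run becomes one blink (50-500 ms, inclusive) or
    dropout event."""
    params = params or DetectionParams()
    t = samples["t_s"].to_numpy(dtype=float)
    valid = samples["valid"].to_numpy().astype(bool)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    rate = 1.0 / dt
    lo = _min_samples(params.blink_gap_range[0], rate)
    hi = _max_samples(params.blink_gap_range[1], rate)

    rows = []
    for i_on, i_off in _runs(~valid):
        n = i_off - i_on
        etype = "blink" if lo <= n <= hi else "dropout"
        rows.append({
            "event_type": etype,
            "t_on_s": t[i_on],
            "t_off_s": t[i_off] if i_off < len(t) else t[-1] + dt,
            "duration_s": n * dt,
            "amplitude_deg": np.nan,
            "peak_vel_deg_s": np.nan,
            "angle_deg": np.nan,
            "qualifying": False,
            "object_id": "",
            "mean_distance_m": np.nan,
            "i_on": i_on,
            "i_off": i_off,
        })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def extract_fixations(saccades: pd.DataFrame, samples: pd.DataFrame,
                      params: DetectionParams | None = None) -> pd.DataFrame:
    """Fixations as inter-saccadic intervals within contiguous valid segments.

    Intervals of at least the minimum fixation duration (50 ms) become
    fixation events; the qualifying flag marks those of at least 100 ms.
    Shorter residual intervals remain unclassified (no event).  Fixations
    never span gaps: each valid segment is treated independently.
    """
    params = params or DetectionParams()
    t = samples["t_s"].to_numpy(dtype=float)
    valid = samples["valid"].to_numpy().astype(bool)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    rate = 1.0 / dt
    n_fix = _min_samples(params.min_fixation_dur, rate)
    n_qual = _min_samples(params.qualifying_fixation_dur, rate)

    sacc_bounds = list(zip(saccades["i_on"].astype(int),
                           saccades["i_off"].astype(int)))
    rows = []
    for seg_on, seg_off in _runs(valid):
        inside = [(a, b) for a, b in sacc_bounds if a >= seg_on and b <= seg_off]
        edges = [seg_on]
        for a, b in inside:
            edges.append(a)
            edges.append(b)
        edges.append(seg_off)
        for k in range(0, len(edges), 2):
            i_on, i_off = edges[k], edges[k + 1]
            n = i_off - i_on
            if n < n_fix:
                continue
            rows.append({
                "event_type": "fixation",
                "t_on_s": t[i_on],
                "t_off_s": t[i_off] if i_off < len(t) else t[-1] + dt,
                "duration_s": n * dt,
                "amplitude_deg": np.nan,
                "peak_vel_deg_s": np.nan,
                "angle_deg": np.nan,
                "qualifying": n >= n_qual,
                "object_id": "",
                "mean_distance_m": np.nan,
                "i_on": i_on,
                "i_off": i_off,
            })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def qc_main_sequence(saccades: pd.DataFrame,
                     params: DetectionParams | None = None,
                     ) -> tuple[pd.DataFrame, dict]:
    """Main-sequence quality screen plus plot data.

    Keeps saccades with duration in [12, 100] ms and peak velocity in
    [25, 1200] deg/s (inclusive); the report carries per-rule exclusion
    counts, the amplitude/peak-velocity pairs of the kept set (log-log main
    sequence), and a 1-degree-resolution angle histogram.
    """
    params = params or DetectionParams()
    dur_lo, dur_hi = params.qc_saccade_dur_range
    vel_lo, vel_hi = params.qc_peak_vel_range
    eps = 1e-9
    dur = saccades["duration_s"]
    peak = saccades["peak_vel_deg_s"]
    ok_dur = (dur >= dur_lo - eps) & (dur <= dur_hi + eps)
    ok_vel = (peak >= vel_lo) & (peak <= vel_hi)
    kept = saccades[ok_dur & ok_vel].reset_index(drop=True)

    angles = kept["angle_deg"].to_numpy()
    hist, edges = np.histogram(angles, bins=360, range=(-180.0, 180.0))
    report = {
        "n_input": int(len(saccades)),
        "n_kept": int(len(kept)),
        "excluded_duration": int((~ok_dur).sum()),
        "excluded_peak_velocity": int((~ok_vel).sum()),
        "main_sequence": pd.DataFrame({
            "amplitude_deg": kept["amplitude_deg"],
            "peak_vel_deg_s": kept["peak_vel_deg_s"],
        }),
        "angle_hist": pd.DataFrame({
            "angle_deg": (edges[:-1] + edges[1:]) / 2.0,
            "count": hist,
        }),
    }
    return kept, report


def detect_events(samples: pd.DataFrame,
                  params: DetectionParams | None = None,
                  ) -> tuple[pd.DataFrame, dict]:
    """Full detection pass: velocity, thresholds, saccades, fixations, gaps.

    Returns a time-ordered event table (saccade/fixation/blink/dropout) and a
    QC report including the per-session thresholds.
    """
    params = params or DetectionParams()
    params.validate()
    vel = compute_velocity(samples, params)
    attach_positions(vel, samples)
    eta = estimate_thresholds(vel, params)
    saccades = detect_saccades(vel, eta, params)
    fixations = extract_fixations(saccades, samples, params)
    gaps = classify_gaps(samples, params)
    frames = [f for f in (saccades, fixations, gaps) if len(f)]
    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = pd.DataFrame(columns=EVENT_COLUMNS)
    events = events.sort_values("i_on", kind="mergesort").reset_index(drop=True)
    _, qc = qc_main_sequence(saccades, params)
    qc["thresholds_deg_s"] = {"x": eta[0], "y": eta[1]}
    return events, qc
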