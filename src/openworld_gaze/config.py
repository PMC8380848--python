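"""Configuration objects for the simulator, detector, labeler, and study runner.

Every tunable default of the package lives here, mirrored in the shipped
``defaults.yaml`` (the versioned default-config file).  Detection constants
follow the adaptive velocity-threshold literature (velocity factor 6, 12 ms
minimum saccade, 50 ms minimum inter-saccadic interval, 100 ms qualifying
fixation, 50-500 ms blink gaps); generator defaults are calibrated so that the
full pipeline recovers the study-level descriptive statistics documented in
``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

CONDITIONS = ("humvee", "motorcycle", "aircraft", "furniture")

TERRAIN_ID = "terrain"
SKY_ID = "sky"


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class EnvironmentConfig:
    """Scene-catalog composition and placement.

    Surface areas are lognormal per class: ``(median_m2, sigma)``.  Visibility
    range grows with the square root of surface area (larger objects are
    visible from further away) and is clipped to a plausible band.
    """

    path_length_m: float = 2000.0
    n_targets_per_condition: int = 15
    n_other: int = 166
    n_trail_markers: int = 19
    lateral_offset_sd_m: float = 6.0
    placement_jitter: float = 0.35
    surface_area: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "humvee": (22.0, 0.15),
            "motorcycle": (2.8, 0.20),
            "aircraft": (35.0, 0.50),
            "furniture": (3.5, 0.70),
            "other": (8.0, 1.00),
            "trail_marker": (0.5, 0.10),
        }
    )
    visibility_coeff: float = 30.0
    visibility_exponent: float = 0.15
    visibility_min_m: float = 25.0
    visibility_max_m: float = 90.0

    def validate(self) -> None:
        _require(self.path_length_m > 0, "path_length_m must be positive")
        _require(self.n_targets_per_condition >= 0, "negative target count")
        _require(self.n_other >= 0, "negative object count")
        _require(self.n_trail_markers >= 0, "negative trail-marker count")
        for cls, (med, sig) in self.surface_area.items():
            _require(med > 0 and sig >= 0, f"bad surface-area params for {cls}")


@dataclass
class NavConfig:
    """Navigation-trajectory generation.

    The traversal time of the full path is drawn around ``mean_duration_s``;
    the dual-task (math) epoch multiplies speed by
    ``dual_task_speed_multiplier``.  Speed noise is a multiplicative
    log-AR(1) process with time constant ``speed_noise_tau_s``.
    """

    mean_duration_s: float = 680.0
    sd_duration_s: float = 40.0
    speed_noise_sd: float = 0.12
    speed_noise_tau_s: float = 5.0
    eye_height_m: float = 1.7
    math_onset_s: float = 480.0
    dual_task_speed_multiplier: float = 0.76
    # math-task trial schedule
    math_n_trials: int = 3
    math_numbers_per_trial: tuple[int, int] = (3, 4)
    math_number_audio_s: float = 1.0
    math_pause_range_s: tuple[float, float] = (3.0, 4.0)
    math_response_s: float = 4.0
    math_break_range_s: tuple[float, float] = (8.0, 30.0)

    def validate(self) -> None:
        _require(self.mean_duration_s > 0, "mean_duration_s must be positive")
        _require(
            0.0 < self.dual_task_speed_multiplier <= 1.0,
            "dual_task_speed_multiplier must lie in (0, 1]",
        )
        _require(self.math_onset_s >= 0, "math_onset_s must be non-negative")


@dataclass
class GazeConfig:
    """Gaze-stream generation.

    Fixation durations are lognormal (median ``fixation_median_s``) with a
    separate mass of short (50-99 ms) fixations.  Saccades follow a main
    sequence via an amplitude-dependent duration ``d0 + d1*A`` and a
    raised-cosine velocity profile.  Object choice is a Markov scheduler over
    currently visible objects with area- and distance-dependent weights,
    refixation bursts, and target-preference multipliers.  Dual-task modifiers
    apply inside the math epoch.
    """

    sampling_rate_hz: float = 300.0
    # fixation durations
    fixation_median_s: float = 0.30
    fixation_sigma: float = 0.68
    fixation_max_s: float = 4.0
    short_fixation_prob: float = 0.10
    # within-fixation kinematics
    position_noise_sd_deg: float = 0.03
    drift_speed_max_deg_s: float = 3.0
    # saccade main sequence: duration = d0 + d1 * amplitude, jittered
    saccade_d0_s: float = 0.020
    saccade_d1_s_per_deg: float = 0.0022
    saccade_dur_jitter: float = 0.10
    saccade_dur_range_s: tuple[float, float] = (0.012, 0.090)
    new_target_amp_median_deg: float = 5.0
    new_target_amp_sigma: float = 0.60
    refix_amp_median_deg: float = 1.3
    refix_amp_sigma: float = 0.50
    amp_range_deg: tuple[float, float] = (0.3, 25.0)
    # saccade-direction field (horizontal-biased wrapped-normal mixture)
    angle_horizontal_weight: float = 0.70
    angle_horizontal_sd_deg: float = 25.0
    gaze_extent_x_deg: float = 18.0
    gaze_extent_y_deg: float = 7.0
    # gaps
    blink_prob_per_boundary: float = 0.14
    blink_median_s: float = 0.150
    blink_sigma: float = 0.45
    blink_range_s: tuple[float, float] = (0.060, 0.450)
    dropout_short_prob: float = 0.010
    dropout_short_range_s: tuple[float, float] = (0.010, 0.040)
    dropout_long_prob: float = 0.010
    dropout_long_range_s: tuple[float, float] = (0.60, 2.0)
    # object scheduler
    background_prob: float = 0.505
    background_burst_mean: float = 5.2
    terrain_share: float = 0.80
    area_exponent: float = 0.15
    distance_decay_m: float = 70.0
    burst_mean: float = 5.8
    target_weight_mult: float = 1.05
    target_inspection_prob: float = 0.93
    target_burst_mult: float = 1.25
    target_dwell_factor: float = 0.955
    target_distance_decay_m: float = 60.0
    contamination_prob: float = 0.05
    terrain_distance_median_m: float = 25.0
    sky_distance_m: float = 1000.0
    # dual-task modifiers
    math_blink_mult: float = 1.48
    math_burst_mult: float = 0.70
    math_target_switch_mult: float = 1.0

    def validate(self) -> None:
        _require(self.sampling_rate_hz > 0, "sampling_rate_hz must be positive")
        _require(
            0 < self.blink_range_s[0] < self.blink_range_s[1],
            "blink duration range must be positive and increasing",
        )
        for name in ("blink_prob_per_boundary", "dropout_short_prob",
                     "dropout_long_prob", "background_prob",
                     "contamination_prob", "short_fixation_prob"):
            _require(0 <= getattr(self, name) <= 1, f"{name} must lie in [0, 1]")
        _require(self.burst_mean >= 1, "burst_mean must be >= 1")
        _require(self.fixation_median_s > 0, "fixation_median_s must be positive")


@dataclass
class DetectionParams:
    """Adaptive velocity-threshold detector parameters.

    The saccade threshold per component is ``velocity_factor`` times a
    median-based dispersion of the velocity series (see
    :func:`openworld_gaze.detection.estimate_thresholds`).
    """

    velocity_factor: float = 6.0
    min_saccade_dur: float = 0.012
    min_fixation_dur: float = 0.050
    qualifying_fixation_dur: float = 0.100
    blink_gap_range: tuple[float, float] = (0.050, 0.500)
    velocity_window: int = 5
    qc_saccade_dur_range: tuple[float, float] = (0.012, 0.100)
    qc_peak_vel_range: tuple[float, float] = (25.0, 1200.0)
    threshold_floor: float = 5.0
    median_estimator: str = "dispersion"  # or "literal"

    def validate(self) -> None:
        for name in ("velocity_factor", "min_saccade_dur", "min_fixation_dur",
                     "qualifying_fixation_dur", "threshold_floor"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        _require(
            self.min_fixation_dur <= self.qualifying_fixation_dur,
            "min_fixation_dur must not exceed qualifying_fixation_dur",
        )
        _require(
            self.blink_gap_range[0] < self.blink_gap_range[1],
            "blink_gap_range must be increasing",
        )
        _require(self.median_estimator in ("dispersion", "literal"),
                 "median_estimator must be 'dispersion' or 'literal'")


@dataclass
class LabelingParams:
    """Fixation-to-object assignment parameters (dominance rule)."""

    dominance_threshold: float = 0.10
    exclude_classes: tuple[str, ...] = (TERRAIN_ID, SKY_ID)
    count_invalid_in_denominator: bool = True
    dominance_among_excluded: bool = False
    sweep_thresholds: tuple[float, ...] = (0.0, 0.01, 0.10, 0.20, 0.50)

    def validate(self) -> None:
        _require(0.0 <= self.dominance_threshold <= 1.0,
                 "dominance_threshold must lie in [0, 1]")


@dataclass
class MetricsParams:
    """Session/cohort metric options and exclusion rules."""

    dropout_exclusion_frac: float = 0.25
    timeout_s: float = 1200.0
    min_validated_targets: int = 10
    outlier_sd: float = 3.0
    normalized_sign: str = "subject_minus_global"  # or "global_minus_subject"

    def validate(self) -> None:
        _require(0 < self.dropout_exclusion_frac <= 1, "bad dropout threshold")
        _require(self.outlier_sd > 0, "outlier_sd must be positive")


@dataclass
class StudyConfig:
    """Full study: cohort composition plus all stage configs."""

    n_subjects: dict[str, int] = field(
        default_factory=lambda: {
            "humvee": 15, "motorcycle": 14, "aircraft": 9, "furniture": 7,
        }
    )
    master_seed: int = 1
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    navigation: NavConfig = field(default_factory=NavConfig)
    gaze: GazeConfig = field(default_factory=GazeConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    labeling: LabelingParams = field(default_factory=LabelingParams)
    metrics: MetricsParams = field(default_factory=MetricsParams)
    tolerances: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "t1": (0.27, 0.33),
            "t2": (1.86, 2.26),
            "t3": (6.1, 8.1),
            "t4": (2.30, 2.90),
            "t5": (42.0, 52.0),
            "t6": (37.0, 57.0),
            "t7": (31.0, 51.0),
            "t8": (19.0, 29.0),
            "t9": (36.0, 56.0),
            "t10": (15.0, 15.0),
            "t11": (19.0, 19.0),
            "t12": (166.0, 166.0),
        }
    )

    def validate(self) -> None:
        for cond, n in self.n_subjects.items():
            _require(cond in CONDITIONS, f"unknown condition {cond!r}")
            _require(n >= 0, "negative subject count")
        for sub in (self.environment, self.navigation, self.gaze,
                    self.detection, self.labeling, self.metrics):
            sub.validate()

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return _asdict_plain(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        cfg = cls(
            n_subjects=dict(d.get("n_subjects", cls().n_subjects)),
            master_seed=int(d.get("master_seed", 1)),
            environment=_from_dict(EnvironmentConfig, d.get("environment", {})),
            navigation=_from_dict(NavConfig, d.get("navigation", {})),
            gaze=_from_dict(GazeConfig, d.get("gaze", {})),
            detection=_from_dict(DetectionParams, d.get("detection", {})),
            labeling=_from_dict(LabelingParams, d.get("labeling", {})),
            metrics=_from_dict(MetricsParams, d.get("metrics", {})),
            tolerances={k: tuple(v) for k, v in d.get(
                "tolerances", cls().tolerances).items()},
        )
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _asdict_plain(obj: Any) -> Any:
    """dataclasses.asdict with tuples rendered as lists (YAML/JSON friendly)."""
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _asdict_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_asdict_plain(v) for v in obj]
    return obj


def _from_dict(cls: type, d: dict[str, Any]) -> Any:
    defaults = cls()
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            val = d[f.name]
            cur = getattr(defaults, f.name)
            if isinstance(cur, tuple):
                val = tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                            for v in val)
            if isinstance(cur, dict):
                val = {k: tuple(v) if isinstance(v, (list, tuple)) else v
                       for k, v in val.items()}
            kwargs[f.name] = val
    obj = cls(**kwargs)
    obj.validate()
    return obj


def default_config() -> StudyConfig:
    """The shipped default configuration (contents of ``defaults.yaml``)."""
    with resources.files("openworld_gaze").joinpath("defaults.yaml").open() as fh:
        return StudyConfig.from_dict(yaml.safe_load(fh))


def load_config(path: str | Path) -> StudyConfig:
    """Load a YAML or JSON study config from ``path``."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return StudyConfig.from_dict(json.loads(text))
    return StudyConfig.from_dict(yaml.safe_load(text))


def dump_config(cfg: StudyConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
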