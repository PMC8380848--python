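"""Scene catalog for the open-world trail environment.

The world is modelled as a 1-D trail of length ``path_length_m`` with objects
placed at semi-regular arc-length intervals and signed lateral offsets from
the centerline.  Four target classes (humvee, motorcycle, aircraft, furniture)
have 15 instances each; every other labelable object ("other" clutter and the
19 trail markers) is a distractor for every condition.  Terrain and sky are
singleton pseudo-objects that collect background gaze and are excluded from
object-level analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CONDITIONS, SKY_ID, TERRAIN_ID, ConfigError, EnvironmentConfig

BACKGROUND_IDS = (TERRAIN_ID, SKY_ID)

OBJECT_COLUMNS = [
    "object_id", "object_class", "path_position_m", "lateral_offset_m",
    "surface_area_m2", "max_visibility_range_m",
]


@dataclass(frozen=True)
class SceneObject:
    """One environment object (or background pseudo-object)."""

    object_id: str
    object_class: str
    path_position_m: float
    lateral_offset_m: float
    surface_area_m2: float
    max_visibility_range_m: float


@dataclass
class Environment:
    """Scene catalog: an object table plus per-condition target-ID sets."""

    catalog: pd.DataFrame
    path_length_m: float
    target_ids_by_condition: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def labelable(self) -> pd.DataFrame:
        """Objects eligible for fixation labels (everything but terrain/sky)."""
        return self.catalog[~self.catalog["object_id"].isin(BACKGROUND_IDS)]

    def target_ids(self, condition: str) -> tuple[str, ...]:
        if condition not in self.target_ids_by_condition:
            raise KeyError(f"unknown condition {condition!r}")
        return self.target_ids_by_condition[condition]

    def distractor_ids(self, condition: str) -> tuple[str, ...]:
        """Labelable objects outside the condition's target set."""
        targets = set(self.target_ids(condition))
        ids = self.labelable["object_id"]
        return tuple(ids[~ids.isin(targets)])

    def objects(self) -> list[SceneObject]:
        return [SceneObject(**row) for row in
                self.catalog[OBJECT_COLUMNS].to_dict("records")]


def _visibility_range(area: np.ndarray, cfg: EnvironmentConfig) -> np.ndarray:
    return np.clip(cfg.visibility_coeff * area ** cfg.visibility_exponent,
                   cfg.visibility_min_m, cfg.visibility_max_m)


def build_environment(config: EnvironmentConfig | None = None,
                      seed: int = 0) -> Environment:
    """Build a deterministic scene catalog.

    Objects are shuffled into a single random sequence and placed at
    semi-regular intervals (uniform spacing with seeded jitter) along the
    trail.  For a fixed ``(config, seed)`` the catalog is bit-identical across
    calls.
    """
    cfg = config or EnvironmentConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    ids: list[str] = []
    classes: list[str] = []
    for cond in CONDITIONS:
        for i in range(cfg.n_targets_per_condition):
            ids.append(f"{cond}_{i:02d}")
            classes.append(cond)
    for i in range(cfg.n_other):
        ids.append(f"other_{i:03d}")
        classes.append("other")
    for i in range(cfg.n_trail_markers):
        ids.append(f"trail_marker_{i:02d}")
        classes.append("trail_marker")

    n = len(ids)
    order = rng.permutation(n)
    ids_arr = np.array(ids, dtype=object)[order]
    cls_arr = np.array(classes, dtype=object)[order]

    if n > 0:
        spacing = cfg.path_length_m / n
        base = (np.arange(n) + 0.5) * spacing
        jitter = rng.uniform(-cfg.placement_jitter, cfg.placement_jitter, n) * spacing
        pos = np.clip(base + jitter, 0.0, cfg.path_length_m)
    else:
        pos = np.empty(0)
    lateral = rng.normal(0.0, cfg.lateral_offset_sd_m, n)

    areas = np.empty(n)
    for cls, (med, sig) in cfg.surface_area.items():
        m = cls_arr == cls
        areas[m] = med * np.exp(rng.normal(0.0, sig, int(m.sum())))
    unknown = ~np.isin(cls_arr, list(cfg.surface_area))
    if unknown.any():
        raise ConfigError(f"no surface-area params for classes "
                          f"{sorted(set(cls_arr[unknown]))}")

    cat = pd.DataFrame({
        "object_id": ids_arr,
        "object_class": cls_arr,
        "path_position_m": pos,
        "lateral_offset_m": lateral,
        "surface_area_m2": areas,
        "max_visibility_range_m": _visibility_range(areas, cfg),
    })
    background = pd.DataFrame({
        "object_id": [TERRAIN_ID, SKY_ID],
        "object_class": [TERRAIN_ID, SKY_ID],
        "path_position_m": [np.nan, np.nan],
        "lateral_offset_m": [0.0, 0.0],
        "surface_area_m2": [1e6, 1e6],
        "max_visibility_range_m": [np.inf, np.inf],
    })
    cat = pd.concat([cat, background], ignore_index=True)

    targets = {
        cond: tuple(f"{cond}_{i:02d}" for i in range(cfg.n_targets_per_condition))
        for cond in CONDITIONS
    }
    return Environment(catalog=cat, path_length_m=cfg.path_length_m,
                       target_ids_by_condition=targets)
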