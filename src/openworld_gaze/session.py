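"""Session records and the on-disk session-directory format.

A session directory holds ``session.json`` (metadata), ``objects.csv`` (the
scene catalog), ``samples.csv`` (the 300 Hz gaze stream) and
``truth_events.csv`` (the simulator's ground-truth log; absent for real
recordings).  All CSVs are RFC-4180, UTF-8, with a header row; floats are
written in shortest round-trip representation so ``read_session(write_session
(s)) == s`` holds bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GazeConfig, NavConfig
from .navigate import simulate_navigation
from .simulate import GroundTruthLog, SAMPLE_COLUMNS, TRUTH_COLUMNS, simulate_gaze
from .world import Environment, OBJECT_COLUMNS


class SessionFormatError(ValueError):
    """A session file violates the schema (reports file, line, column)."""

    def __init__(self, file: str, line: int | None, column: str | None,
                 message: str):
        self.file, self.line, self.column = file, line, column
        loc = file
        if line is not None:
            loc += f":{line}"
        if column is not None:
            loc += f" (column {column})"
        super().__init__(f"{loc}: {message}")


@dataclass
class SessionRecord:
    """One subject's run: metadata, environment, samples, and truth."""

    subject_id: str
    condition: str
    seed: int
    math_task_interval: tuple[float, float]
    math_completed: bool
    environment: Environment
    samples: pd.DataFrame
    truth: GroundTruthLog | None = None
    config_hash: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        n = len(self.samples)
        dt = self.samples["t_s"].iloc[1] - self.samples["t_s"].iloc[0]
        return float(n * dt)

    @property
    def dropout_fraction(self) -> float:
        return float(1.0 - self.samples["valid"].mean())


def simulate_session(env: Environment, condition: str, seed: int,
                     nav_config: NavConfig | None = None,
                     gaze_config: GazeConfig | None = None,
                     subject_id: str | None = None,
                     config_hash: str = "") -> SessionRecord:
    """Generate one complete synthetic session (navigation + gaze + truth)."""
    gcfg = gaze_config or GazeConfig()
    traj = simulate_navigation(env, nav_config, seed=seed,
                               rate_hz=gcfg.sampling_rate_hz)
    samples, truth = simulate_gaze(env, traj, gcfg, seed=seed + 1,
                                   condition=condition)
    return SessionRecord(
        subject_id=subject_id or f"{condition}_s{seed}",
        condition=condition,
        seed=seed,
        math_task_interval=traj.math_task_interval,
        math_completed=traj.math_completed,
        environment=env,
        samples=samples,
        truth=truth,
        config_hash=config_hash,
    )


def write_session(session: SessionRecord, out_dir: str | Path) -> dict:
    """Write a session directory; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": session.subject_id,
        "condition": session.condition,
        "seed": session.seed,
        "math_task_interval": list(session.math_task_interval),
        "math_completed": session.math_completed,
        "config_hash": session.config_hash,
        "path_length_m": session.environment.path_length_m,
        "target_ids_by_condition": {
            k: list(v)
            for k, v in session.environment.target_ids_by_condition.items()
        },
    }
    (out / "session.json").write_text(json.dumps(meta, indent=1))
    session.environment.catalog[OBJECT_COLUMNS].to_csv(
        out / "objects.csv", index=False)
    session.samples[SAMPLE_COLUMNS].to_csv(out / "samples.csv", index=False)
    if session.truth is not None:
        session.truth.events[TRUTH_COLUMNS].to_csv(
            out / "truth_events.csv", index=False)
    manifest = {"dir": str(out), "files": sorted(
        p.name for p in out.iterdir() if p.is_file())}
    return manifest


def read_session(in_dir: str | Path) -> SessionRecord:
    """Read a session directory written by :func:`write_session`."""
    d = Path(in_dir)
    try:
        meta = json.loads((d / "session.json").read_text())
    except FileNotFoundError:
        raise SessionFormatError("session.json", None, None, "missing file")
    except json.JSONDecodeError as e:
        raise SessionFormatError("session.json", e.lineno, None, e.msg)

    objects = _read_csv(d / "objects.csv", OBJECT_COLUMNS,
                        {"object_id": "string", "object_class": "string"})
    objects["object_id"] = objects["object_id"].astype(object)
    objects["object_class"] = objects["object_class"].astype(object)
    env = Environment(
        catalog=objects,
        path_length_m=float(meta.get("path_length_m", np.nan)),
        target_ids_by_condition={
            k: tuple(v)
            for k, v in meta.get("target_ids_by_condition", {}).items()
        },
    )

    samples = _read_csv(d / "samples.csv", SAMPLE_COLUMNS, {})
    samples["object_id"] = samples["object_id"].fillna("").astype(object)
    samples["valid"] = samples["valid"].astype(np.int8)
    t = samples["t_s"].to_numpy()
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise SessionFormatError("samples.csv", int(bad[0]) + 3, "t_s",
                                 "timestamps not strictly increasing")

    truth = None
    if (d / "truth_events.csv").exists():
        ev = _read_csv(d / "truth_events.csv", TRUTH_COLUMNS, {})
        ev["event_type"] = ev["event_type"].astype(object)
        ev["object_id"] = ev["object_id"].fillna("").astype(object)
        truth = GroundTruthLog(events=ev)

    return SessionRecord(
        subject_id=meta["subject_id"],
        condition=meta["condition"],
        seed=int(meta["seed"]),
        math_task_interval=tuple(meta["math_task_interval"]),
        math_completed=bool(meta.get("math_completed", True)),
        environment=env,
        samples=samples,
        truth=truth,
        config_hash=meta.get("config_hash", ""),
    )


def _read_csv(path: Path, expected_cols: list[str], dtypes: dict) -> pd.DataFrame:
    if not path.exists():
        raise SessionFormatError(path.name, None, None, "missing file")
    try:
        df = pd.read_csv(path, dtype=dtypes, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as e:
        raise SessionFormatError(path.name, None, None, str(e))
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise SessionFormatError(path.name, 1, missing[0],
                                 "missing required column")
    return df[expected_cols]


def sessions_equal(a: SessionRecord, b: SessionRecord) -> bool:
    """Field-for-field equality (used by round-trip tests)."""
    if (a.subject_id, a.condition, a.seed) != (b.subject_id, b.condition, b.seed):
        return False
    if tuple(a.math_task_interval) != tuple(b.math_task_interval):
        return False
    try:
        pd.testing.assert_frame_equal(
            a.samples[SAMPLE_COLUMNS].reset_index(drop=True),
            b.samples[SAMPLE_COLUMNS].reset_index(drop=True),
            check_dtype=False)
        pd.testing.assert_frame_equal(
            a.environment.catalog[OBJECT_COLUMNS].reset_index(drop=True),
            b.environment.catalog[OBJECT_COLUMNS].reset_index(drop=True),
            check_dtype=False)
        if (a.truth is None) != (b.truth is None):
            return False
        if a.truth is not None:
            pd.testing.assert_frame_equal(
                a.truth.events[TRUTH_COLUMNS].reset_index(drop=True),
                b.truth.events[TRUTH_COLUMNS].reset_index(drop=True),
                check_dtype=False)
    except AssertionError:
        return False
    return True


def derive_subject_seed(master_seed: int, condition: str, index: int) -> int:
    """Stable per-subject seed (documented so single sessions reproduce)."""
    import hashlib

    h = hashlib.sha256(f"{master_seed}:{condition}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
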