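"""End-to-end study orchestration: simulate -> detect -> label -> metrics.

``run_study`` generates the full synthetic cohort (default 45 subjects:
15 humvee / 14 motorcycle / 9 aircraft / 7 furniture), applies the
exclusion screen, and produces every table the analysis defines, fully
deterministically for a fixed master seed.  ``acceptance_values`` recomputes
the study-level recovery quantities (median fixation duration, fixation
rate, per-object fixations and dwell, background share, target-vs-distractor
and dual-task contrasts, environment composition) from scratch, and
``check_acceptance`` compares them against configured tolerance bands.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CONDITIONS, StudyConfig
from .detection import detect_events
from .labeling import label_session
from .metrics import (ConditionReport, condition_report,
                      dual_task_percent_changes, exclusion_screen,
                      global_means, normalize, per_object_metrics,
                      session_summary)
from .session import SessionRecord, derive_subject_seed, simulate_session
from .world import Environment, build_environment

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries stage, subject, and seed context."""

    def __init__(self, stage: str, subject_id: str, seed: int, cause: Exception):
        super().__init__(
            f"stage {stage!r} failed for subject {subject_id!r} "
            f"(seed {seed}): {cause}")
        self.stage, self.subject_id, self.seed = stage, subject_id, seed
        self.__cause__ = cause


@dataclass
class SubjectResult:
    subject_id: str
    condition: str
    seed: int
    meta: dict
    object_table: pd.DataFrame
    labels: pd.DataFrame
    summaries: list[dict]
    qc: dict


@dataclass
class StudyResult:
    config: StudyConfig
    environment: Environment
    subjects: dict[str, SubjectResult]
    exclusions: pd.DataFrame
    kept: list[str]
    kept_math: set[str]
    globals_table: pd.DataFrame
    norm_tables: dict[str, pd.DataFrame]
    summaries: pd.DataFrame
    report: ConditionReport
    dual_task: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def process_session(session: SessionRecord, config: StudyConfig,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Detect events and label qualifying fixations for one session."""
    events, qc = detect_events(session.samples, config.detection)
    events, labels = label_session(session, events, config.labeling)
    return events, labels, qc


def _subject_pass(session: SessionRecord, config: StudyConfig) -> SubjectResult:
    sid, seed = session.subject_id, session.seed
    try:
        events, labels, qc = process_session(session, config)
    except Exception as e:  # re-raise with stage context
        raise StageError("detect/label", sid, seed, e)
    try:
        summaries = [session_summary(session, events, labels, ep)
                     for ep in ("full", "during_math", "outside_math")]
        obj_table = per_object_metrics(labels, sid)
    except Exception as e:
        raise StageError("metrics", sid, seed, e)
    full = summaries[0]
    meta = {
        "subject_id": sid,
        "condition": session.condition,
        "seed": seed,
        "duration_s": session.duration_s,
        "dropout_fraction": session.dropout_fraction,
        "math_completed": session.math_completed,
        "gaze_validated_target_count": full["gaze_validated_target_count"],
    }
    qc_small = {k: v for k, v in qc.items()
                if k not in ("main_sequence", "angle_hist")}
    return SubjectResult(subject_id=sid, condition=session.condition,
                         seed=seed, meta=meta, object_table=obj_table,
                         labels=labels, summaries=summaries, qc=qc_small)


def iter_cohort(config: StudyConfig):
    """Yield (condition, index, seed) for every subject of the cohort."""
    for cond in CONDITIONS:
        for i in range(config.n_subjects.get(cond, 0)):
            yield cond, i, derive_subject_seed(config.master_seed, cond, i)


def run_study(config: StudyConfig | None = None,
              out_dir: str | Path | None = None,
              progress: bool = False) -> StudyResult:
    """Run the complete synthetic study.

    Deterministic for a fixed config: the environment seed is the master
    seed and each subject's seed is a stable hash of (master seed,
    condition, index).
    """
    config = config or StudyConfig()
    config.validate()
    env = build_environment(config.environment, seed=config.master_seed)

    subjects: dict[str, SubjectResult] = {}
    for cond, i, seed in iter_cohort(config):
        sid = f"{cond}_{i:02d}"
        try:
            session = simulate_session(
                env, cond, seed, config.navigation, config.gaze,
                subject_id=sid, config_hash=config.config_hash())
        except Exception as e:
            raise StageError("simulate", sid, seed, e)
        subjects[sid] = _subject_pass(session, config)
        if progress:
            logger.info("processed %s (seed %d)", sid, seed)
        del session

    metas = [s.meta for s in subjects.values()]
    kept, exclusions = exclusion_screen(metas, config.metrics)
    kept_math = set(exclusions[exclusions["kept_math"]]["subject_id"])
    for _, row in exclusions.iterrows():
        if row["reasons"]:
            logger.info("exclusion: %s -> %s", row["subject_id"], row["reasons"])

    kept_tables = [subjects[s].object_table for s in kept]
    globals_table = global_means(kept_tables, env) if kept_tables else None
    norm_tables = {
        s: normalize(subjects[s].object_table, globals_table, config.metrics)
        for s in kept
    }
    summaries = pd.DataFrame(
        [row for s in kept for row in subjects[s].summaries])
    conditions = {s: subjects[s].condition for s in kept}
    report = condition_report(norm_tables, conditions, env, summaries,
                              kept_math=kept_math)
    dual = dual_task_percent_changes(report.math_paired)

    manifest = {
        "package": "openworld-gaze",
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "n_subjects": len(subjects),
        "n_kept": len(kept),
        "n_kept_math": len(kept_math),
    }
    result = StudyResult(config=config, environment=env, subjects=subjects,
                         exclusions=exclusions, kept=kept,
                         kept_math=kept_math, globals_table=globals_table,
                         norm_tables=norm_tables, summaries=summaries,
                         report=report, dual_task=dual, manifest=manifest)
    if out_dir is not None:
        write_study(result, out_dir)
    return result


def write_study(result: StudyResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "report").mkdir(parents=True, exist_ok=True)
    pd.concat([s.object_table for s in result.subjects.values()],
              ignore_index=True).to_csv(out / "object_metrics.csv", index=False)
    if result.globals_table is not None:
        result.globals_table.to_csv(out / "global_metrics.csv", index=False)
    if result.norm_tables:
        pd.concat([t.assign(subject_id=s)
                   for s, t in result.norm_tables.items()],
                  ignore_index=True).to_csv(
            out / "normalized_metrics.csv", index=False)
    result.summaries.to_csv(out / "session_summary.csv", index=False)
    result.exclusions.to_csv(out / "exclusions.csv", index=False)
    result.report.per_subject.to_csv(
        out / "report" / "target_vs_distractor.csv", index=False)
    result.report.percent_change.to_csv(
        out / "report" / "percent_change.csv", index=False)
    result.report.humvee_motorcycle.to_csv(
        out / "report" / "humvee_motorcycle.csv", index=False)
    result.report.math_paired.to_csv(
        out / "report" / "math_paired.csv", index=False)
    result.dual_task.to_csv(out / "report" / "dual_task.csv", index=False)
    qc = {s: r.qc for s, r in result.subjects.items()}
    (out / "qc_report.json").write_text(json.dumps(qc, indent=1, default=str))
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))


# ---------------------------------------------------------------------------
# study-level recovery quantities


def pooled_session_stats(config: StudyConfig, seeds: list[int],
                         conditions: list[str] | None = None) -> dict:
    """Pooled recovery statistics over independent default-config sessions.

    Returns the pooled median qualifying-fixation duration (s), the
    session-mean fixation rate (/s), the per-object fixation count and dwell
    means (object -> subject averaging), and the mean percentage of
    qualifying fixations not labeled with a scene object (background share).
    """
    config = config or StudyConfig()
    env = build_environment(config.environment, seed=config.master_seed)
    if conditions is None:
        conditions = [CONDITIONS[i % len(CONDITIONS)]
                      for i in range(len(seeds))]

    durations: list[np.ndarray] = []
    rates, n_fix_means, dwell_means, bg_shares = [], [], [], []
    for seed, cond in zip(seeds, conditions):
        session = simulate_session(env, cond, seed, config.navigation,
                                   config.gaze)
        events, labels, _ = process_session(session, config)
        fx = events[(events["event_type"] == "fixation") & events["qualifying"]]
        durations.append(fx["duration_s"].to_numpy())
        summ = session_summary(session, events, labels, "full")
        rates.append(summ["fixation_rate_hz"])
        bg_shares.append(100.0 * (1.0 - summ["prop_fixations_on_objects"]))
        obj = per_object_metrics(labels, session.subject_id)
        if len(obj):
            n_fix_means.append(float(obj["n_fixations"].mean()))
            dwell_means.append(float(obj["dwell_time_s"].mean()))
        del session
    pooled = np.concatenate(durations) if durations else np.empty(0)
    return {
        "median_fixation_duration_s": float(np.median(pooled)),
        "fixation_rate_hz": float(np.mean(rates)),
        "mean_n_fixations_per_object": float(np.mean(n_fix_means)),
        "mean_dwell_per_object_s": float(np.mean(dwell_means)),
        "background_share_pct": float(np.mean(bg_shares)),
        "n_sessions": len(seeds),
        "n_fixations_pooled": int(len(pooled)),
    }


def study_contrasts(result: StudyResult) -> dict:
    """Target-vs-distractor and dual-task percent changes from a cohort run."""
    pc = result.report.percent_change.set_index("metric")
    dual = result.dual_task.set_index("metric")
    return {
        "target_fixation_increase_pct":
            float(pc.loc["n_fixations", "mean_percent_change"]),
        "target_dwell_increase_pct":
            float(pc.loc["dwell_time_s", "mean_percent_change"]),
        "speed_decrease_pct":
            float(dual.loc["position_velocity_m_s", "mean_percent_change"]),
        "blink_rate_increase_pct":
            float(dual.loc["blink_rate_hz", "mean_percent_change"]),
        "n_kept": len(result.kept),
        "n_kept_math": len(result.kept_math),
    }


def acceptance_values(config: StudyConfig | None = None,
                      seed: int = 1) -> dict[str, dict]:
    """Recompute every acceptance quantity from scratch.

    t1-t5 pool 10 independent default sessions (seeds seed..seed+9);
    t6-t9 run the full 45-subject cohort with master seed ``seed``;
    t10-t12 count the environment composition.
    """
    config = config or StudyConfig()
    config = StudyConfig.from_dict({**config.to_dict(), "master_seed": seed})

    seeds = [seed + i for i in range(10)]
    pooled = pooled_session_stats(config, seeds)
    result = run_study(config)
    contrasts = study_contrasts(result)

    env = result.environment
    cat = env.labelable
    n_sessions = pooled["n_sessions"]
    n_cohort = len(result.kept)
    values = {
        "t1": {"value": pooled["median_fixation_duration_s"], "n": n_sessions},
        "t2": {"value": pooled["fixation_rate_hz"], "n": n_sessions},
        "t3": {"value": pooled["mean_n_fixations_per_object"], "n": n_sessions},
        "t4": {"value": pooled["mean_dwell_per_object_s"], "n": n_sessions},
        "t5": {"value": pooled["background_share_pct"], "n": n_sessions},
        "t6": {"value": contrasts["target_fixation_increase_pct"], "n": n_cohort},
        "t7": {"value": contrasts["target_dwell_increase_pct"], "n": n_cohort},
        "t8": {"value": contrasts["speed_decrease_pct"],
               "n": contrasts["n_kept_math"]},
        "t9": {"value": contrasts["blink_rate_increase_pct"],
               "n": contrasts["n_kept_math"]},
        "t10": {"value": float(len(env.target_ids("humvee"))), "n": 4},
        "t11": {"value": float((cat["object_class"] == "trail_marker").sum()),
                "n": 1},
        "t12": {"value": float((cat["object_class"] == "other").sum()), "n": 1},
    }
    return values


def check_acceptance(values: dict[str, dict],
                     tolerances: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Pass/fail table: one row per configured tolerance band."""
    rows = []
    for tid, (lo, hi) in sorted(tolerances.items()):
        entry = values.get(tid)
        if entry is None:
            rows.append({"id": tid, "value": np.nan, "lo": lo, "hi": hi,
                         "verdict": "fail", "reason": "missing metric"})
            continue
        v = entry["value"]
        ok = np.isfinite(v) and lo <= v <= hi
        rows.append({"id": tid, "value": v, "lo": lo, "hi": hi,
                     "verdict": "pass" if ok else "fail", "reason": ""})
    return pd.DataFrame(rows)
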