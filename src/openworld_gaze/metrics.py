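"""Object-level, session-level, and epoch-level gaze metrics.

Implements the dependent-variable battery of the analysis: per-object
fixation counts, dwell times and distances; cohort global means and the
global-mean normalization (subject mean minus global mean, correcting for
object size/placement salience); session summaries per epoch (full session,
during the math task, outside it); the gaze-validated target count;
subject-exclusion screening; the +/-3 SD outlier rule; and tidy
target-vs-distractor / dual-task comparison tables for downstream
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MetricsParams
from .session import SessionRecord
from .world import Environment

EPOCHS = ("full", "during_math", "outside_math")


class MetricsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# per-object metrics


def per_object_metrics(labels: pd.DataFrame, subject_id: str) -> pd.DataFrame:
    """One row per (subject, labeled object): n_fixations, dwell, distance.

    Only qualifying labeled fixations contribute; dwell is the sum of their
    durations and mean_distance the fixation-weighted mean of per-fixation
    mean collision distances.
    """
    lab = labels[labels["object_id"] != ""].copy()
    if len(lab) == 0:
        return pd.DataFrame(columns=[
            "subject_id", "object_id", "n_fixations", "dwell_time_s",
            "mean_distance_m"])
    lab["duration_s"] = lab["t_off_s"] - lab["t_on_s"]
    g = (lab.groupby("object_id")
         .agg(n_fixations=("duration_s", "size"),
              dwell_time_s=("duration_s", "sum"),
              mean_distance_m=("mean_distance_m", "mean"))
         .reset_index())
    g.insert(0, "subject_id", subject_id)
    return g


def global_means(object_tables: list[pd.DataFrame],
                 env: Environment) -> pd.DataFrame:
    """Per-object means across subjects.

    Counts and dwell average over *all* analyzed subjects (a subject who
    never fixated the object contributes 0); distance averages only over
    subjects who fixated it (undefined otherwise).
    """
    n_subj = len(object_tables)
    if n_subj == 0:
        raise MetricsError("no subjects")
    if n_subj == 1:
        warnings.warn("global means over a single subject equal that "
                      "subject's values", stacklevel=2)
    pooled = pd.concat(object_tables, ignore_index=True) if object_tables else None
    ids = env.labelable["object_id"]
    base = pd.DataFrame({"object_id": ids.to_numpy(dtype=object)})
    if pooled is None or len(pooled) == 0:
        base["global_n_fixations"] = 0.0
        base["global_dwell_time_s"] = 0.0
        base["global_distance_m"] = np.nan
        return base
    sums = (pooled.groupby("object_id")
            .agg(n=("n_fixations", "sum"), d=("dwell_time_s", "sum"),
                 dist=("mean_distance_m", "mean"))
            .reset_index())
    out = base.merge(sums, on="object_id", how="left")
    out["global_n_fixations"] = out["n"].fillna(0.0) / n_subj
    out["global_dwell_time_s"] = out["d"].fillna(0.0) / n_subj
    out["global_distance_m"] = out["dist"]
    return out[["object_id", "global_n_fixations", "global_dwell_time_s",
                "global_distance_m"]]


def normalize(object_table: pd.DataFrame, globals_table: pd.DataFrame,
              params: MetricsParams | None = None) -> pd.DataFrame:
    """Normalized per-object metrics: subject mean minus global mean.

    The sign convention is switchable (``normalized_sign``); the default
    makes preferentially fixated objects positive.
    """
    params = params or MetricsParams()
    missing = set(object_table["object_id"]) - set(globals_table["object_id"])
    if missing:
        raise MetricsError(f"objects missing from globals: {sorted(missing)[:5]}")
    m = object_table.merge(globals_table, on="object_id", how="left")
    sign = 1.0 if params.normalized_sign == "subject_minus_global" else -1.0
    m["norm_n_fixations"] = sign * (m["n_fixations"] - m["global_n_fixations"])
    m["norm_dwell_time_s"] = sign * (m["dwell_time_s"] - m["global_dwell_time_s"])
    m["norm_distance_m"] = sign * (m["mean_distance_m"] - m["global_distance_m"])
    return m


# ---------------------------------------------------------------------------
# session-level summaries


def _epoch_bounds(session: SessionRecord, epoch: str) -> list[tuple[float, float]]:
    ms = session.math_task_interval
    dur = session.duration_s
    if epoch == "full":
        return [(0.0, dur)]
    if epoch == "during_math":
        return [ms] if ms[1] > ms[0] else []
    if epoch == "outside_math":
        parts = []
        if ms[0] > 0:
            parts.append((0.0, ms[0]))
        if dur > ms[1]:
            parts.append((ms[1], dur))
        return parts or [(0.0, dur)]
    raise MetricsError(f"unknown epoch {epoch!r}")


def _in_epoch(t_on: np.ndarray, bounds: list[tuple[float, float]]) -> np.ndarray:
    m = np.zeros(len(t_on), dtype=bool)
    for lo, hi in bounds:
        m |= (t_on >= lo) & (t_on < hi)
    return m


def session_summary(session: SessionRecord, events: pd.DataFrame,
                    labels: pd.DataFrame, epoch: str = "full") -> dict:
    """Epoch summary: fixation/object/blink rates, proportion of fixations on
    objects, position velocity, per-object means, validated target count.

    Events are assigned to an epoch by onset time; rates divide by the
    epoch's wall time, so the full-session rate is the duration-weighted
    mean of the two epoch rates.
    """
    bounds = _epoch_bounds(session, epoch)
    wall = sum(hi - lo for lo, hi in bounds)
    if wall <= 0:
        raise MetricsError(f"zero-length epoch {epoch!r}")

    fx = events[(events["event_type"] == "fixation") & events["qualifying"]]
    in_ep = _in_epoch(fx["t_on_s"].to_numpy(dtype=float), bounds)
    n_fix = int(in_ep.sum())

    lab_in = labels[_in_epoch(labels["t_on_s"].to_numpy(dtype=float), bounds)]
    labeled = lab_in[lab_in["object_id"] != ""]
    n_labeled = len(labeled)

    blinks = events[events["event_type"] == "blink"]
    n_blinks = int(_in_epoch(blinks["t_on_s"].to_numpy(dtype=float), bounds).sum())

    # position velocity: mean speed over the epoch's samples
    t = session.samples["t_s"].to_numpy(dtype=float)
    obs = session.samples[["obs_x_m", "obs_y_m", "obs_z_m"]].to_numpy(dtype=float)
    step = np.linalg.norm(np.diff(obs, axis=0), axis=1)
    dt = float(np.median(np.diff(t)))
    m = _in_epoch(t[:-1], bounds)
    pos_vel = float(step[m].sum() / (m.sum() * dt)) if m.sum() else np.nan

    per_obj = per_object_metrics(lab_in, session.subject_id)
    dur_labeled = (labeled["t_off_s"] - labeled["t_on_s"]).to_numpy()
    dur_all = (fx["t_off_s"] - fx["t_on_s"]).to_numpy()[in_ep]

    targets = set(session.environment.target_ids(session.condition))
    validated = len(set(labeled["object_id"]) & targets)

    return {
        "subject_id": session.subject_id,
        "condition": session.condition,
        "epoch": epoch,
        "epoch_duration_s": wall,
        "n_qualifying_fixations": n_fix,
        "fixation_rate_hz": n_fix / wall,
        "object_rate_hz": labeled["object_id"].nunique() / wall,
        "blink_rate_hz": n_blinks / wall,
        "prop_fixations_on_objects": (n_labeled / n_fix) if n_fix else np.nan,
        "position_velocity_m_s": pos_vel,
        "mean_individual_fixation_duration_s":
            float(np.mean(dur_all)) if len(dur_all) else np.nan,
        "mean_fixation_duration_on_objects_s":
            float(np.mean(dur_labeled)) if len(dur_labeled) else np.nan,
        "median_fixation_duration_s":
            float(np.median(dur_all)) if len(dur_all) else np.nan,
        "mean_n_fixations_per_object":
            float(per_obj["n_fixations"].mean()) if len(per_obj) else np.nan,
        "mean_dwell_per_object_s":
            float(per_obj["dwell_time_s"].mean()) if len(per_obj) else np.nan,
        "gaze_validated_target_count": validated,
    }


def gaze_validated_target_count(labels: pd.DataFrame,
                                env: Environment, condition: str) -> int:
    """Distinct target instances with >= 1 qualifying labeled fixation."""
    targets = set(env.target_ids(condition))
    labeled = labels[labels["object_id"] != ""]
    return len(set(labeled["object_id"]) & targets)


# ---------------------------------------------------------------------------
# cohort screening


def exclusion_screen(sessions: list[dict],
                     params: MetricsParams | None = None,
                     ) -> tuple[list[str], pd.DataFrame]:
    """Apply the subject-exclusion rules.

    Each entry needs: subject_id, dropout_fraction, duration_s,
    gaze_validated_target_count, math_completed.  Rules: high dropout
    (fraction above the configured threshold) excludes from all analysis;
    exceeding the time limit *and* validating fewer than 10 targets excludes
    from all analysis; an unfinished math task excludes from the math
    analysis only.
    """
    params = params or MetricsParams()
    rows = []
    kept = []
    for s in sessions:
        reasons = []
        if s["dropout_fraction"] > params.dropout_exclusion_frac:
            reasons.append("high_dropout")
        if (s["duration_s"] > params.timeout_s
                and s["gaze_validated_target_count"] < params.min_validated_targets):
            reasons.append("timeout_and_lt10_targets")
        math_ok = bool(s.get("math_completed", True)) and not reasons
        if not s.get("math_completed", True):
            reasons.append("math_task_incomplete")
        full_ok = not [r for r in reasons if r != "math_task_incomplete"]
        if full_ok:
            kept.append(s["subject_id"])
        rows.append({
            "subject_id": s["subject_id"],
            "kept": full_ok,
            "kept_math": math_ok,
            "reasons": ";".join(reasons),
        })
    return kept, pd.DataFrame(rows)


def outlier_filter(values: pd.Series, params: MetricsParams | None = None,
                   ) -> tuple[pd.Series, pd.Series]:
    """Single-pass +/-3 SD outlier rule over a per-subject series."""
    params = params or MetricsParams()
    v = values.dropna()
    if len(v) < 3:
        raise MetricsError("need at least 3 values for outlier screening")
    mean, sd = v.mean(), v.std(ddof=1)
    if sd == 0:
        return v, v.iloc[0:0]
    z = (v - mean).abs() / sd
    return v[z <= params.outlier_sd], v[z > params.outlier_sd]


# ---------------------------------------------------------------------------
# condition report


@dataclass
class ConditionReport:
    """Tidy comparison tables for the cohort."""

    per_subject: pd.DataFrame       # target-vs-distractor means per subject
    percent_change: pd.DataFrame    # cohort percent-change summary
    humvee_motorcycle: pd.DataFrame
    math_paired: pd.DataFrame       # one row per subject x epoch x metric
    summaries: pd.DataFrame = field(default_factory=pd.DataFrame)


def _subject_contrast(norm_table: pd.DataFrame, env: Environment,
                      condition: str) -> dict:
    targets = set(env.target_ids(condition))
    is_t = norm_table["object_id"].isin(targets)
    t_rows, d_rows = norm_table[is_t], norm_table[~is_t]
    out = {}
    for col, name in [("n_fixations", "n_fixations"),
                      ("dwell_time_s", "dwell_time_s"),
                      ("mean_distance_m", "distance_m"),
                      ("norm_n_fixations", "norm_n_fixations"),
                      ("norm_dwell_time_s", "norm_dwell_time_s"),
                      ("norm_distance_m", "norm_distance_m")]:
        out[f"target_{name}"] = float(t_rows[col].mean()) if len(t_rows) else np.nan
        out[f"distractor_{name}"] = (float(d_rows[col].mean())
                                     if len(d_rows) else np.nan)
    return out


def condition_report(subject_norm_tables: dict[str, pd.DataFrame],
                     conditions: dict[str, str],
                     env: Environment,
                     summaries: pd.DataFrame,
                     kept_math: set[str] | None = None) -> ConditionReport:
    """Build the target-vs-distractor, 2x2, and dual-task comparison tables.

    ``subject_norm_tables`` maps subject -> normalized per-object table;
    ``conditions`` maps subject -> condition; ``summaries`` holds one row per
    subject x epoch from :func:`session_summary`.
    """
    rows = []
    for sid, table in subject_norm_tables.items():
        cond = conditions[sid]
        row = {"subject_id": sid, "condition": cond}
        row.update(_subject_contrast(table, env, cond))
        rows.append(row)
    per_subject = pd.DataFrame(rows)

    pct_rows = []
    for metric in ("n_fixations", "dwell_time_s", "distance_m"):
        t = per_subject[f"target_{metric}"]
        d = per_subject[f"distractor_{metric}"]
        pct = 100.0 * (t - d) / d
        pct_rows.append({
            "metric": metric,
            "mean_percent_change": float(pct.mean()),
            "n_subjects": int(pct.notna().sum()),
        })
    percent_change = pd.DataFrame(pct_rows)

    # Humvee/Motorcycle 2x2 sub-table (condition x fixation-object class)
    hm_rows = []
    for sid, table in subject_norm_tables.items():
        cond = conditions[sid]
        if cond not in ("humvee", "motorcycle"):
            continue
        cls = table["object_id"].str.rsplit("_", n=1).str[0]
        for obj_cls in ("humvee", "motorcycle"):
            sub = table[cls == obj_cls]
            hm_rows.append({
                "subject_id": sid,
                "condition": cond,
                "fixation_object": obj_cls,
                "n_fixations": float(sub["n_fixations"].mean())
                if len(sub) else np.nan,
                "dwell_time_s": float(sub["dwell_time_s"].mean())
                if len(sub) else np.nan,
                "norm_n_fixations": float(sub["norm_n_fixations"].mean())
                if len(sub) else np.nan,
                "norm_dwell_time_s": float(sub["norm_dwell_time_s"].mean())
                if len(sub) else np.nan,
            })
    humvee_motorcycle = pd.DataFrame(hm_rows)

    # during vs outside math, paired per subject
    math_metrics = [
        "fixation_rate_hz", "object_rate_hz", "blink_rate_hz",
        "prop_fixations_on_objects", "position_velocity_m_s",
        "mean_fixation_duration_on_objects_s", "mean_n_fixations_per_object",
        "mean_dwell_per_object_s",
    ]
    paired_rows = []
    eligible = (set(summaries["subject_id"]) if kept_math is None
                else kept_math)
    for sid in sorted(set(summaries["subject_id"]) & set(eligible)):
        sub = summaries[summaries["subject_id"] == sid]
        during = sub[sub["epoch"] == "during_math"]
        outside = sub[sub["epoch"] == "outside_math"]
        if len(during) != 1 or len(outside) != 1:
            continue
        for metric in math_metrics:
            paired_rows.append({
                "subject_id": sid,
                "metric": metric,
                "during_math": float(during[metric].iloc[0]),
                "outside_math": float(outside[metric].iloc[0]),
            })
    math_paired = pd.DataFrame(paired_rows)

    return ConditionReport(
        per_subject=per_subject,
        percent_change=percent_change,
        humvee_motorcycle=humvee_motorcycle,
        math_paired=math_paired,
        summaries=summaries,
    )


def dual_task_percent_changes(math_paired: pd.DataFrame) -> pd.DataFrame:
    """Cohort-mean percent change during vs outside the math epoch.

    Decreasing metrics (position velocity, fixation rate, per-object
    fixations/dwell) are reported as percent *decrease* (outside - during) /
    outside; increasing ones (blink rate, object rate) as percent *increase*
    (during - outside) / outside.
    """
    rows = []
    for metric, direction in [
        ("position_velocity_m_s", "decrease"),
        ("fixation_rate_hz", "decrease"),
        ("mean_n_fixations_per_object", "decrease"),
        ("mean_dwell_per_object_s", "decrease"),
        ("blink_rate_hz", "increase"),
        ("object_rate_hz", "increase"),
        ("prop_fixations_on_objects", "increase"),
    ]:
        sub = math_paired[math_paired["metric"] == metric]
        if len(sub) == 0:
            continue
        during = sub["during_math"].to_numpy()
        outside = sub["outside_math"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            if direction == "decrease":
                pct = 100.0 * (outside - during) / outside
            else:
                pct = 100.0 * (during - outside) / outside
        rows.append({
            "metric": metric,
            "direction": direction,
            "mean_percent_change": float(np.nanmean(pct)),
            "n_subjects": int(np.isfinite(pct).sum()),
        })
    return pd.DataFrame(rows)
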