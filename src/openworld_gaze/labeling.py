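"""Fixation-to-object assignment from per-sample gaze-ray collisions.

Each qualifying fixation is assigned the dominant collision object of its
epoch — the non-background (terrain/sky excluded) object with the most
collision samples — provided that object covers at least the dominance
threshold (default 10%) of all samples in the epoch.  The denominator counts
every sample of the epoch, valid or not.  Ties go to the object with the
smaller mean collision distance, then lexicographically.  The threshold
sweep reproduces the labeled-count / mean-distance diagnostic across
thresholds {0, 1, 10, 20, 50}%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import LabelingParams
from .session import SessionRecord
from .world import Environment

LABEL_COLUMNS = [
    "fixation_index", "t_on_s", "t_off_s", "object_id", "object_class",
    "collision_fraction", "mean_distance_m", "is_target",
]


class LabelingError(ValueError):
    pass


def _epoch_counts(fixations: pd.DataFrame, samples: pd.DataFrame,
                  ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-(fixation, object) collision counts and mean distances, plus the
    per-fixation epoch-size denominator (all samples, valid or not)."""
    i_on = fixations["i_on"].to_numpy(dtype=int)
    i_off = fixations["i_off"].to_numpy(dtype=int)
    n = len(samples)
    fix_idx = np.full(n, -1, dtype=np.int64)
    for k in range(len(fixations)):
        fix_idx[i_on[k]:i_off[k]] = k

    denom = pd.Series(i_off - i_on, index=pd.RangeIndex(len(fixations)))

    df = pd.DataFrame({
        "fix": fix_idx,
        "object_id": samples["object_id"].to_numpy(dtype=object),
        "dist": samples["gaze_distance_m"].to_numpy(dtype=float),
    })
    df = df[(df["fix"] >= 0) & (df["object_id"] != "")]
    grouped = (df.groupby(["fix", "object_id"], sort=False)
               .agg(count=("dist", "size"), mean_dist=("dist", "mean"))
               .reset_index())
    return grouped, denom


def _labels_from_counts(grouped: pd.DataFrame, denom: pd.Series,
                        n_fix: int, env: Environment,
                        params: LabelingParams) -> pd.DataFrame:
    """Resolve dominance per fixation from a counts table."""
    excl = set(params.exclude_classes)
    cls_of = dict(zip(env.catalog["object_id"], env.catalog["object_class"]))
    unknown = set(grouped["object_id"]) - set(cls_of)
    if unknown:
        raise LabelingError(f"collision object(s) missing from catalog: "
                            f"{sorted(unknown)[:5]}")

    g = grouped[~grouped["object_id"].map(cls_of).isin(excl)]
    out_obj = np.full(n_fix, "", dtype=object)
    out_frac = np.zeros(n_fix)
    out_dist = np.full(n_fix, np.nan)
    if len(g):
        # sort so the winner is first per fixation: count desc, dist asc, id asc
        g = g.sort_values(["fix", "count", "mean_dist", "object_id"],
                          ascending=[True, False, True, True],
                          kind="mergesort")
        top = g.drop_duplicates("fix", keep="first")
        for _, row in top.iterrows():
            k = int(row["fix"])
            frac = row["count"] / denom.loc[k]
            thresh = params.dominance_threshold
            if row["count"] >= max(1, thresh * denom.loc[k] - 1e-9):
                out_obj[k] = row["object_id"]
                out_frac[k] = frac
                out_dist[k] = row["mean_dist"]
    return pd.DataFrame({
        "object_id": out_obj,
        "collision_fraction": out_frac,
        "mean_distance_m": out_dist,
    })


def assign_fixation_object(fixation: pd.Series, samples: pd.DataFrame,
                           env: Environment,
                           params: LabelingParams | None = None) -> pd.Series:
    """Label a single qualifying fixation (convenience over label_session)."""
    params = params or LabelingParams()
    fx = pd.DataFrame([fixation])
    if int(fixation["i_off"]) - int(fixation["i_on"]) <= 0:
        raise LabelingError("fixation epoch contains zero samples")
    grouped, denom = _epoch_counts(fx.reset_index(drop=True), samples)
    lab = _labels_from_counts(grouped, denom, 1, env, params)
    return lab.iloc[0]


def label_session(session: SessionRecord, events: pd.DataFrame,
                  params: LabelingParams | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every qualifying fixation of a detected event table.

    Returns ``(events_labeled, fixation_labels)`` where ``fixation_labels``
    has one row per qualifying fixation (``LABEL_COLUMNS``).  A distractor is
    any labelable object outside the session condition's target set.
    """
    params = params or LabelingParams()
    params.validate()
    env = session.environment
    fx = events[(events["event_type"] == "fixation")
                & events["qualifying"]].reset_index()
    if len(fx) == 0:
        empty = pd.DataFrame(columns=LABEL_COLUMNS)
        return events.copy(), empty

    grouped, denom = _epoch_counts(fx, session.samples)
    lab = _labels_from_counts(grouped, denom, len(fx), env, params)

    targets = set(env.target_ids(session.condition))
    cls_of = dict(zip(env.catalog["object_id"], env.catalog["object_class"]))
    labels = pd.DataFrame({
        "fixation_index": fx["index"],
        "t_on_s": fx["t_on_s"].to_numpy(),
        "t_off_s": fx["t_off_s"].to_numpy(),
        "object_id": lab["object_id"].to_numpy(),
        "object_class": [cls_of.get(o, "") for o in lab["object_id"]],
        "collision_fraction": lab["collision_fraction"].to_numpy(),
        "mean_distance_m": lab["mean_distance_m"].to_numpy(),
        "is_target": [o in targets for o in lab["object_id"]],
    })

    out = events.copy()
    out.loc[labels["fixation_index"], "object_id"] = labels["object_id"].to_numpy()
    out.loc[labels["fixation_index"], "mean_distance_m"] = (
        labels["mean_distance_m"].to_numpy())
    return out, labels


def threshold_sweep(sessions_events: list[tuple[SessionRecord, pd.DataFrame]],
                    thresholds: list[float] | None = None,
                    params: LabelingParams | None = None) -> pd.DataFrame:
    """Labeled-fixation count and mean labeled distance vs threshold.

    Pools the given (session, detected-events) pairs; thresholds default to
    {0, 1, 10, 20, 50}% and are evaluated in sorted order.
    """
    params = params or LabelingParams()
    if thresholds is None:
        thresholds = list(params.sweep_thresholds)
    thresholds = sorted(thresholds)

    rows = []
    per_thresh_counts = {th: 0 for th in thresholds}
    per_thresh_dist: dict[float, list[np.ndarray]] = {th: [] for th in thresholds}
    for session, events in sessions_events:
        fx = events[(events["event_type"] == "fixation")
                    & events["qualifying"]].reset_index()
        if len(fx) == 0:
            continue
        grouped, denom = _epoch_counts(fx, session.samples)
        for th in thresholds:
            p = LabelingParams(dominance_threshold=th,
                               exclude_classes=params.exclude_classes)
            lab = _labels_from_counts(grouped, denom, len(fx),
                                      session.environment, p)
            labeled = lab[lab["object_id"] != ""]
            per_thresh_counts[th] += len(labeled)
            if len(labeled):
                per_thresh_dist[th].append(
                    labeled["mean_distance_m"].to_numpy())
    for th in thresholds:
        dists = (np.concatenate(per_thresh_dist[th])
                 if per_thresh_dist[th] else np.empty(0))
        rows.append({
            "threshold": th,
            "n_labeled": per_thresh_counts[th],
            "mean_distance_m": float(np.mean(dists)) if len(dists) else np.nan,
        })
    return pd.DataFrame(rows)
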