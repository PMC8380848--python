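"""Gaze-metric computations: per-object aggregation, global means and
normalization, session summaries, exclusion and outlier rules, reports."""

import numpy as np
import pandas as pd
import pytest

from openworld_gaze.config import MetricsParams
from openworld_gaze.metrics import (MetricsError, condition_report,
                                    dual_task_percent_changes,
                                    exclusion_screen,
                                    gaze_validated_target_count, global_means,
                                    normalize, outlier_filter,
                                    per_object_metrics, session_summary)
from openworld_gaze.pipeline import process_session


def _labels(rows):
    return pd.DataFrame(rows, columns=[
        "fixation_index", "t_on_s", "t_off_s", "object_id", "object_class",
        "collision_fraction", "mean_distance_m", "is_target"])


def test_per_object_hand_summed():
    labels = _labels([
        (0, 0.0, 0.2, "a", "other", 1.0, 10.0, False),
        (1, 1.0, 1.3, "a", "other", 1.0, 12.0, False),
        (2, 2.0, 2.5, "a", "other", 1.0, 14.0, False),
        (3, 3.0, 3.2, "", "", 0.0, np.nan, False),
    ])
    t = per_object_metrics(labels, "s1")
    assert len(t) == 1
    row = t.iloc[0]
    assert row["n_fixations"] == 3
    assert row["dwell_time_s"] == pytest.approx(1.0)
    assert row["mean_distance_m"] == pytest.approx(12.0)
    # dwell >= 0.1 * n for qualifying fixations
    assert row["dwell_time_s"] >= 0.1 * row["n_fixations"]


def test_per_object_empty_when_everything_unlabeled():
    labels = _labels([(0, 0.0, 0.2, "", "", 0.0, np.nan, False)])
    assert len(per_object_metrics(labels, "s1")) == 0


def test_global_means_zero_fill_and_distance_exclusion(small_env):
    t1 = pd.DataFrame({"subject_id": "a", "object_id": ["x1"],
                       "n_fixations": [4], "dwell_time_s": [1.0],
                       "mean_distance_m": [20.0]})
    t2 = pd.DataFrame({"subject_id": "b", "object_id": ["x1"],
                       "n_fixations": [6], "dwell_time_s": [3.0],
                       "mean_distance_m": [40.0]})
    env = small_env
    t1["object_id"] = env.labelable["object_id"].iloc[0]
    t2["object_id"] = env.labelable["object_id"].iloc[0]
    g = global_means([t1, t2], env)
    oid = env.labelable["object_id"].iloc[0]
    row = g[g["object_id"] == oid].iloc[0]
    assert row["global_n_fixations"] == 5.0     # (4+6)/2
    assert row["global_dwell_time_s"] == 2.0
    assert row["global_distance_m"] == 30.0     # only subjects who fixated
    other = g[g["object_id"] != oid]
    assert (other["global_n_fixations"] == 0).all()  # absent -> 0
    assert other["global_distance_m"].isna().all()   # absent -> undefined


def test_global_means_single_subject_warns(small_env):
    t1 = pd.DataFrame({"subject_id": "a",
                       "object_id": [small_env.labelable["object_id"].iloc[0]],
                       "n_fixations": [4], "dwell_time_s": [1.0],
                       "mean_distance_m": [20.0]})
    with pytest.warns(UserWarning):
        g = global_means([t1], small_env)
    oid = t1["object_id"].iloc[0]
    assert g[g["object_id"] == oid]["global_n_fixations"].iloc[0] == 4.0


def test_normalize_sign_and_cohort_zero_mean(small_env):
    oid = small_env.labelable["object_id"].iloc[0]
    tables = []
    for sid, n in [("a", 4), ("b", 6)]:
        tables.append(pd.DataFrame({
            "subject_id": sid, "object_id": [oid], "n_fixations": [n],
            "dwell_time_s": [n * 0.3], "mean_distance_m": [20.0]}))
    g = global_means(tables, small_env)
    n1 = normalize(tables[0], g)
    n2 = normalize(tables[1], g)
    assert n1["norm_n_fixations"].iloc[0] == pytest.approx(-1.0)  # 4 - 5
    assert n2["norm_n_fixations"].iloc[0] == pytest.approx(+1.0)  # 6 - 5
    # cohort mean of normalized values is exactly zero per object
    assert (n1["norm_n_fixations"].iloc[0]
            + n2["norm_n_fixations"].iloc[0]) == pytest.approx(0.0, abs=1e-12)
    # sign switch
    p = MetricsParams(normalized_sign="global_minus_subject")
    assert normalize(tables[0], g, p)["norm_n_fixations"].iloc[0] == \
        pytest.approx(+1.0)


def test_normalize_missing_object_rejected(small_env):
    t = pd.DataFrame({"subject_id": "a", "object_id": ["ghost"],
                      "n_fixations": [1], "dwell_time_s": [0.2],
                      "mean_distance_m": [5.0]})
    g = global_means([t.assign(object_id=small_env.labelable["object_id"]
                               .iloc[0])], small_env)
    with pytest.raises(MetricsError):
        normalize(t, g)


def test_session_summary_rates_and_epochs(short_session, study_config):
    events, labels, _ = process_session(short_session, study_config)
    full = session_summary(short_session, events, labels, "full")
    during = session_summary(short_session, events, labels, "during_math")
    outside = session_summary(short_session, events, labels, "outside_math")
    # epoch durations partition the session
    assert during["epoch_duration_s"] + outside["epoch_duration_s"] == \
        pytest.approx(full["epoch_duration_s"], abs=1e-9)
    # full rate is the duration-weighted mean of epoch rates
    w = (during["fixation_rate_hz"] * during["epoch_duration_s"]
         + outside["fixation_rate_hz"] * outside["epoch_duration_s"]) \
        / full["epoch_duration_s"]
    assert full["fixation_rate_hz"] == pytest.approx(w, abs=1e-9)
    assert 0 <= full["prop_fixations_on_objects"] <= 1
    # during-epoch starts at the configured onset
    assert short_session.math_task_interval[0] == 30.0
    # hand check of the rate definition
    fx = events[(events["event_type"] == "fixation") & events["qualifying"]]
    assert full["fixation_rate_hz"] == pytest.approx(
        len(fx) / short_session.duration_s)


def test_dwell_sum_bounded_by_duration(short_session, study_config):
    events, labels, _ = process_session(short_session, study_config)
    obj = per_object_metrics(labels, "s")
    assert obj["dwell_time_s"].sum() <= short_session.duration_s


def test_zero_length_epoch_rejected(short_session, study_config):
    events, labels, _ = process_session(short_session, study_config)
    from dataclasses import replace
    s2 = replace(short_session, math_task_interval=(10.0, 10.0))
    with pytest.raises(MetricsError):
        session_summary(s2, events, labels, "during_math")


def test_gaze_validated_target_count(small_env, short_session, study_config):
    events, labels, _ = process_session(short_session, study_config)
    count = gaze_validated_target_count(labels, small_env, "humvee")
    assert 0 <= count <= len(small_env.target_ids("humvee"))
    empty = labels.iloc[0:0]
    assert gaze_validated_target_count(empty, small_env, "humvee") == 0


@pytest.mark.parametrize("duration,targets,kept", [
    (1260.0, 8, False),   # 21 min and < 10 targets: excluded
    (1260.0, 12, True),   # 21 min but enough targets: kept
    (700.0, 8, True),     # under the time limit: kept
])
def test_exclusion_rule_requires_both_conditions(duration, targets, kept):
    sess = [{"subject_id": "s", "dropout_fraction": 0.05,
             "duration_s": duration, "gaze_validated_target_count": targets,
             "math_completed": True}]
    kept_ids, table = exclusion_screen(sess)
    assert ("s" in kept_ids) == kept


def test_exclusion_high_dropout_and_math():
    sess = [
        {"subject_id": "a", "dropout_fraction": 0.40, "duration_s": 700,
         "gaze_validated_target_count": 12, "math_completed": True},
        {"subject_id": "b", "dropout_fraction": 0.05, "duration_s": 700,
         "gaze_validated_target_count": 12, "math_completed": False},
    ]
    kept, table = exclusion_screen(sess)
    assert kept == ["b"]
    trow = table.set_index("subject_id")
    assert "high_dropout" in trow.loc["a", "reasons"]
    assert not trow.loc["b", "kept_math"]
    assert trow.loc["b", "kept"]  # math incompleteness only hits math analysis


def test_outlier_filter_single_pass():
    vals = pd.Series([0.0] * 9 + [100.0])
    kept, removed = outlier_filter(vals)
    # mean 10, sd 31.6 -> z(100) = 2.85 < 3: kept (single-pass rule)
    assert len(removed) == 0
    same = pd.Series([5.0, 5.0, 5.0, 5.0])
    kept, removed = outlier_filter(same)
    assert len(removed) == 0
    with pytest.raises(MetricsError):
        outlier_filter(pd.Series([1.0, 2.0]))
    vals2 = pd.Series([0.0] * 30 + [100.0])
    kept2, removed2 = outlier_filter(vals2)
    assert list(removed2) == [100.0]


def test_condition_report_identity_cases(small_env):
    """Identical target/distractor behavior gives zero percent change, and
    the paired table has one row per subject per metric."""
    oid_t = small_env.target_ids("humvee")[0]
    oid_d = small_env.distractor_ids("humvee")[0]
    tables = {}
    for sid in ("a", "b"):
        t = pd.DataFrame({
            "subject_id": sid, "object_id": [oid_t, oid_d],
            "n_fixations": [5, 5], "dwell_time_s": [1.5, 1.5],
            "mean_distance_m": [20.0, 20.0]})
        tables[sid] = normalize(t, global_means(
            [t.drop(columns="subject_id").assign(subject_id=sid)], small_env))
    summaries = pd.DataFrame([
        {"subject_id": s, "epoch": ep, "fixation_rate_hz": 2.0,
         "object_rate_hz": 0.2, "blink_rate_hz": 0.3,
         "prop_fixations_on_objects": 0.5, "position_velocity_m_s": 3.0,
         "mean_fixation_duration_on_objects_s": 0.3,
         "mean_n_fixations_per_object": 5.0, "mean_dwell_per_object_s": 1.5}
        for s in ("a", "b") for ep in ("full", "during_math", "outside_math")])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rep = condition_report(tables, {"a": "humvee", "b": "humvee"},
                               small_env, summaries)
    pct = rep.percent_change.set_index("metric")
    assert pct.loc["n_fixations", "mean_percent_change"] == pytest.approx(0.0)
    assert pct.loc["dwell_time_s", "mean_percent_change"] == pytest.approx(0.0)
    # paired table shape: subjects x metrics
    n_metrics = rep.math_paired["metric"].nunique()
    assert len(rep.math_paired) == 2 * n_metrics
    dual = dual_task_percent_changes(rep.math_paired)
    assert np.allclose(dual["mean_percent_change"], 0.0)
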