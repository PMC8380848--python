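"""Naive, loop-based reference implementations used as independent oracles.

Everything here is deliberately unvectorized and written directly from the
event-definition rules, so the production detector can be compared against
it exactly on small streams.
"""

from __future__ import annotations

import math

import numpy as np


def naive_detect(samples, params):
    """Brute-force event scan.

    Returns a list of (event_type, i_on, i_off) with event_type in
    {"saccade", "fixation", "blink", "dropout"} plus a dict of extras
    {"qualifying": {...}} for fixations.  Mirrors the published rules:
    5-sample central-difference velocity, per-component median-dispersion
    thresholds x factor, >= 12 ms suprathreshold runs, largest-saccade rule
    within 50 ms, >= 50 ms inter-saccadic fixations (qualifying >= 100 ms),
    blink gaps 50-500 ms inclusive.
    """
    t = list(samples["t_s"])
    x = list(samples["x_deg"])
    y = list(samples["y_deg"])
    valid = [bool(v) for v in samples["valid"]]
    n = len(t)
    diffs = sorted(t[i + 1] - t[i] for i in range(n - 1))
    dt = diffs[len(diffs) // 2]
    rate = 1.0 / dt

    def n_min(dur):
        return math.ceil(dur * rate - 1e-9)

    def n_max(dur):
        return math.floor(dur * rate + 1e-9)

    # velocity, defined mask
    vx = [float("nan")] * n
    vy = [float("nan")] * n
    defined = [False] * n
    for i in range(2, n - 2):
        if all(valid[j] for j in range(i - 2, i + 3)):
            vx[i] = (x[i + 2] + x[i + 1] - x[i - 1] - x[i - 2]) / (6 * dt)
            vy[i] = (y[i + 2] + y[i + 1] - y[i - 1] - y[i - 2]) / (6 * dt)
            defined[i] = (not math.isnan(vx[i])) and (not math.isnan(vy[i]))

    def med(vals):
        s = sorted(vals)
        m = len(s)
        if m % 2:
            return s[m // 2]
        return 0.5 * (s[m // 2 - 1] + s[m // 2])

    etas = []
    for comp in (vx, vy):
        v = [comp[i] for i in range(n) if defined[i]]
        sig2 = med([u * u for u in v]) - med(v) ** 2
        sigma = math.sqrt(max(sig2, 0.0))
        etas.append(max(params.velocity_factor * sigma, params.threshold_floor))
    ex, ey = etas

    crit = [defined[i] and (vx[i] / ex) ** 2 + (vy[i] / ey) ** 2 > 1.0
            for i in range(n)]

    # suprathreshold runs
    runs = []
    i = 0
    while i < n:
        if crit[i]:
            j = i
            while j < n and crit[j]:
                j += 1
            if j - i >= n_min(params.min_saccade_dur):
                runs.append((i, j))
            i = j
        else:
            i += 1

    # largest-saccade rule
    def amp(run):
        a, b = run
        return math.hypot(x[b - 1] - x[a], y[b - 1] - y[a])

    gap_min = n_min(params.min_fixation_dur)
    changed = True
    while changed:
        changed = False
        out = []
        k = 0
        while k < len(runs):
            if k + 1 < len(runs):
                lo, hi = runs[k][1], runs[k + 1][0]
                if all(valid[lo:hi]) and (hi - lo) < gap_min:
                    out.append(runs[k] if amp(runs[k]) >= amp(runs[k + 1])
                               else runs[k + 1])
                    k += 2
                    changed = True
                    continue
            out.append(runs[k])
            k += 1
        runs = out

    events = [("saccade", a, b) for a, b in runs]
    qualifying = {}

    # valid segments
    segs = []
    i = 0
    while i < n:
        if valid[i]:
            j = i
            while j < n and valid[j]:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1

    n_fix = n_min(params.min_fixation_dur)
    n_qual = n_min(params.qualifying_fixation_dur)
    for seg_on, seg_off in segs:
        inside = [(a, b) for a, b in runs if a >= seg_on and b <= seg_off]
        cursor = seg_on
        bounds = []
        for a, b in inside:
            bounds.append((cursor, a))
            cursor = b
        bounds.append((cursor, seg_off))
        for a, b in bounds:
            if b - a >= n_fix:
                events.append(("fixation", a, b))
                qualifying[(a, b)] = (b - a) >= n_qual

    # gaps
    lo_b, hi_b = params.blink_gap_range
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            etype = ("blink" if n_min(lo_b) <= (j - i) <= n_max(hi_b)
                     else "dropout")
            events.append((etype, i, j))
            i = j
        else:
            i += 1

    events.sort(key=lambda e: e[1])
    return events, qualifying, (ex, ey)


def naive_label(fixation_bounds, samples, env, threshold, exclude):
    """Exhaustive per-object dominance count for one fixation epoch."""
    i_on, i_off = fixation_bounds
    cls_of = dict(zip(env.catalog["object_id"], env.catalog["object_class"]))
    counts: dict[str, int] = {}
    dists: dict[str, list[float]] = {}
    total = i_off - i_on
    obj = list(samples["object_id"][i_on:i_off])
    dist = list(samples["gaze_distance_m"][i_on:i_off])
    for o, d in zip(obj, dist):
        if o == "" or cls_of.get(o) in exclude:
            continue
        counts[o] = counts.get(o, 0) + 1
        dists.setdefault(o, []).append(d)
    if not counts:
        return None
    best = sorted(counts.items(),
                  key=lambda kv: (-kv[1], float(np.mean(dists[kv[0]])), kv[0]))
    o, c = best[0]
    if c >= max(1, threshold * total - 1e-9):
        return o, c / total, float(np.mean(dists[o]))
    return None
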