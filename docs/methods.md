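# Methods

This note documents the models and procedures implemented in
`openworld_gaze`, the assumptions behind the synthetic-data generator, the
choices made where the design was genuinely open, and the limitations of
what the validation can show.

## 1. Event detection

Detection follows the adaptive velocity-threshold family of algorithms used
for microsaccade and saccade detection in free-viewing data.

**Velocity.** Gaze velocity is a 5-sample central difference,
`v_n = (x_{n+2} + x_{n+1} − x_{n−1} − x_{n−2}) / (6Δt)`, computed per
component on degree-scaled positions. Velocity is *undefined* wherever the
window touches a stream edge or an invalid (blink/dropout) sample; windows
are masked, never shortened. Consequently fixations cannot span gaps: a
blink terminates the inter-saccadic interval and a new one starts after it.

**Thresholds.** Per component, the threshold is
`η = factor · σ` with `factor = 6` and
`σ = sqrt(median(v²) − (median v)²)` over the defined samples of the whole
session — the median-based dispersion estimator, which is robust to the
saccades themselves (for zero-mean Gaussian noise it equals 0.6745 of the
standard deviation). The phrase "six times the median velocity" admits a
second, literal reading (6·median(|v|)); both are implemented behind
`DetectionParams.median_estimator`, with the dispersion estimator as the
default because the detector derives from EEG-eye-tracking toolchains that
use it. A floor of 5 °/s guards against degenerate (constant) input, with a
logged warning.

**Events.** Samples with `(v_x/η_x)² + (v_y/η_y)² > 1` form candidate runs;
runs ≥ 12 ms are saccades (amplitude = displacement between run endpoints,
peak velocity = max 2-D speed, angle = atan2 of the displacement). When two
saccades within one valid segment are separated by less than the 50 ms
minimum fixation duration, only the larger-amplitude one is kept, iterating
left-to-right until stable; ties keep the earlier one. Inter-saccadic
intervals ≥ 50 ms become fixations, flagged *qualifying* iff ≥ 100 ms;
shorter residues stay unclassified and enter no metric. Gap runs are blinks
iff their duration lies in [50 ms, 500 ms] — boundaries inclusive, as are
the 100 ms and 12 ms cutoffs — otherwise dropouts. All duration rules are
evaluated on integer sample counts (`ceil(dur·rate − ε)`), which makes
event boundaries exactly reproducible and lets the test suite compare the
vectorized implementation against a naive reference scan sample-for-sample.

**QC.** The main-sequence screen keeps saccades with duration 12–100 ms and
peak velocity 25–1200 °/s and emits the amplitude/peak-velocity pairs
(log-log main sequence) plus a 1°-resolution angle histogram.

## 2. Object labeling

Each qualifying fixation's epoch `[t_on, t_off)` is scanned for per-sample
collision objects. Terrain and sky are excluded from candidacy but count in
the denominator, as do invalid samples ("all gaze samples for that
fixation"). The non-excluded object with the most collision samples is the
candidate; it is assigned iff its count reaches 10 % of the epoch's
samples. Open choices resolved here (each switchable in
`LabelingParams`):

- dominance is computed *among non-excluded objects only* — a terrain
  majority does not block an object label;
- ties break toward the smaller mean collision distance, then
  lexicographic object ID;
- the per-object mean distance uses only the samples colliding with the
  assigned object (distance "from the object when the fixation occurred"),
  not the whole epoch;
- trail markers are labelable and are distractors for every condition.

The threshold sweep re-labels all fixations at {0, 1, 10, 20, 50} % and
reports labeled-fixation counts and mean distances; counts are
non-increasing in the threshold by construction, which the tests verify
against brute-force relabeling.

## 3. Metrics

Per (subject, object): `n_fixations`, `dwell_time` (Σ qualifying fixation
durations) and fixation-weighted mean distance. Global (cohort) means per
object average over *all* analyzed subjects, counting 0 for subjects who
never fixated the object — except distance, which is undefined without a
fixation and averages only over subjects who fixated it. Normalized
metrics are **subject mean − global mean**; the defining phrase ("mean
subtracted from the global") literally reads the other way, but the
published group comparisons show normalized values *larger* for preferred
objects, which requires this orientation; a sign switch is exposed. The
cohort mean of every normalized metric is identically zero per object once
zero-contributions are included (an algebraic identity the tests assert).

Session summaries are computed per epoch — full session, during the math
task, outside it — with events assigned to epochs by onset time, so the
full-session rate is exactly the duration-weighted mean of the two epoch
rates. Object rate counts each distinct object once per epoch. Position
velocity is the mean per-sample observer speed over the epoch.

Exclusion rules: (i) dropout fraction above a configurable threshold
(default 25 %; no number is published), (ii) exceeding the 20-minute limit
*and* validating fewer than 10 targets — both conditions required, (iii) an
unfinished math task excludes from the math analysis only. Outliers are
removed in a single pass at |z| > 3 computed from the unfiltered mean/SD.

## 4. Synthetic world and gaze generator

The generator's defaults *are* the study conditions; they live in
`defaults.yaml` (mirrored by the config dataclasses) and were calibrated
once so that the full pipeline — detection and labeling included, not the
truth log — recovers the study-level statistics; they are not per-analysis
dials.

**World.** A 1-D trail of 2000 m ("meters" are virtual-world units) with
objects at semi-regular intervals (uniform spacing + seeded jitter) and
Gaussian lateral offsets. Class-wise surface areas are lognormal with
invented medians (humvee 22 m², motorcycle 2.8, aircraft 35, furniture 3.5,
other 8, trail marker 0.5) — no size distribution is published beyond
anecdotes (humvee ≫ motorcycle), so these are documented as synthetic.
Visibility range grows as `30·A^0.15` m clipped to [25, 90] m: monotone in
area but deliberately flat, because a steeper size dependence produced
implausibly size-dominated gaze (see §5).

**Navigation.** Total traversal time is drawn around 680 s (≈ 11–12 min
sessions); speed carries multiplicative log-AR(1) noise (sd 0.12, τ = 5 s)
and is multiplied by 0.76 inside the math epoch. The math schedule starts
at 480 s: three summation trials of 3–4 spoken digits (1 s audio, 3–4 s
pauses), a 4 s response window, 8–30 s inter-trial breaks; the epoch ends
with the third response, giving ≈ 90–120 s. (The published total time on
the task is reported as ≈ 150 s; the schedule recipe above is what the
task description specifies, and only ratio-based dual-task contrasts depend
on the epoch, not its exact length.)

**Gaze.** Generated event-first in degrees of visual angle as a single
cyclopean stream (no eye-combination model; a pixel→degree helper for a
70 cm / 1920×1080 setup exists separately). A Markov scheduler alternates
fixations and transitions:

- *Fixation durations*: lognormal, median 0.30 s, σ = 0.68, plus a 10 %
  mass of short (50–99 ms) fixations; fixations carry slow drift (≤ 3 °/s,
  pursuit/optokinetic residue) and 0.03° white position noise.
- *Object choice*: background (terrain/sky) with probability 0.505, in
  runs averaging 5.2 fixations; otherwise an object visible from the
  current trail position, weighted by `area^0.15 · exp(−d/decay)`.
  Refixation bursts have length 1 + Poisson(mean − 1) with mean 5.8 —
  chosen over geometric bursts, whose heavy tail made per-object counts
  (and hence the cohort target contrast) excessively variable.
- *Target preference*: assigned targets get a 1.05× selection weight,
  1.25× burst length, a shorter distance decay (60 m vs 70 m, i.e. they
  are approached closer before being fixated), marginally shorter
  individual fixations (×0.955; dwell on targets rises a little less than
  their count, as observed), and — crucially — a *deliberate inspection*:
  when a target first enters view it is queued and inspected at the next
  opportunity with probability 0.93. The inspection mechanism models the
  explicit search-and-count instruction; without it a memoryless lottery
  validates only ~6–9 of 15 targets per session, far from the observed
  median of 14.
- *Saccades*: amplitude lognormal (median 5° toward new objects, 1.3° for
  refixations), direction from a horizontal-biased wrapped-normal mixture
  (70 % horizontal, sd 25°) reflected inside a ±18° × ±7° gaze field;
  duration `20 ms + 2.2 ms/°` with 10 % jitter, raised-cosine profile, so
  peak velocity `πA/2T` follows a saturating main sequence below 1200 °/s.
- *Gaps*: blinks at 0.14 per fixation boundary (≈ 0.28/s), lognormal
  durations clipped to [60, 450] ms; short (10–40 ms) and long (0.6–2 s)
  dropouts at low rates.
- *Collisions*: per-sample object IDs with 5 % within-fixation
  contamination (mostly terrain, sometimes a neighbouring object),
  emulating gaze-vector estimation error and occluders — this is what the
  10 % dominance rule must filter.
- *Dual-task modifiers* (inside the math epoch): blink probability ×1.52,
  burst length ×0.70 (fewer fixations per object, more objects per unit
  time).

Scheduling is in integer sample counts at 300 Hz, so truth events tile the
session exactly and everything is bit-identical under a fixed seed. The
cohort runner derives per-subject seeds as a stable SHA-256 hash of
(master seed, condition, index), so any single session can be regenerated
in isolation.

## 5. Calibration and what passing tests show

Calibrated quantities and their recovered values (pipeline output on the
default cohort, mean over 8 master seeds): median qualifying-fixation
duration 0.31 s, fixation rate 2.13 /s, 7.0 fixations and 2.67 s dwell per
labeled object, 44 % of fixations on terrain/sky, +47 % fixations and
+41 % dwell on targets vs distractors, −24 % navigation speed and +43 %
blink rate during the math epoch, gaze-validated target-count median 14.

Two generator decisions came *out of* calibration rather than first
principles and are worth flagging. First, burst-length dispersion: with
geometric bursts the per-subject target/distractor contrast had a standard
error near 7 percentage points across seeds; shifted-Poisson bursts halve
it without changing any mean. Second, the size dependence of gaze: an
`area^0.7`-weighted lottery produced contrasts from +190 % (aircraft, large
targets) to −30 % (furniture, small targets) — qualitatively wrong, since
the study observed a robust positive contrast in every condition analyzed.
The flat weighting plus the deliberate-inspection mechanism reproduces
both the overall contrast and a positive contrast in each condition, while
keeping the documented positive correlation between object size and
fixation counts.

What the synthetic data does **not** emulate: 3-D geometry and occlusion
(visibility is a 1-D range test; collisions are generated, not ray-cast),
head/eye coordination (gaze direction is free; no separate head channel),
smooth pursuit of moving objects (drift is random, not target-locked),
calibration drift, pupil dynamics, and any spatial structure in where
subjects leave the trail (the observer never does). Passing recovery tests
therefore shows that the *pipeline* — detector, labeler, metrics,
normalization, epoching — correctly extracts known structure from
realistic-statistics streams; it does not validate the generator as a model
of human gaze beyond the calibrated moments.

## 6. Numerical choices and degenerate inputs

- Duration thresholds in samples: `n ≥ ceil(dur·rate − 1e−9)` (inclusive
  boundaries robust to floating-point grids).
- Threshold floor 5 °/s; σ = 0 triggers the floor plus a warning rather
  than an error.
- Epoch assignment by event onset; a zero-length epoch is a contract error.
- Labeling with a zero-sample epoch is a contract error; an unknown
  collision object (absent from the catalog) is a validation error.
- Session CSVs store floats in shortest round-trip representation and are
  re-read with round-trip parsing, making `read(write(s))` bit-exact.
- Single-subject cohorts: global means degenerate to that subject's values
  with a warning; all normalized values are then zero.

## 7. Problem sizes

The shipped validation uses ten ~11.5-minute sessions (~2.1 M samples) for
pooled statistics and the full 45-subject cohort (~9.3 M samples) for the
contrasts; both run in well under a minute each on a single CPU. Unit and
property tests use a reduced world (300 m, 44 objects) and ~90 s sessions.
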