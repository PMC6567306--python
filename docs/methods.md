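# Methods

## The monitoring model

`pheromap` treats the home as four behaviorally significant places (P1
bedroom, P2 kitchen, P3 bathroom, P4 living room) placed in a generic
Cartesian space — by default at the quadrant centers of a 128×128 grid
(P1=(32,32), P2=(32,96), P3=(96,32), P4=(96,96)). The physical floor plan,
furniture, and exact sensor positions are deliberately discarded: only the
place a firing sensor belongs to matters. This is what makes the method
transferable across homes and tolerant to sensor redundancy changes.

Each hour of each day becomes a grayscale map: every place hosts one virtual
pheromone source whose intensity is the place's accounted event count for
that hour; the source diffuses linearly to a range σ, sources superpose
additively, and the aggregated field is quantized to 8-bit gray. Two
rendering modes exist:

* **count mode (default)** — one source per place, intensity = hourly count,
  no within-hour time structure. This is the mode used throughout the
  pipeline: it is linear in the counts, which makes count-averaging and
  image-averaging commute (see reference construction below).
* **evaporation mode** — one unit source per event, created at its
  within-hour minute, evaluated at the end of the hour with linear decay
  `(1 − Δt/τ)` clipped at zero. Provided for completeness; whether hourly
  maps should carry within-hour evaporation is a genuinely open modeling
  choice, and the hourly-count abstraction already discards most of the
  information evaporation would encode.

Both the diffusion factor and the decay factor are clipped below at zero: a
source out of range or fully evaporated contributes nothing (the linear
formulas go negative otherwise, which has no physical meaning).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grid_size | 128 | px | map resolution; small enough to render 60 days in seconds |
| σ (diffusion range) | 40 | px | lobes are smooth but the four quadrant places do not merge |
| τ (evaporation) | 60 | min | one rendering period; only used in evaporation mode |
| intensity cap P_max | 99th pct of all per-place hourly counts | events/h | fixes the white point once per analysis interval so "white" means the same brightness on every day; a fixed cap can be set for cross-dataset comparability |
| SSIM k1, k2, L | 0.01, 0.03, 255 | — | the standard stabilization constants for 8-bit images |
| debounce gap | 60 | s | repeated firings of one sensor faster than once a minute are one activity event |
| pressure mute | 10 | min | pressure mats fire continuously during rest |
| outlier threshold k | 3.0 | robust z | ≈0.1 % one-sided false-flag rate under normal noise |
| MAD fallback ε | 0.01 | index units | keeps deviant days flaggable when >half the series is identical (MAD = 0) |
| change-point min segment | 5 | days | shortest believable "new routine" |
| min SSE reduction | 30 % | — | a shift must explain a third of the series' variance |

SSIM is computed **globally** (one window covering the whole image, means /
variances / covariance with population divisor N). The pheromone maps are
smooth low-frequency fields, so the sliding-window, locally-weighted SSIM of
the image-quality literature adds nothing; the test suite nevertheless
cross-checks the implementation against an independent windowed
implementation configured for a single uniform full-image window (agreement
to 1e-6).

## Preprocessing contract

The pipeline order is fixed and each stage is idempotent:

1. motion OFF-filtering (PIRs reset automatically; OFF is uninformative;
   door CLOSE events are genuine state changes and are kept, with a
   configuration flag to drop them),
2. per-sensor 60 s debouncing (greedy forward pass anchored on the last
   *kept* event — the behavior of a rate limiter; deterministic),
3. per-sensor 10-minute pressure muting (same greedy pass, pressure type
   only),
4. sensor→place mapping (unknown sensors are dropped with a count — a
   mid-deployment hardware upgrade must not crash the pipeline),
5. hourly binning into half-open bins [h:00, h+1:00), local naive time, day
   boundary at midnight, no DST handling (the target datasets use naive
   local timestamps). Days without events yield all-zero matrices and stay
   in the analysis: an all-black day scored against the reference is
   exactly the "time away from home" signal.

## Reference construction and the daily index

The reference is built by averaging the **counts** hour-by-hour over the
reference window and rendering the 24 mean-count maps — not by averaging
pixels. In count mode the two are identical before quantization (the field
is linear in the source intensities); quantization is applied once, after
averaging, so a reference over n identical days reproduces the single-day
images bit-for-bit.

The reference window is chosen (a) manually, (b) as the 7 consecutive days
minimizing the summed across-days standard deviation of the (place, hour)
counts, or (c) as the 7 days minimizing the standard deviation of daily
sleep duration when annotations (or simulation ground truth) provide it.
Ties go to the earliest window.

A day's index is the unweighted mean of its hourly SSIMs over the chosen
hour subset. The aggregation had to be chosen; the mean is symmetric,
matches the hour-subset analyses (7–9 h mornings, 0–5 h nights) trivially,
and keeps the index in [−1, 1].

## Deviation detection

Outlier days: one-sided robust z-score, flag iff
`index < median − k·1.4826·MAD` (or below an optional absolute floor). Only
low similarity is anomalous. Trend shifts: exhaustive single change-point
scan over all splits with both segments ≥ 5 days, scored by two-segment
piecewise-constant SSE; accepted only if descending and the SSE reduction
exceeds 30 %. Exactly one change point is sought; multiple change points
are out of scope.

The two detectors interfere when both deviation kinds are present: extreme
singular days dominate the SSE and can mask a genuine level shift, and a
level shift inflates the global MAD. `analyze()` therefore (1) flags
extreme days globally and masks them, (2) scans the masked series for the
change point, and (3) re-applies the outlier rule within each segment,
re-centered on the segment's own median (falling back to the global rule
for segments shorter than 7 days). The raw `detect_outlier_days` /
`detect_trend_shift` functions keep the plain single-purpose rules.

All thresholds here are declared engineering defaults, not claims about any
particular dataset: the underlying approach identifies deviations that a
human reading the similarity plot would see, and the explicit rules exist
so the tests can quantify recovery.

## The synthetic generator

`simulate` draws each (day, place, hour) accounted-event count from a
Poisson distribution with a 4×24 rate profile, times events uniformly
within their hour, and attributes each to a uniformly chosen sensor of the
place's pool. Motion-sensor semantics are reproduced so the preprocessing
rules are genuinely exercised: every ON is followed by an automatic OFF 5 s
later, and 10 % of events double-fire within 1–30 s (removed by
debouncing). The default profile is a realistic single-occupant weekday —
bedroom activity ≈ 6 events/h through the night, kitchen peaks of 10–12
events/h at breakfast, lunch and dinner, bathroom spikes morning and
bedtime, living-room afternoons and evenings, and a 0.3–2 events/h
background; the kitchen deliberately has 4 sensors so fault-redundancy
experiments are possible.

Scenario operators: `away_day` scales all rates by (1 − magnitude);
`shifted_sleep` rotates the bedroom profile by whole hours; `missed_meal`
zeroes the kitchen in the breakfast window; `profile_swap` exchanges two
places' rows (an involution). A `sensor_change` adds ids to a place's pool
from a date on, and — since each sensor contributes its proportional share
of the place's events — scales the place's rate by
(n_old + n_added)/n_old; four added kitchen sensors therefore double the
kitchen flow, the analogue of a mid-study hardware upgrade. Faults remove a
sensor's events within a date range. Ground-truth sleep duration is read
off the schedule (hours where the bedroom rate is ≥ half its daily peak),
not inferred from events.

What the generator does **not** emulate: spatial correlation between
neighboring sensors, human micro-behavior (dwell-time distributions,
trajectories), overdispersion beyond Poisson (a negative-binomial hook is
the natural extension), visitors, or multi-resident homes. Passing the
synthetic recovery tests therefore shows the pipeline recovers deviations
of the magnitudes injected under Poisson-level noise; it does not by itself
establish performance on real homes.

## Numerical choices and degenerate inputs

* Quantization: `round(255·min(I, P_max)/P_max)` with round-half-up, so
  intensity P_max/2 maps to pixel 128; monotone in intensity.
* Pixel coordinates are cell centers, row-major, origin top-left, 0-based;
  distances are Euclidean in pixel units.
* SSIM of two identical images is exactly 1 by construction (the quotient
  collapses symbolically); constant-vs-constant pairs are stabilized by C1,
  C2.
* Empty logs, empty days, and all-zero rate profiles flow through every
  stage without special-casing; an empty hour subset, an uncovered
  reference window, and series too short for detection raise `ValueError`.
* Determinism: one `numpy` Generator seeded per scenario; rerunning any
  pipeline configuration reproduces byte-identical CSV/JSON artifacts.

## Problem sizes used in validation

The recovery experiments run 20 replicates of 60-day scenarios (≈ 30 k raw
events each) — enough days for a 7-day reference plus a 20-day post-change
segment, and enough replicates to call a ≥ 90 % success criterion with
binomial noise of ≈ 7 %. Oracle-equivalence checks use 16×16 grids (exact
to 1e-9), 1,000 random ≤ 50-event logs for the preprocessing rules, and 500
random series for the change-point scan.

## Known limitations

Single occupant only (a visitor looks like an anomaly); one change point
per series; hour-resolution binning hides sub-hour structure; the place
abstraction assumes a sensible sensor→place assignment exists; SSIM
saturates once a day's maps are fully dissimilar from the reference, so the
index separates "unusual" from "normal" more reliably than it ranks degrees
of unusualness.
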