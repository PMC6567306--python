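# pheromap

Long-term activity monitoring for a person living alone, from nothing but
low-cost binary sensors (PIR motion detectors, magnetic door contacts,
pressure mats). `pheromap` abstracts the home into four behaviorally
significant *places* — bedroom, kitchen, bathroom, living room — arranged in
a generic space, renders each hour of each day as a grayscale
**pheromone-distribution map**, and compares those maps against a reference
week to flag two kinds of routine deviation:

* **singular unusual days** (a day away, a badly shifted night), and
* **slow or sustained drifts** in the routine (including abrupt shifts in the
  sensor data flow itself, e.g. after a hardware upgrade).

The method needs no activity annotation, no training, and no knowledge of the
floor plan; it is aimed at ambient-assisted-living researchers and at anyone
prototyping routine monitoring on top of commodity security-system sensors.

## The model

Each place hosts a *virtual pheromone source* of intensity `P` (the place's
hourly event count). Pheromones diffuse linearly up to a range σ (pixels):

    p(x) = P (1 − x/σ)   for x ≤ σ,    0 otherwise,

superpose additively over sources, and can optionally evaporate linearly in
time with constant τ: `p(x, t) = P (1 − x/σ)(1 − (t − t_k)/τ)`, both factors
clipped at zero. Rendering the aggregated field over a 128×128 grid and
quantizing to 8-bit gray gives one map per hour — black where nothing
happened, bright lobes where and in proportion to how much activity occurred.

Before rendering, raw logs are cleaned with three rules: motion-detector OFF
events are discarded, repeated firings of the same sensor within one minute
are debounced, and pressure sensors are muted for 10 minutes after each
accounted event.

Maps are compared with the global structural similarity index

    SSIM(x, y) = (2 μx μy + C1)(2 σxy + C2) / ((μx² + μy² + C1)(σx² + σy² + C2)),

with `C1 = (0.01·255)²`, `C2 = (0.03·255)²`. The 24 reference maps come from
averaging the hourly counts over a reference week (chosen manually, by
minimum count dispersion, or by minimum sleep-duration spread); a day's
similarity index is the mean hourly SSIM over a chosen hour subset (all 24,
or e.g. 7–9 h to isolate the breakfast routine). Outlier days are flagged
one-sidedly at median − 3·1.4826·MAD; sustained shifts by an exhaustive
two-segment change-point fit that must be descending and explain ≥ 30 % of
the series' SSE.

## Worked example

No dataset is required: the `simulate` module generates event logs with the
statistical structure the method assumes. The script
`examples/03_detect_deviations.py` builds a 60-day routine with two injected
away-days, one 4 h sleep shift, and a kitchen sensor upgrade on day 40, then
runs the full analysis:

```
injected ground truth: {'anomaly_days': ['2022-03-13', '2022-03-26', '2022-04-17'],
                        'change_date': '2022-04-09', ...}
Anomaly report
==============
Unusual days (low similarity):
  2022-03-13  index=0.2917  robust_z=-18.07
  2022-03-26  index=0.7302  robust_z=-4.59
  2022-04-17  index=0.2257  robust_z=-14.92
Descending trend shift at 2022-04-09: mean 0.8750 -> 0.7966 (SSE reduction 53.9%)

morning 7-9: similarity shift |before-after| = 0.173
night 0-5: similarity shift |before-after| = 0.017
```

All three injected days are flagged (an ordinary day scores ≈ 0.85–0.95; the
away days drop below 0.3), and the sensor upgrade is located on the exact
day. The last two lines show the shift is concentrated in the morning hours
— the upgrade touched the kitchen — while the night-time bedroom series
barely moves.

The same pipeline is available as a CLI:

```sh
pheromap simulate --days 60 --seed 3 --with-sensor-change --out log.txt
pheromap run log.txt --reference-start 2022-03-01 --outdir out/
```

which writes the daily-activity CSV, similarity CSV + plot, and the anomaly
report (JSON and text) under `out/`. Readers for CASAS-style whitespace logs
and a generic `timestamp,sensor_id,value,sensor_type` CSV dialect are built
in, with example sensor→place configs shipped for the CASAS HH126 and
Kasteren House C testbeds.

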