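# surgaze

Gaze-behaviour analytics for simulated cataract surgery under a 3-D
heads-up display (HUD).

Expert and novice ophthalmic surgeons look at the operative field in
measurably different ways. When cataract surgery is performed through a
3-D HUD with a head-mounted eye tracker, those differences show up in
fixation durations, saccade lengths, how gaze is split between the HUD,
the instrument field and the periphery, how much of the capsulorhexis
model the surgeon's gaze covers, and in the geometry of the
capsulorhexis tear itself. `surgaze` implements that entire analysis as
a tested library — from raw gaze samples to group-level inference — for
researchers in surgical-skill assessment and eye-movement analysis.

## What is implemented

* **Event detection** (`surgaze.events`) — dispersion-threshold (I-DT)
  fixation classification with the deployed parameters (maximum
  dispersion 1.50°, duration 80–420 ms), where dispersion is the maximum
  pairwise angular separation of the window samples; saccades as
  centroid-to-centroid shifts between gap-free fixation pairs; blinks as
  sustained tracker-confidence dropouts; per-session metrics.
* **AOI mapping** (`surgaze.aoi`) — point-in-polygon assignment of
  fixation centroids to labeled surfaces (HUD, instrument field,
  peripheral) and the count-weighted gaze distribution.
* **Coverage** (`surgaze.coverage`) — 5° circular markers painted at
  fixation locations over a blue-labeled baseline mask of the
  capsulorhexis model; coverage = pixels blue in the baseline and
  non-blue afterwards over total baseline pixels; Gaussian fixation
  heatmaps.
* **Tear geometry** (`surgaze.rhexis`) — the tear-vector/forceps angle
  θ (directed convention on [0°, 180°]), tear length over the model
  reference length, initiation-to-wound distance in travel-circle radii,
  and the isoperimetric circularity 4πA/P² of closed tear outlines.
* **Inference from summaries** (`surgaze.stats`) — one-way ANOVA and
  Tukey HSD computed directly from per-group (n, mean, SD) tuples:
  MS_w = Σ(nᵢ−1)sᵢ²/Σ(nᵢ−1), q_ij = |m̄ᵢ−m̄ⱼ|/√(MS_w/n), with p-values
  from the studentized range distribution; Pearson correlation.
* **Synthetic cohorts** (`surgaze.synthetic`) — a generator that emits
  gaze streams, surfaces, masks and tear annotations with ground-truth
  event logs, parameterised by five expertise profiles whose values are
  the published group statistics (e.g. attending fixation duration
  0.118 ± 0.016 s, PGY2 saccade length 0.294 ± 0.053°, attending HUD
  share 77.2 ± 4.09%, tear angles from 88.4° ± 14.3° down to
  6.0° ± 1.58°).

The numbered scripts under `analysis/` run the stages over a
deterministic 5 × 5 cohort and write tables to `results/`; the
`surg-gaze` CLI exposes the same stages on files.

## Worked example

Tukey HSD from the published tear-angle summaries (five groups, n = 5
each) — the one analysis that is fully recomputable from printed values:

```sh
python -c "
import surgaze as sg
from surgaze import stats as st
st.write_group_summaries(sg.TEAR_ANGLE_SUMMARIES, 'tear_angles.csv')"
surg-gaze stats --summaries tear_angles.csv
```

prints

```
ANOVA: F(4, 20) = 104.83, p = 4.03e-13
  PGY2 vs PGY3: diff = +18, q = 5.34, p = 0.00926 *
  PGY2 vs PGY4: diff = +40, q = 11.87, p = 5.08e-07 *
  PGY2 vs fellow: diff = +70, q = 20.78, p = 3.35e-11 *
  PGY2 vs attending: diff = +82.4, q = 24.46, p = 1.62e-12 *
  PGY3 vs PGY4: diff = +22, q = 6.53, p = 0.0014 *
  PGY3 vs fellow: diff = +52, q = 15.43, p = 6.7e-09 *
  PGY3 vs attending: diff = +64.4, q = 19.11, p = 1.53e-10 *
  PGY4 vs fellow: diff = +30, q = 8.90, p = 3.41e-05 *
  PGY4 vs attending: diff = +42.4, q = 12.58, p = 2.01e-07 *
  fellow vs attending: diff = +12.4, q = 3.68, p = 0.108
```

The F statistic is the between-group tear-angle variance over the pooled
within-group variance (104.8 on 4 and 20 df); every novice-vs-expert
contrast is significant at far below α = 0.05, while fellows and
attendings are statistically indistinguishable — the expected signature
of tear control saturating with experience.

A full synthetic cohort run:

```sh
surg-gaze run --n-per-group 5 --duration 120 --seed 42 --out-dir out/
```

writes per-session metrics, group summaries and the ANOVA/Tukey tables,
and is byte-for-byte reproducible under a fixed seed.

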