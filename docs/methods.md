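# Methods

This note documents the models, parameters and numerical choices behind
`surgaze`, in the order the pipeline runs: event detection, AOI mapping,
coverage, tear geometry, inference, and the synthetic-data generator that
ties them together.

## Scene geometry

The world camera records 1280 × 720 px with a 100° diagonal field of
view at a nominal gaze rate of 200 Hz. Gaze is expressed in degrees of
visual angle in the scene frame (origin top-left, y down); surfaces and
masks are in pixels. The two frames are related by a single linear scale
`deg_per_px = diagonal_fov / diagonal_px` (≈ 0.068°/px), a small-angle
approximation. This is adequate here because every metric the pipeline
computes is either local (fixation dispersion, saccade amplitudes below
1°) or purely set-theoretic (containment, pixel counts), where tangent
distortion cancels or is irrelevant.

## Fixation detection (I-DT)

A window of consecutive samples is a fixation iff its **dispersion** —
the maximum pairwise angular separation, a rotation-invariant choice,
unlike the classic bounding-box width+height sum — stays ≤ 1.50° and its
duration lies in [80, 420] ms. Windows grow greedily left-to-right;
earliest-start windows win ties.

Decisions a user should know about:

* **Confidence gaps break windows.** Streams are confidence-filtered
  (default threshold 0.6; trackers report a per-sample confidence but
  the deployed threshold value is not published, so 0.6 is a
  configurable default). Samples removed by the filter leave temporal
  gaps; a gap > 2× the nominal sample interval terminates the window.
  This matters because consecutive dwells here are often < 0.3° apart —
  far below the 1.5° threshold — so temporal structure, not spatial
  spread, is what separates them. Real pupil trackers lose confidence
  during fast eye motion and blinks, which is exactly when dwells end.
* **Long dwells are split**, not discarded: a stationary episode longer
  than 420 ms becomes consecutive capped fixations, with a terminal
  remainder kept only if it still reaches 80 ms.
* **Duration comparisons carry a 1 ns absolute slack** so that a dwell
  of exactly 16 samples (80 ms on a 5 ms grid) is not rejected by
  floating-point cancellation in `t[j] − t[i]`.
* **Monotonicity caveat.** Raising `max_dispersion` does *not*
  universally increase the number of samples absorbed into fixations: a
  wider first window can strand a sub-80 ms tail that a narrower
  threshold would have split into two kept fixations (and the 420 ms cap
  produces the same effect independently). The property holds in the
  single-window regime and is tested there.

## Saccades and blinks

A saccade is the shift between two consecutive fixation centroids:
amplitude is the flat-plane angular distance (all observed amplitudes
are ≪ 1°, so spherical corrections are negligible), duration the
inter-fixation gap. Pairs separated by more than `max_gap` (default
75 ms) are **not** counted as saccades: physiological saccades complete
within tens of milliseconds, so a 300 ms hole is a blink or tracking
loss, not an eye movement. `max_gap=None` restores the pair-everything
behaviour. Centroid-to-centroid amplitude (rather than sample-path
length) is the default because it is deterministic under resampling; it
is the convention the published numbers are consistent with.

Blinks are maximal runs of confidence below 0.5 lasting ≥ 100 ms,
detected on the *unfiltered* stream. The floor sits below the analysis
threshold (0.6) deliberately: motion-degraded samples (0.5–0.6) are
excluded from fixation analysis without being miscounted as blinks.

## AOI mapping

Three labeled simple polygons partition the scene: HUD, instrument
field, peripheral. Fixations are assigned by the surface containing
their centroid (boundary counts as inside); overlapping surfaces
resolve by the fixed priority HUD > instrument_field > peripheral, and
unmatched centroids fall back to peripheral. The gaze distribution is
count-weighted (each fixation votes once, regardless of duration).
Containment is delegated to shapely's `covers`; the test suite checks it
against an independently written even-odd ray-casting oracle on random
points. Marker-tracking homography is out of scope: surfaces arrive
already in scene coordinates.

## Coverage

The model region is labeled with an exact blue mask, RGB (0, 0, 255); a
color tolerance is available for imported images. A circular marker of
5° angular **diameter** (the size is configurable and the
diameter-vs-radius reading is explicit, since "5° circular marker"
admits both) is painted at each fixation centroid; a per-sample mode
exists behind a flag. Coverage is the count of pixels blue in the
baseline and non-blue after painting, divided by the **total pixel
count of the baseline image**; `denominator="blue_region"` restricts
the denominator to the model region itself (the two conventions differ
by a constant factor ≈ 20× for the default layout, and both are
reported by the analysis scripts). Heatmaps deposit unit (or
duration-weighted) mass per fixation and smooth with an isotropic
Gaussian; rasterization uses `skimage.draw.disk`, whose pixel counts
match πr² within a perimeter-order tolerance.

## Tear geometry

Annotations carry the forceps axis, tear vector, forceps travel circle,
tear path polyline, initiation and wound points, and a model reference
length, all in pixels.

* **Tear angle** defaults to the *directed* convention: the angle
  between the two direction vectors, in [0°, 180°]. The folded
  undirected-line convention ([0°, 90°]) is available via
  `mode="line"`, but it cannot be the convention behind the observed
  data: a distribution supported on [0, 90] with mean 88.4 cannot have
  an SD above √((90−88.4)·88.4) ≈ 11.9 (Bhatia–Davis inequality), and
  the novice group reports 14.3. Angles near 0° mean the flap is drawn
  along the forceps axis (controlled, tangential tearing); angles near
  90° and above mean pulling across or against it.
* **Diameter fraction** is tear-path arc length over the model
  reference length; the reference defaults to the travel-circle
  circumference but is an explicit input, since the published
  length-over-length percentages do not pin the reference down.
* **Initiation distance** is the initiation-to-wound Euclidean distance
  in travel-circle radii.
* **Circularity** is the isoperimetric quotient 4πA/P² of the closed
  outline (shoelace area, segment-sum perimeter). Paths are auto-closed
  when the endpoint gap is < 10% of the path length and rejected (with
  the gap size) otherwise; the quotient is 1 only in the circular limit
  and equals (π/n)/tan(π/n) for regular n-gons, which the tests use as
  a closed form.

All four metrics are invariant under global rotation, translation and
positive scaling, which the property tests assert.

## Inference from summary statistics

Raw per-participant values are not available, so the inference layer
works from (label, n, mean, sd) tuples. The summary-statistic one-way
ANOVA is algebraically identical to the raw-data ANOVA of any sample
matching those moments, which is how it is tested (against
`scipy.stats.f_oneway` on moment-matched reconstructions). Tukey HSD is
implemented for the balanced design only (q = |Δm̄|/√(MS_w/n), p from
the studentized range with k groups and k(n−1) df); the Tukey–Kramer
unequal-n extension is deliberately not offered. The studentized range
tail comes from `scipy.stats.studentized_range`, and the k = 2 identity
q = |t|√2 against the pooled t-test is verified to 1e-6. Published
means/SDs are rounded, so reproduced p-values are checked against the
published *bounds* (p < 0.0001), not for equality. No correction beyond
Tukey itself is applied.

## Synthetic-data generator

The generator exists so every stage can be tested against ground truth.
It emulates, per session:

* **Dwell/saccade structure.** Sessions are sequences of dwells
  (ground-truth fixations) separated by centroid jumps with 2–3
  transit samples. Dwell durations follow a truncated log-normal on
  [80, 420] ms (positive, right-skewed, supported exactly on the
  detector window; log-scale shape 0.45) whose *truncated* mean is
  solved to equal the session's duration parameter. Jump amplitudes are
  log-normal (shape 0.4) with mean equal to the saccade parameter;
  directions are resampled uniformly until the step stays inside the
  current work disk, which preserves amplitude exactly. Within-dwell
  jitter is isotropic Gaussian noise truncated at ±3.5 SD per axis, so
  a dwell's dispersion is bounded by 9.9 × noise_sd and every generated
  dwell is classifiable by construction (noise_sd ≤ 0.15°).
* **Participant heterogeneity.** The published group values are
  mean ± SD across n = 5 participants. Each session therefore first
  draws its own duration, amplitude and HUD-share parameters from
  truncated normals around the group values — again moment-matched, so
  the truncation never biases the group mean. This hierarchy is what
  makes "recovered mean within 3 SE over 30 replicates" a meaningful
  check rather than a formality.
* **Confidence as event structure.** Dwell samples carry confidence
  0.85–1.0; transit, between-AOI reorientation and repositioning
  samples carry 0.50–0.58 (degraded by motion — below the 0.6 analysis
  threshold, above the 0.5 blink floor); blinks drop to ≤ 0.05 for
  100–300 ms, inserted between dwells at the profile's rate (the
  insertion probability is solved so the expected rate survives the
  cycle lengthening that blinks cause).
* **AOI structure.** A session is divided into a handful of contiguous
  AOI blocks (long allocations split into two visits) whose total time
  matches the session's AOI shares; between-block reorientations are
  emitted as low-confidence transit, since a head-scale gaze shift to a
  surface tens of degrees away is not a clean saccade and real trackers
  lose the surface during it. Within a block, gaze random-walks inside
  a work disk centred in the surface polygon.
* **Strategy.** Feed-forward (expert) profiles scan: their work disk is
  broad (4°) and the walk re-anchors to a new spot in the disk every
  2–4 s through a short low-confidence repositioning gap. Reactive
  (novice) profiles stay locked to the tool tip (1.5° disk, no
  re-anchoring). This reproduces the qualitative coverage finding —
  experts' markers spread over the model, novices' cluster at the tear
  site — without touching the saccade-amplitude statistics, because
  repositioning shifts are excluded from clean saccade pairs.
* **Tear annotations.** The true tear angle is a moment-matched
  truncated normal on [0°, 180°]; the construction rotates the tear
  vector away from a random forceps axis by exactly the drawn angle, so
  the measured angle recovers the draw to float precision. Tear paths
  are circular arcs whose length over the circumference equals the
  drawn diameter fraction; initiation points sit on the travel circle
  at the profile's wound distance. Closed outlines for circularity
  studies perturb the circle radially with low-order harmonics whose
  amplitude depends on strategy.

Seeds derive stably from (base_seed, group label, replicate index) via
CRC-32, stay below 2³¹, and identical (profile, seed) pairs reproduce
byte-identical streams.

### What the generator does *not* emulate

No smooth pursuit, no main-sequence saccade dynamics (transits are 2–3
interpolated samples), no drift or calibration error, no pupil imagery,
no correlation between a participant's gaze parameters and their tear
geometry, and no realistic surgical video. Consequently, passing
recovery tests show that the *pipeline* is unbiased and internally
consistent under the published statistical structure — they do not
validate the detector against human-labeled recordings.

### Profile table provenance

All five groups' tear-angle parameters, both endpoints' fixation
durations, saccade amplitudes (PGY2, fellow, attending), HUD and
instrument-field shares (PGY2, attending), diameter fractions (PGY2,
fellow, attending) and the two published fixation counts are used
verbatim. The remaining entries (intermediate groups' durations,
counts, AOI splits and diameter fractions; all blink rates ~12/min;
noise SD 0.12°; initiation-distance parameters) are monotone
interpolations or field-realistic defaults, flagged inline in
`profiles.py`; no recovery experiment depends on them.

## Problem sizes

The acceptance script and the recovery tests use 30 replicates of 300 s
sessions per group (≈ 60 000 samples each), the cohort scripts 5 × 5
sessions of 120 s — sizes at which the between-participant SE, not the
within-session noise, dominates the recovery bands. The full test suite
runs in under a minute on one CPU.

## Known limitations

* The individual-level published results (R² = 0.93 over 25
  participants; the fixation-duration contrast p = 0.042) require
  per-participant raw values that were never published and are
  therefore out of reach; the package reproduces the group-level
  inference instead (group-mean competency vs experience: r ≈ 0.98).
* The summary-ANOVA layer assumes the published SDs are sample SDs
  (ddof = 1); if any were SEMs the reconstructed F would change.
* Coverage depends on the assumed model-circle placement within the
  instrument field; the analysis scripts treat it as a fixed layout
  parameter.
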