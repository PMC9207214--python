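# Methods

`olcquant` packages the quantification procedures used to profile
oligodendrocyte-lineage cells (OLCs) that associate with dorsal root
ganglion (DRG) sensory axons in the larval zebrafish spinal cord:
migration-track featurization with k-means/elbow clustering, ROI
integrated-density measurement, Z-score calcium event calling, sheath
morphometry statistics, and behavioral shiver scoring.  The raw movies
behind the original measurements are not publicly deposited, so every
stage is paired with a seeded synthetic generator whose ground truth is
known exactly; this note records the models, parameter choices and
their limits.

## Coordinate and unit conventions

Positions are in microns with x running anterior→posterior and y
ventral→dorsal; track time is in minutes (time-lapse frames every
5 min by default), trace time in seconds (2 s sampling by default),
and contact delays are reported in hours.  Pixel coordinates are
0-based `(row, col)`; a pixel belongs to an ROI when its center does.

## Migration tracks and features

A track is the centroid of one cell traced through a movie.  Features:

* **total distance** — sum of Euclidean step lengths, Σᵢ‖xᵢ₊₁ − xᵢ‖;
* **direction changes** — displacement vectors shorter than `min_step`
  (default 2 μm) are merged forward as tracing jitter; a change is
  counted wherever the turning angle between successive retained
  vectors is ≥ `angle_threshold` (default 90°, threshold inclusive so
  right-angle turns count);
* **net displacement**, **duration**, and **velocity** = total
  distance / elapsed time (μm/min).

The source study never formalizes "direction change"; the
jitter-filtered turning-angle rule was chosen because it is parameter
transparent, invariant to rigid motion and uniform scaling, and
reduces to the qualitative direct-vs-wandering dichotomy the original
migration plots show.  Both parameters are exposed everywhere.

DREZ-timing quantities operate on annotated tracks: `contact_delay` is
(DREZ contact − pioneer-axon entry)/60 in hours and must be
non-negative; `dorsal_displacement_after_contact` is the dorsal (+y)
offset between the track end and the nearest sample at or after the
annotated contact time.

### Track generator

Each simulated cell is a polyline of `n_frames` waypoints (default 11,
i.e. 10 equal steps) whose step lengths sum exactly to the configured
path length, with exactly the configured number of turns (default
turn angle 150°, alternating sign) placed at evenly spread step
boundaries; isotropic Gaussian jitter of SD `positional_noise_sd` is
then added to every waypoint.  At zero noise the extracted features
equal the targets exactly, which is what the construction was chosen
for.  The default three-group layout mirrors the observed migration
structure: (75 μm, 1 change), (90 μm, 4), (250 μm, 5), seven cells
each, jitter 2 μm.

The waypoint count is deliberately small: with 2 μm jitter the steps
of the shortest configured path are ≈7.5 μm, large enough that the
turning-angle featurizer sees the built-in geometry rather than noise.
The generator therefore emulates tracks at the granularity of manual
waypoint tracing, not the full 5-min frame rate of a 24 h movie; it
also omits heterogeneous speeds within a track, pauses, and cell
division (the imaged sensory OLCs do not divide in the 24 h windows).
Conclusions from passing tests are about the estimators under this
waypoint model, not about biological variability.

## Clustering and elbow selection

Tracks are clustered in the 2-D feature space (total distance,
direction changes).  Raw distances (tens to hundreds of μm) dwarf
change counts (0–6), so both features are z-standardized by default;
the flag is recorded in the result and an unscaled path exists because
the original analysis does not state whether it standardized.

K-means is Lloyd's algorithm with k-means++ seeding, best of
`n_restarts = 20` restarts by within-cluster sum of squares (WCSS),
deterministic under (seed, restarts); scikit-learn's `KMeans` provides
exactly this and is used directly, with an exhaustive-enumeration
optimum as the test oracle at tiny n.

k is selected on the WCSS curve for k = 1..k_max (default 8).  Two
automations are provided.  The default, `knee`, picks the k with the
largest vertical distance below the chord joining the curve's
endpoints.  The alternative, `second_diff`, maximizes the discrete
curvature W(k−1) − 2W(k) + W(k+1).  The second difference was
considered first but degenerates on exactly the cluster layouts this
analysis produces: when one group (the long-range migrators) lies much
farther out than the two short-distance groups, the k=1→2 WCSS drop
dominates the curvature and k = 2 is returned even for zero-noise
data.  The chord criterion accounts for the cumulative drop and finds
the visual elbow at k = 3 on these layouts, so it is the default; ties
resolve to the smallest k and the full curve is returned for audit.
Cluster-label agreement is scored with the adjusted Rand index (ARI).

## ROI integrated density

Integrated density is the sum of pixel intensities inside an ROI,
per frame.  Polygons are filled by the even-odd rule evaluated at
pixel centers; polylines include every pixel whose center lies within
`line_width/2` of the path (round caps).  No sub-pixel interpolation
is performed: masks are bit-reproducible, at the cost of marginal
accuracy at the mask boundary, which is irrelevant at test scale.

Background normalization follows the rule that every fluorescence
quantification is normalized to the image's background, but the
original operator is not defined.  Default: `raw − mean(background) ×
ROI area`, which preserves integrated-density units and maps an ROI
identical to its background to exactly 0; `divide` (raw / mean
background) is available.  Both are exposed because either reading is
defensible.

The stack generator renders a Gaussian blob (σ = 1.5 px) moving along
a configured path over a flat background; the per-frame ROI truth is
computed from the noise-free render, so added Gaussian pixel noise is
the only discrepancy a measurement can show.

## Calcium event calling

Each trace is Z-scored against its own whole-trace mean and sample
standard deviation (ddof = 1, matching the spreadsheet workflow the
original analysis describes): zₜ = (xₜ − x̄)/s.  A whole-trace
reference was chosen over a pre-stimulus baseline window because the
described procedure computes one Z per trace; Z-scores are affine
invariant, so raw intensity scaling never changes calls.  A
zero-variance trace is flagged degenerate and yields an all-zero
Z-series and no events — a constant cell is "inactive", not an error.

Events are maximal runs of consecutive samples with z ≥ 2 (threshold
inclusive: "2 or greater"); each run is one peak, `is_active` means at
least one peak.  Runs separated by fewer than `min_gap_samples`
(default 1, i.e. no merging) sub-threshold samples can be merged for
slow indicators.  Run-based counting was chosen because the original
peak counts are not defined per sample; a decaying transient hovering
at threshold can split into two runs, which slightly inflates peak
counts near threshold.  Events are assigned to pre/post stimulus
epochs by the time of their peak sample; the two counts always sum to
the number of peaks.

### Trace generator and the bounded-noise assumption

Traces are baseline + noise + transients with instantaneous rise and
exponential decay (default amplitude 30, decay 5 samples, baseline
100, noise SD 5, 60 samples at 2 s).  The default noise is **bounded**:
arcsine-distributed with exact SD `noise_sd` and hard amplitude bound
√2 × SD.  This encodes the premise of the Z ≥ 2 rule — that baseline
fluctuation stays below the calling threshold.  Unbounded Gaussian
noise violates that premise by construction: ≈2.3% of Gaussian samples
exceed 2 SDs, i.e. roughly 1.3 spurious "events" per event-free
60-sample trace, and even uniform noise (bound √3 × SD ≈ 1.73 SD)
drifts over threshold in a few percent of traces once the sample SD
fluctuates at n = 60.  `noise_dist="uniform"` and `"gaussian"` are
available precisely to study how the rule degrades on heavier-tailed
baselines; results on real traces depend on how well their baseline
conforms to the bounded assumption.

## Sheath morphometry

Group comparisons use the cell as the unit of analysis: sheath values
are averaged per cell first (the original study reports average
process length per cell), then per-cell averages are compared across
classes with a Welch two-sample t test (no variance-equality
information exists, so the pooled test was not used); raw-sheath
pooling is available behind `unit="sheath"`.  Per-fish stability
across days is a one-way ANOVA of sheath measurements grouped by day.
The original per-fish p values could come from repeated-measures or
corrected procedures — the text does not say — so the plain ANOVA is
documented as an approximation; a dataset with zero variance both
between and within days is flagged degenerate and reported as F = 0,
p = 1 (perfect stability), while zero within-day variance with
distinct day means gives F = ∞, p = 0.

Generator defaults reproduce the reported magnitudes: sensory sheaths
187.78 μm long and 5.01 μm wide versus 94.67 μm and 7.49 μm for
non-sensory cells, n = 12 vs 11 cells, with class SDs equal to the
reported SEMs × √n and 10% within-cell scatter.  The across-day
generator defaults to equal day means (the stable-sheath null used for
p-value calibration).

## Behavior scoring

Recordings longer than 20 s are truncated to their first 20 s
("normalized to 20 s"; for a fraction-of-time score, truncation and
denominator rescaling are algebraically equivalent, truncation was
implemented).  The original shivering was scored by eye, so a detector
had to be defined: 4th-order zero-phase Butterworth high-pass at 5 Hz
separates the rapid shiver component from slow swim undulation, a
centered 0.5 s sliding-window RMS envelope is thresholded at
`amp_threshold`, and the shiver fraction is marked samples / total
samples.  All three parameters are exposed; the amplitude threshold
has no in-study analogue and is calibrated only against the synthetic
generator (unit-amplitude 15 Hz tone bursts over Gaussian noise, SD
0.05), so applying the detector to real displacement traces requires
re-choosing it.  The default threshold, 0.5 = (tone RMS)/√2, is the
half-overlap point of the sliding window: the envelope then crosses
threshold exactly at a burst edge, making the estimated shiver
duration unbiased rather than smeared outward.  Tactile responses are
simple per-group responder percentages.

## Determinism and numerical choices

All generators draw from `numpy.random.default_rng(seed)` per call; no
global state.  Equal configs and seeds give byte-identical CSVs, and
the pipeline writes its fully resolved YAML config next to its
outputs.  Tolerances: Z-series mean/SD contract at 1e-9; rasterization
uses a 1e-9 slack so exact half-width hits count as inside; turning
angles get a 1e-9 degree slack so exact-threshold turns count.  Ties
in elbow selection resolve to the smallest k.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
data at the scale of the original experiments: 21-cell track cohorts
(100 seeds for recovery rates), 60-sample traces (100 seeds per
operating characteristic), 12 + 11 cell sheath tables, 200-seed null
calibration for the stability ANOVA, and eight animals per behavior
group.  These sizes make every property checkable in seconds while
matching the reported ns; none of the statistics here need more.

## Known limitations

* The direction-change and shiver detectors are explicit stand-ins for
  manual scoring; their parameters are choices, not measurements.
* The elbow is automated; on WCSS curves without a pronounced bend the
  chord criterion still returns some k — inspect `wcss_curve`.
* Peak counting near threshold can split one biological transient into
  two runs (see above); use `min_gap_samples` for slow indicators.
* The synthetic generators emulate statistical structure, not imaging
  physics: no photon noise model, drift, z-projection artifacts, or
  segmentation errors.  Passing tests validate the estimators under
  the stated models only.
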