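# olcquant

Quantification toolkit for intravital time-lapse imaging of
oligodendrocyte-lineage cells (OLCs) in the larval zebrafish spinal
cord — in particular the small population of OLCs that migrates to the
dorsal root entry zone (DREZ) and settles on dorsal root ganglion
(DRG) sensory axons.  It is written for imaging labs that track single
cells through confocal movies and need the downstream numbers:
migration profiles, cluster structure, fluorescence event calls,
sheath morphometry, and behavior scores.

## What it computes

* **Migration features** per tracked cell: total distance
  Σᵢ‖xᵢ₊₁ − xᵢ‖, number of direction changes (turning angle ≥ 90°
  after a 2 μm jitter filter), net displacement, velocity; DREZ-timing
  quantities (contact delay in hours after pioneer-axon entry, dorsal
  displacement after contact) and origin-overlaid migration-plot
  tables.
* **Clustering** of the (distance, direction-changes) feature space:
  Lloyd k-means (k-means++ seeding, best of 20 restarts), k chosen by
  the elbow of the within-cluster sum-of-squares curve, agreement
  scored by adjusted Rand index.
* **ROI integrated density** over TIFF stacks: polygon (even-odd
  rule) and widened-polyline ROIs, background normalization by
  subtraction (default) or division.
* **Calcium event calling**: per-trace Z-scores
  zₜ = (xₜ − x̄)/s (sample SD), events = maximal runs with z ≥ 2,
  percent-active per animal, pre/post-stimulus epoch counts, cells ×
  time Z-score heatmaps.
* **Sheath morphometry**: per-cell averaged length/width compared
  between sensory and non-sensory classes (Welch t), per-fish
  across-day stability (one-way ANOVA).
* **Behavior**: 20 s shiver scoring (high-pass + sliding-RMS
  detector), group summaries with pairwise Welch tests, tactile
  response rates.
* **Synthetic generators** with exact ground truth for every stage,
  so the whole pipeline is testable without the original movies.

See `docs/methods.md` for the models, default parameters and their
rationale.

## Worked example

Recover the three migration groups from a simulated 21-cell cohort
(`examples/01_track_features_and_clustering.py`):

```python
from olcquant import (TrackSimConfig, generate_tracks, features_table,
                      elbow_select_k, cluster_agreement)

tracks, truth = generate_tracks(TrackSimConfig(seed=2))
feats = features_table(tracks)
result = elbow_select_k(feats, k_max=8, seed=2)
print(result.k, cluster_agreement(result.labels, truth))
```

Output:

```
track_id  total_distance  n_direction_changes  net_displacement  duration  velocity
track000       72.539966                    1         13.914166      50.0  1.450799
track001       80.779925                    1         20.087840      50.0  1.615599
track002       84.182060                    1         13.580770      50.0  1.683641

elbow-selected k = 3  (WCSS curve: 1:42.0, 2:11.2, 3:0.1, 4:0.1, 5:0.0, ...)
adjusted Rand index vs ground truth = 1.00
```

The elbow lands at k = 3 — the cohort splits into short/direct,
short/wandering and long-range/wandering cells — and the ARI of 1.0
says the k-means labels match the generator's ground truth exactly.
The other scripts in `examples/` walk through ROI densities, calcium
event calling, morphometry and behavior the same way, and
`examples/06_full_pipeline.py` (or `olcquant run-all --seed 7 --out
demo`) runs every stage from one config with full provenance.

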