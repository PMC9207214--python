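"""Featurize migration tracks and recover the three migration groups.

Generates a 21-cell cohort with the three-group structure (short/direct,
short/wandering, long-range/wandering), extracts total distance and
direction changes per cell, and lets the elbow method pick the number
of k-means clusters.
"""

import numpy as np

from olcquant import (
    TrackSimConfig,
    cluster_agreement,
    elbow_select_k,
    features_table,
    generate_tracks,
)

tracks, truth = generate_tracks(TrackSimConfig(seed=2))
feats = features_table(tracks)
print(feats.head(3).to_string(index=False))

result = elbow_select_k(feats, k_max=8, seed=2)
ari = cluster_agreement(result.labels, truth)

print(f"\nelbow-selected k = {result.k}  (WCSS curve: "
      + ", ".join(f"{k}:{w:.1f}" for k, w in result.wcss_curve.items()) + ")")
print(f"adjusted Rand index vs ground truth = {ari:.2f}")
print("\nk = 3 with ARI near 1 means the two migration features alone "
      "separate the three simulated cell populations, as in the profiling "
      "of migrating oligodendrocyte progenitors.")
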