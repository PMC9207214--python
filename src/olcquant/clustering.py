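"""K-means clustering of migration features with elbow-method k selection.

Tracks are clustered in the two-feature space used for the migration
profiling: total distance migrated (um) and number of direction
changes.  Because raw distances (tens to hundreds of um) dwarf change
counts (0-6), both features are z-standardized by default before
clustering; the flag is recorded in the result for provenance.

The number of clusters is chosen by the elbow method on the
within-cluster sum of squares (WCSS) curve.  Two automations are
provided: ``"knee"`` (default) picks the k with the largest vertical
distance below the chord joining the ends of the WCSS curve, the
discrete analogue of the visual elbow; ``"second_diff"`` picks the k
maximizing the second difference of the curve.  The knee rule is the
default because the second difference degenerates to k = 2 whenever
the first WCSS drop dominates, which happens for cluster layouts where
one group is much farther out than the others (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .tracks import TrackFeatures

__all__ = [
    "ClusterResult",
    "feature_matrix",
    "kmeans_fit",
    "elbow_select_k",
    "cluster_agreement",
]

#: features defining the clustering space
FEATURE_COLUMNS = ("total_distance", "n_direction_changes")


@dataclass
class ClusterResult:
    """Outcome of a k-means fit (fixed k or elbow-selected).

    ``centroids`` are reported in the original feature units regardless
    of standardization.  ``wcss_curve`` maps each fitted k to its best
    within-cluster sum of squares (in the fitted, possibly standardized,
    space); for a fixed-k fit it has a single entry.
    """

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    wcss_curve: dict[int, float]
    seed: int
    n_restarts: int
    standardized: bool
    method: str = "fixed"  # fixed | knee | second_diff
    track_ids: list[str] = field(default_factory=list)

    @property
    def wcss(self) -> float:
        return self.wcss_curve[self.k]

    def labels_frame(self) -> pd.DataFrame:
        ids = self.track_ids or [str(i) for i in range(len(self.labels))]
        return pd.DataFrame({"track_id": ids, "cluster": self.labels})


def feature_matrix(
    features: pd.DataFrame | list[TrackFeatures],
) -> tuple[np.ndarray, list[str]]:
    """Extract the (n, 2) matrix [total_distance, n_direction_changes]
    and the track ids from a feature table or list."""
    if isinstance(features, pd.DataFrame):
        df = features
    else:
        df = pd.DataFrame([f.as_dict() for f in features])
    X = df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    ids = [str(t) for t in df["track_id"]] if "track_id" in df else \
        [str(i) for i in range(len(X))]
    return X, ids


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)  # constant feature: leave centered only
    return (X - mu) / sd, mu, sd


def _fit_one(Xs: np.ndarray, k: int, seed: int, n_restarts: int) -> KMeans:
    return KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(Xs)


def kmeans_fit(
    features: pd.DataFrame | list[TrackFeatures],
    k: int,
    seed: int = 0,
    n_restarts: int = 20,
    standardize: bool = True,
) -> ClusterResult:
    """Lloyd k-means (k-means++ seeding, best of ``n_restarts`` by WCSS)
    at a fixed k on the (distance, direction-changes) feature space."""
    X, ids = feature_matrix(features)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(X):
        raise ValueError(f"k = {k} exceeds the number of tracks ({len(X)})")
    if standardize:
        Xs, mu, sd = _standardize(X)
    else:
        Xs, mu, sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    km = _fit_one(Xs, k, seed, n_restarts)
    return ClusterResult(
        k=k,
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_ * sd + mu,
        wcss_curve={k: float(km.inertia_)},
        seed=seed,
        n_restarts=n_restarts,
        standardized=standardize,
        method="fixed",
        track_ids=ids,
    )


def _select_knee(ks: np.ndarray, wcss: np.ndarray) -> int:
    """k with the largest vertical drop below the chord from the first to
    the last point of the WCSS curve (ties -> smallest k)."""
    k0, k1 = ks[0], ks[-1]
    w0, w1 = wcss[0], wcss[-1]
    chord = w0 + (w1 - w0) * (ks - k0) / max(k1 - k0, 1)
    gaps = chord - wcss
    return int(ks[int(np.argmax(gaps))])


def _select_second_diff(ks: np.ndarray, wcss: np.ndarray) -> int:
    """k maximizing the discrete curvature W(k-1) - 2 W(k) + W(k+1)
    (ties -> smallest k)."""
    if len(ks) < 3:
        return int(ks[0])
    d2 = wcss[:-2] - 2 * wcss[1:-1] + wcss[2:]
    return int(ks[1:-1][int(np.argmax(d2))])


def elbow_select_k(
    features: pd.DataFrame | list[TrackFeatures],
    k_max: int = 8,
    seed: int = 0,
    n_restarts: int = 20,
    standardize: bool = True,
    method: str = "knee",
) -> ClusterResult:
    """Fit k = 1..k_max and pick the elbow of the WCSS curve.

    Returns the full fit at the selected k with the whole WCSS curve
    attached for audit.  Needs at least 3 tracks; k_max is clipped to
    the number of tracks.
    """
    if method not in ("knee", "second_diff"):
        raise ValueError(f"unknown elbow method {method!r}")
    X, ids = feature_matrix(features)
    if len(X) < 3:
        raise ValueError("elbow selection needs at least 3 tracks")
    k_hi = min(k_max, len(X))
    if standardize:
        Xs, mu, sd = _standardize(X)
    else:
        Xs, mu, sd = X, np.zeros(X.shape[1]), np.ones(X.shape[1])
    fits = {k: _fit_one(Xs, k, seed, n_restarts) for k in range(1, k_hi + 1)}
    ks = np.arange(1, k_hi + 1)
    wcss = np.array([fits[k].inertia_ for k in ks])
    if method == "knee":
        k_sel = _select_knee(ks, wcss)
    else:
        k_sel = _select_second_diff(ks, wcss)
    km = fits[k_sel]
    return ClusterResult(
        k=k_sel,
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_ * sd + mu,
        wcss_curve={int(k): float(w) for k, w in zip(ks, wcss)},
        seed=seed,
        n_restarts=n_restarts,
        standardized=standardize,
        method=method,
        track_ids=ids,
    )


def cluster_agreement(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings (1 = identical up to
    label permutation, ~0 = chance)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(a, b))
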