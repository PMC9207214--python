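"""Migration-track metrics for oligodendrocyte-lineage cells.

A track is the time-ordered sequence of cell-body centroid positions
(in microns) obtained by tracing one cell through a time-lapse movie.
Coordinate convention throughout the package: x runs anterior to
posterior, y runs ventral to dorsal, both in microns; time is in
minutes.  Annotated event times (pioneer-axon entry into the spinal
cord, first contact with the dorsal root entry zone) are expressed on
the same time axis and reported as delays in hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackFeatures",
    "path_length",
    "count_direction_changes",
    "velocity",
    "contact_delay",
    "dorsal_displacement_after_contact",
    "migration_plot_table",
    "extract_features",
    "features_table",
    "tracks_to_frame",
    "tracks_from_frame",
    "read_tracks_csv",
    "write_tracks_csv",
    "apply_annotations",
]

#: default turning-angle threshold (degrees) for a direction change
DEFAULT_ANGLE_THRESHOLD = 90.0
#: default jitter filter: displacement vectors shorter than this (um) are
#: merged forward before turning angles are evaluated
DEFAULT_MIN_STEP = 2.0


@dataclass
class Track:
    """One cell's centroid positions over time.

    Parameters
    ----------
    track_id:
        Identifier of the tracked cell.
    t:
        Strictly increasing timestamps in minutes, shape ``(n,)``.
    xy:
        Positions in microns, shape ``(n, 2)``; column 0 is x
        (anterior->posterior), column 1 is y (ventral->dorsal).
    axon_entry_min, drez_contact_min:
        Optional annotated event times (minutes, same axis as ``t``):
        when the DRG pioneer axon entered the spinal cord and when this
        cell first contacted the dorsal root entry zone.
    """

    track_id: str
    t: np.ndarray
    xy: np.ndarray
    axon_entry_min: float | None = None
    drez_contact_min: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.t.ndim != 1 or self.t.size < 1:
            raise ValueError("track needs at least one timestamped point")
        if self.xy.shape != (self.t.size, 2):
            raise ValueError(
                f"xy must have shape (n, 2) matching t; got {self.xy.shape}"
            )
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Elapsed time in minutes (0 for a single point)."""
        return float(self.t[-1] - self.t[0])


@dataclass
class TrackFeatures:
    """Per-track scalar summary used for clustering and reporting."""

    track_id: str
    total_distance: float          # um, sum of step lengths
    n_direction_changes: int
    net_displacement: float        # um, start-to-end straight line
    duration: float                # minutes
    velocity: float                # um/min (NaN for zero duration)

    def as_dict(self) -> dict:
        return {
            "track_id": self.track_id,
            "total_distance": self.total_distance,
            "n_direction_changes": self.n_direction_changes,
            "net_displacement": self.net_displacement,
            "duration": self.duration,
            "velocity": self.velocity,
        }


def path_length(track: Track) -> float:
    """Total distance migrated: sum of Euclidean step lengths, in um."""
    if track.n_points < 2:
        return 0.0
    steps = np.diff(track.xy, axis=0)
    return float(np.sqrt((steps ** 2).sum(axis=1)).sum())


def _merged_steps(xy: np.ndarray, min_step: float) -> np.ndarray:
    """Merge consecutive displacement vectors forward until each retained
    vector reaches ``min_step`` um; a trailing sub-threshold remainder is
    dropped as jitter.  Returns retained vectors, shape (m, 2)."""
    steps = np.diff(xy, axis=0)
    kept: list[np.ndarray] = []
    acc = np.zeros(2)
    for s in steps:
        acc = acc + s
        if float(np.hypot(acc[0], acc[1])) >= min_step:
            kept.append(acc)
            acc = np.zeros(2)
    return np.array(kept) if kept else np.empty((0, 2))


def count_direction_changes(
    track: Track,
    angle_threshold: float = DEFAULT_ANGLE_THRESHOLD,
    min_step: float = DEFAULT_MIN_STEP,
) -> int:
    """Number of turns of at least ``angle_threshold`` degrees.

    Displacement vectors shorter than ``min_step`` are merged forward
    (jitter filter) before turning angles between successive retained
    vectors are evaluated.  An angle exactly at the threshold counts as
    a change.  Tracks with fewer than two retained vectors score 0.
    """
    if not (0.0 < angle_threshold <= 180.0):
        raise ValueError("angle_threshold must lie in (0, 180] degrees")
    if min_step < 0:
        raise ValueError("min_step must be non-negative")
    if track.n_points < 3:
        return 0
    vecs = _merged_steps(track.xy, min_step)
    if len(vecs) < 2:
        return 0
    norms = np.sqrt((vecs ** 2).sum(axis=1))
    dots = (vecs[:-1] * vecs[1:]).sum(axis=1)
    cosang = np.clip(dots / (norms[:-1] * norms[1:]), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))
    # tiny tolerance so right-angle turns trip the default 90 deg threshold
    return int(np.count_nonzero(angles >= angle_threshold - 1e-9))


def velocity(track: Track) -> float:
    """Mean speed along the path: total distance / elapsed time (um/min)."""
    if track.n_points < 2 or track.duration <= 0:
        raise ValueError(
            f"velocity undefined for track {track.track_id!r}: "
            "need at least two time points spanning a positive duration"
        )
    return path_length(track) / track.duration


def contact_delay(track: Track) -> float:
    """Hours between pioneer-axon entry and this cell's DREZ contact."""
    if track.axon_entry_min is None or track.drez_contact_min is None:
        raise ValueError(
            f"track {track.track_id!r} lacks axon_entry/drez_contact annotations"
        )
    delay_min = track.drez_contact_min - track.axon_entry_min
    if delay_min < 0:
        raise ValueError(
            f"track {track.track_id!r}: DREZ contact precedes axon entry "
            f"({delay_min:g} min); inconsistent annotations"
        )
    return delay_min / 60.0


def dorsal_displacement_after_contact(track: Track) -> float:
    """Dorsal (``+y``) displacement from DREZ contact to the track end, um.

    The position at contact is taken from the nearest sample at or after
    the annotated contact time.
    """
    if track.drez_contact_min is None:
        raise ValueError(f"track {track.track_id!r} lacks a drez_contact annotation")
    tc = track.drez_contact_min
    if tc < track.t[0] or tc > track.t[-1]:
        raise ValueError(
            f"track {track.track_id!r}: contact time {tc:g} min outside the "
            f"track span [{track.t[0]:g}, {track.t[-1]:g}]"
        )
    idx = int(np.searchsorted(track.t, tc, side="left"))
    return float(track.xy[-1, 1] - track.xy[idx, 1])


def migration_plot_table(tracks: list[Track]) -> pd.DataFrame:
    """Overlay table for migration plots: every track translated so its
    first point is the origin.  Long form: track_id, t_min, dx_um, dy_um."""
    rows = []
    for tr in tracks:
        rel = tr.xy - tr.xy[0]
        for ti, (dx, dy) in zip(tr.t, rel):
            rows.append((tr.track_id, float(ti), float(dx), float(dy)))
    return pd.DataFrame(rows, columns=["track_id", "t_min", "dx_um", "dy_um"])


def extract_features(
    track: Track,
    angle_threshold: float = DEFAULT_ANGLE_THRESHOLD,
    min_step: float = DEFAULT_MIN_STEP,
) -> TrackFeatures:
    """Compute the feature vector of one track (distance, turns, net
    displacement, duration, velocity)."""
    total = path_length(track)
    net = float(np.hypot(*(track.xy[-1] - track.xy[0]))) if track.n_points > 1 else 0.0
    dur = track.duration
    vel = total / dur if dur > 0 else math.nan
    return TrackFeatures(
        track_id=track.track_id,
        total_distance=total,
        n_direction_changes=count_direction_changes(track, angle_threshold, min_step),
        net_displacement=net,
        duration=dur,
        velocity=vel,
    )


def features_table(
    tracks: list[Track],
    angle_threshold: float = DEFAULT_ANGLE_THRESHOLD,
    min_step: float = DEFAULT_MIN_STEP,
) -> pd.DataFrame:
    """Feature table with one row per track."""
    return pd.DataFrame(
        [extract_features(tr, angle_threshold, min_step).as_dict() for tr in tracks]
    )


# ---------------------------------------------------------------------------
# tabular I/O  (track CSV: track_id, frame, t_min, x_um, y_um)

def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for frame, (ti, (x, y)) in enumerate(zip(tr.t, tr.xy)):
            rows.append((tr.track_id, frame, float(ti), float(x), float(y)))
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_min", "x_um", "y_um"])


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_min")
        tracks.append(
            Track(str(tid), g["t_min"].to_numpy(), g[["x_um", "y_um"]].to_numpy())
        )
    return tracks


def write_tracks_csv(tracks: list[Track], path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def read_tracks_csv(path) -> list[Track]:
    return tracks_from_frame(pd.read_csv(path))


def apply_annotations(tracks: list[Track], annotations: pd.DataFrame) -> list[Track]:
    """Attach event times from an annotation table (track_id,
    axon_entry_min, drez_contact_min) to matching tracks, in place."""
    byid = {tr.track_id: tr for tr in tracks}
    for _, row in annotations.iterrows():
        tr = byid.get(str(row["track_id"]))
        if tr is None:
            continue
        if "axon_entry_min" in row and pd.notna(row["axon_entry_min"]):
            tr.axon_entry_min = float(row["axon_entry_min"])
        if "drez_contact_min" in row and pd.notna(row["drez_contact_min"]):
            tr.drez_contact_min = float(row["drez_contact_min"])
    return tracks
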