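"""Calcium-transient event calling on integrated-density traces.

GCaMP6s fluorescence of a cell or projection is summarized per frame as
the integrated density inside a traced ROI.  Each trace is converted to
Z-scores against its own whole-trace mean and sample standard deviation,
and every maximal run of samples with Z at or above the threshold
(default 2) is called one active-firing event.  A cell is "active" if it
has at least one event.  Traces recorded around a stimulus (e.g. the
addition of 4 deg C water) can have their events split into pre- and
post-stimulus counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceTrace",
    "EventCallResult",
    "zscore_trace",
    "is_degenerate",
    "call_events",
    "analyze_trace",
    "epoch_event_counts",
    "percent_active",
    "activity_heatmap",
    "traces_from_frame",
    "traces_to_frame",
    "events_to_frame",
]

#: Z-score at or above which a sample is part of an active firing event
DEFAULT_Z_THRESHOLD = 2.0


@dataclass
class FluorescenceTrace:
    """Integrated-density time series for one ROI/cell.

    ``times`` are in seconds (uniform 2 s spacing in the reference
    protocol), ``values`` in arbitrary intensity units.  ``stimulus_time``
    (seconds, optional) marks when the stimulus was applied.
    """

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    animal_id: str | None = None
    cell_class: str | None = None  # drg_neuron | sensory_olc | nonsensory_olc
    stimulus_time: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.times.size


@dataclass
class EventCallResult:
    """Z-series plus called events for one trace.

    ``events`` holds ``(start, end, peak_z)`` with inclusive sample
    indices; events are disjoint and ordered.  ``degenerate`` marks a
    zero-variance trace (all-zero Z-series, no events).
    """

    cell_id: str | None
    z_series: np.ndarray
    events: list[tuple[int, int, float]] = field(default_factory=list)
    n_peaks: int = 0
    is_active: bool = False
    degenerate: bool = False
    epoch_counts: tuple[int, int] | None = None


def zscore_trace(trace: FluorescenceTrace | np.ndarray) -> np.ndarray:
    """Z-score a trace against its own mean and sample SD (ddof=1).

    A zero-variance trace yields an all-zero Z-series (degenerate case:
    constant fluorescence carries no events).  Requires >= 2 samples.
    """
    values = trace.values if isinstance(trace, FluorescenceTrace) else np.asarray(trace, float)
    if values.size < 2:
        raise ValueError("Z-scoring requires at least two samples")
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def is_degenerate(trace: FluorescenceTrace | np.ndarray) -> bool:
    """True when the raw trace has zero sample variance."""
    values = trace.values if isinstance(trace, FluorescenceTrace) else np.asarray(trace, float)
    return bool(values.std(ddof=1) == 0.0)


def _runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as inclusive (start, end) index pairs."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def call_events(
    z_series: np.ndarray,
    threshold: float = DEFAULT_Z_THRESHOLD,
    min_gap_samples: int = 1,
    cell_id: str | None = None,
) -> EventCallResult:
    """Call active-firing events on a Z-series.

    Each maximal run of consecutive samples with ``z >= threshold`` is one
    event ("peak"); runs separated by fewer than ``min_gap_samples``
    sub-threshold samples are merged into one event.  The threshold is
    inclusive, matching the "Z score of 2 or greater" rule.
    """
    z = np.asarray(z_series, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z_series contains non-finite values")
    if min_gap_samples < 1:
        raise ValueError("min_gap_samples must be >= 1")
    runs = _runs(z >= threshold)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < min_gap_samples:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = [(s, e, float(z[s : e + 1].max())) for s, e in merged]
    return EventCallResult(
        cell_id=cell_id,
        z_series=z,
        events=events,
        n_peaks=len(events),
        is_active=len(events) >= 1,
    )


def analyze_trace(
    trace: FluorescenceTrace,
    threshold: float = DEFAULT_Z_THRESHOLD,
    min_gap_samples: int = 1,
) -> EventCallResult:
    """Z-score a trace and call its events in one step."""
    z = zscore_trace(trace)
    result = call_events(z, threshold, min_gap_samples, cell_id=trace.cell_id)
    result.degenerate = is_degenerate(trace)
    return result


def epoch_event_counts(
    result: EventCallResult, trace: FluorescenceTrace
) -> tuple[int, int]:
    """Split called events into (pre, post) stimulus counts.

    An event belongs to the epoch of its peak sample's time (first
    maximal sample on ties).  A stimulus before the trace start puts all
    events in the post epoch.  Counts always sum to ``n_peaks``.
    """
    if trace.stimulus_time is None:
        raise ValueError(f"trace {trace.cell_id!r} has no stimulus_time")
    pre = post = 0
    for s, e, _ in result.events:
        peak_idx = s + int(np.argmax(result.z_series[s : e + 1]))
        if trace.times[peak_idx] < trace.stimulus_time:
            pre += 1
        else:
            post += 1
    result.epoch_counts = (pre, post)
    return pre, post


def percent_active(
    results: list[EventCallResult], animal_ids: list[str]
) -> tuple[pd.Series, float]:
    """Percentage of active cells per animal, plus the across-animal mean.

    ``animal_ids`` is aligned with ``results`` (one entry per cell).
    """
    if len(results) != len(animal_ids):
        raise ValueError("results and animal_ids must have equal length")
    if len(results) == 0:
        raise ValueError("no cells supplied")
    df = pd.DataFrame(
        {
            "animal_id": [str(a) for a in animal_ids],
            "active": [bool(r.is_active) for r in results],
        }
    )
    per_animal = df.groupby("animal_id", sort=True)["active"].mean() * 100.0
    per_animal.name = "percent_active"
    return per_animal, float(per_animal.mean())


def activity_heatmap(
    results: list[EventCallResult], truncate_to_shortest: bool = False
) -> pd.DataFrame:
    """Cells x timepoints matrix of Z-scores, rows ordered by cell_id.

    Ragged Z-series lengths raise unless ``truncate_to_shortest`` is set.
    """
    if not results:
        raise ValueError("no traces supplied")
    lengths = {len(r.z_series) for r in results}
    if len(lengths) > 1 and not truncate_to_shortest:
        raise ValueError(
            f"Z-series lengths differ ({sorted(lengths)}); "
            "pass truncate_to_shortest=True to align them"
        )
    n = min(lengths)
    ordered = sorted(results, key=lambda r: str(r.cell_id))
    mat = np.vstack([r.z_series[:n] for r in ordered])
    return pd.DataFrame(mat, index=[str(r.cell_id) for r in ordered],
                        columns=np.arange(n))


# ---------------------------------------------------------------------------
# tabular I/O  (trace CSV: cell_id, animal_id, cell_class, t_s, intensity)

def traces_to_frame(traces: list[FluorescenceTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for ti, vi in zip(tr.times, tr.values):
            rows.append(
                (tr.cell_id, tr.animal_id, tr.cell_class, float(ti), float(vi),
                 tr.stimulus_time)
            )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "animal_id", "cell_class", "t_s", "intensity",
                 "stimulus_t_s"],
    )


def traces_from_frame(df: pd.DataFrame) -> list[FluorescenceTrace]:
    traces = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("t_s")
        first = g.iloc[0]
        stim = first.get("stimulus_t_s")
        traces.append(
            FluorescenceTrace(
                cell_id=str(cid),
                times=g["t_s"].to_numpy(),
                values=g["intensity"].to_numpy(),
                animal_id=None if pd.isna(first.get("animal_id")) else str(first["animal_id"]),
                cell_class=None if pd.isna(first.get("cell_class")) else str(first["cell_class"]),
                stimulus_time=None if stim is None or pd.isna(stim) else float(stim),
            )
        )
    return traces


def events_to_frame(results: list[EventCallResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for s, e, pz in r.events:
            rows.append((r.cell_id, s, e, pz))
    return pd.DataFrame(rows, columns=["cell_id", "start", "end", "peak_z"])
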