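"""Cold-induced shiver scoring and tactile-response summaries.

Larvae immersed in 4 deg C water show a stereotyped high-frequency
shiver.  Each recording is normalized to a 20 s window and scored as
the fraction of time spent shivering: total shiver time / total time
recorded.  The original scoring was done by eye; here an explicit
detector stands in for the rater: high-pass filter the displacement (or
body-angle) signal to isolate the rapid twitch component, compute a
sliding-window RMS envelope, and mark samples where the envelope
reaches an amplitude threshold.  All three detector parameters are
exposed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d
from scipy.stats import ttest_ind

__all__ = [
    "BehaviorTrace",
    "ShiverScore",
    "normalize_window",
    "detect_shiver",
    "group_behavior_summary",
    "tactile_response_rate",
]

#: scoring window in seconds ("movies longer than 20 s were normalized to 20 s")
DEFAULT_WINDOW_S = 20.0
#: high-pass cutoff (Hz) separating shiver from slow swim undulation
DEFAULT_HP_CUTOFF = 5.0
#: sliding RMS window (s)
DEFAULT_RMS_WINDOW = 0.5
#: RMS amplitude threshold (signal units) marking shiver; set to
#: 1/sqrt(2) of a unit-amplitude tone's RMS so the envelope crosses the
#: threshold exactly at a burst edge (unbiased duration estimate)
DEFAULT_AMP_THRESHOLD = 0.5


@dataclass
class BehaviorTrace:
    """Uniformly sampled displacement/body-angle series for one animal."""

    animal_id: str
    times: np.ndarray    # seconds
    signal: np.ndarray   # displacement or angle, arbitrary units
    group: str = "other"  # intact | ablation_control | sensory_olc_ablated | other

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape or self.times.ndim != 1:
            raise ValueError("times and signal must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("behavior trace needs at least two samples")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise ValueError("behavior trace must be uniformly sampled")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_samples / sample_rate)."""
        return self.times.size / self.sample_rate


@dataclass
class ShiverScore:
    """Per-animal shiver verdict: boolean per-sample mask and the
    fraction of the analyzed window spent shivering."""

    animal_id: str
    shiver_mask: np.ndarray
    shiver_fraction: float
    analyzed_duration: float  # seconds


def normalize_window(trace: BehaviorTrace, window: float = DEFAULT_WINDOW_S) -> BehaviorTrace:
    """Truncate a recording to its first ``window`` seconds.

    Shorter recordings pass through unchanged with a warning.
    """
    if trace.duration > window:
        n = int(round(window * trace.sample_rate))
        return BehaviorTrace(
            animal_id=trace.animal_id,
            times=trace.times[:n],
            signal=trace.signal[:n],
            group=trace.group,
        )
    if trace.duration < window:
        warnings.warn(
            f"trace {trace.animal_id!r} is shorter ({trace.duration:g} s) than "
            f"the {window:g} s scoring window; using it as is",
            stacklevel=2,
        )
    return trace


def detect_shiver(
    trace: BehaviorTrace,
    hp_cutoff: float = DEFAULT_HP_CUTOFF,
    window: float = DEFAULT_RMS_WINDOW,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
) -> ShiverScore:
    """Mark shiver samples by thresholding the high-pass RMS envelope.

    The signal is zero-phase high-pass filtered at ``hp_cutoff`` Hz
    (4th-order Butterworth), squared and averaged over a centered
    ``window``-second sliding window; samples whose RMS reaches
    ``amp_threshold`` count as shivering.  The default threshold is
    half the power of a unit-amplitude shiver tone, so the envelope
    crossing sits on the burst edge and durations are unbiased.
    """
    fs = trace.sample_rate
    if fs <= 2.0 * hp_cutoff:
        raise ValueError(
            f"sample rate {fs:g} Hz too low for a {hp_cutoff:g} Hz high-pass "
            "(need fs > 2 x cutoff)"
        )
    sos = sps.butter(4, hp_cutoff, btype="highpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.signal)
    n_win = max(1, int(round(window * fs)))
    power = uniform_filter1d(filtered ** 2, size=n_win, mode="nearest")
    rms = np.sqrt(np.clip(power, 0.0, None))  # guard tiny negative rounding
    mask = rms >= amp_threshold
    return ShiverScore(
        animal_id=trace.animal_id,
        shiver_mask=mask,
        shiver_fraction=float(mask.mean()),
        analyzed_duration=trace.duration,
    )


def group_behavior_summary(
    scores: list[ShiverScore], groups: list[str]
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-group mean percent time shivering plus pairwise Welch tests.

    ``groups`` is aligned with ``scores``.  Every group must contain at
    least two animals for the pairwise comparisons.
    """
    if len(scores) != len(groups):
        raise ValueError("scores and groups must have equal length")
    if not scores:
        raise ValueError("no scores supplied")
    df = pd.DataFrame(
        {
            "group": [str(g) for g in groups],
            "percent": [100.0 * s.shiver_fraction for s in scores],
        }
    )
    counts = df.groupby("group")["percent"].size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than two animals: {small}")
    means = df.groupby("group", sort=True)["percent"].mean()
    means.name = "mean_percent_shivering"
    rows = []
    for ga, gb in itertools.combinations(sorted(counts.index), 2):
        a = df.loc[df["group"] == ga, "percent"].to_numpy()
        b = df.loc[df["group"] == gb, "percent"].to_numpy()
        t, p = ttest_ind(a, b, equal_var=False)
        rows.append((ga, gb, float(t), float(p)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p"])
    return means, pairwise


def tactile_response_rate(outcomes: pd.DataFrame) -> pd.Series:
    """Percentage of responders per group from a per-animal outcome table
    with columns ``animal_id``, ``group``, ``responded`` (0/1)."""
    if outcomes.empty:
        raise ValueError("no outcomes supplied")
    rate = outcomes.groupby("group", sort=True)["responded"].mean() * 100.0
    rate.name = "percent_responding"
    return rate
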