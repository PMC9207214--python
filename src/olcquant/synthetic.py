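"""Seeded synthetic data with known ground truth for every pipeline stage.

The study's raw movies are not deposited, so each analysis stage ships
with a generator that emulates the statistical structure the stage
assumes:

* **Tracks** — three-group migration structure (short/direct,
  short/wandering, long/wandering cells).  A track is built as a
  polyline of equal-length waypoint steps with exactly the configured
  total path length and number of super-threshold turns, then isotropic
  Gaussian positional jitter is added.  At zero jitter the extracted
  features equal the configured targets exactly.
* **Traces** — baseline plus bounded noise plus instantaneous-rise /
  exponential-decay transients at configured sample indices.
* **Image stacks** — a Gaussian blob moving along a configured path
  over a flat background, with per-frame analytic ROI truth.
* **Behavior** — pure-tone shiver bursts inside configured intervals
  over Gaussian noise.
* **Sheath tables** — per-class and per-day Gaussian sheath
  length/width measurements for the morphometry statistics.

All randomness flows from a per-call seed; no global random state is
touched, and equal seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BehaviorTrace
from .calcium import FluorescenceTrace
from .roi import ImageStack, RoiSpec, rasterize_roi
from .tracks import Track

__all__ = [
    "TrackSimConfig",
    "TraceSimConfig",
    "BehaviorSimConfig",
    "generate_tracks",
    "generate_traces",
    "generate_image_stack",
    "generate_behavior",
    "generate_sheath_groups",
    "generate_sheath_timecourse",
]


# ---------------------------------------------------------------------------
# migration tracks

def _default_cluster_specs() -> list[tuple[float, int, float]]:
    # (target path length um, target direction changes, positional jitter um)
    # mirroring the three observed migration groups: short & direct,
    # similar distance but wandering, and long-range wandering cells
    return [(75.0, 1, 2.0), (90.0, 4, 2.0), (250.0, 5, 2.0)]


@dataclass
class TrackSimConfig:
    """Configuration of the migration-track generator.

    Each entry of ``cluster_specs`` is ``(target_path_length_um,
    target_direction_changes, positional_noise_sd_um)``.  Tracks are
    waypoint polylines of ``n_frames`` points at ``frame_interval``
    minutes; turns of ``turn_angle_deg`` (default 150, comfortably above
    the 90 deg counting threshold) are placed at evenly spaced step
    boundaries.
    """

    n_per_cluster: int = 7
    cluster_specs: list[tuple[float, int, float]] = field(
        default_factory=_default_cluster_specs
    )
    frame_interval: float = 5.0   # minutes between frames
    n_frames: int = 11            # waypoints per track
    turn_angle_deg: float = 150.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_cluster < 1:
            raise ValueError("n_per_cluster must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        for spec in self.cluster_specs:
            length, changes, noise = spec
            if length <= 0:
                raise ValueError("target path length must be positive")
            if changes < 0:
                raise ValueError("target direction changes must be >= 0")
            if noise < 0:
                raise ValueError("positional_noise_sd must be >= 0")
            if self.n_frames - 1 < changes + 1:
                raise ValueError(
                    f"{changes} direction changes need at least {changes + 2} "
                    f"frames; got n_frames={self.n_frames}"
                )


def _build_polyline(
    length: float,
    n_changes: int,
    n_steps: int,
    turn_angle: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Waypoints of a polyline with ``n_steps`` equal steps summing to
    ``length`` and exactly ``n_changes`` turns of ``turn_angle`` degrees
    placed at evenly spread step boundaries."""
    step_len = length / n_steps
    n_segments = n_changes + 1
    seg_steps = np.full(n_segments, n_steps // n_segments)
    seg_steps[: n_steps % n_segments] += 1
    heading = rng.uniform(0.0, 2.0 * np.pi)
    sign = rng.choice([-1.0, 1.0])
    headings = []
    for seg in range(n_segments):
        headings.extend([heading] * int(seg_steps[seg]))
        heading += sign * np.radians(turn_angle)
        sign = -sign  # alternate turn direction to keep the path compact
    h = np.asarray(headings)
    steps = step_len * np.stack([np.cos(h), np.sin(h)], axis=1)
    pts = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    return pts


def generate_tracks(config: TrackSimConfig) -> tuple[list[Track], list[int]]:
    """Generate one track per simulated cell plus true cluster labels.

    With zero positional noise each track's extracted features equal its
    cluster targets exactly; with noise, features scatter around them.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_frames) * config.frame_interval
    tracks: list[Track] = []
    labels: list[int] = []
    idx = 0
    for ci, (length, changes, noise_sd) in enumerate(config.cluster_specs):
        for _ in range(config.n_per_cluster):
            pts = _build_polyline(
                length, changes, config.n_frames - 1, config.turn_angle_deg, rng
            )
            start = rng.uniform([0.0, 0.0], [200.0, 100.0])
            pts = pts + start
            if noise_sd > 0:
                pts = pts + rng.normal(0.0, noise_sd, pts.shape)
            tracks.append(Track(track_id=f"track{idx:03d}", t=t.copy(), xy=pts))
            labels.append(ci)
            idx += 1
    return tracks, labels


# ---------------------------------------------------------------------------
# fluorescence traces

@dataclass
class TraceSimConfig:
    """Configuration of the integrated-density trace generator.

    ``event_times`` lists, per cell, the sample indices at which a
    transient starts (``None`` means no events anywhere).  Transients
    rise instantaneously by ``event_amplitude`` and decay exponentially
    with time constant ``event_decay`` samples.  Baseline noise is
    bounded by default ("bounded": arcsine-distributed with the
    requested SD, hard amplitude bound sqrt(2) x SD): the Z >= 2 calling
    rule presumes baseline fluctuation stays below threshold, which
    unbounded Gaussian tails violate by construction.  ``"uniform"``
    (bound sqrt(3) x SD) and ``"gaussian"`` are available for
    sensitivity studies.
    """

    n_cells: int = 10
    n_samples: int = 60           # 2 min at 2 s sampling
    sample_interval: float = 2.0  # seconds
    baseline: float = 100.0       # arbitrary intensity units
    noise_sd: float = 5.0
    event_times: list[list[int]] | None = None
    event_amplitude: float = 30.0  # 6 x default noise SD
    event_decay: float = 5.0       # samples
    stimulus_index: int | None = None
    noise_dist: str = "bounded"    # bounded (arcsine) | uniform | gaussian
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1 or self.n_samples < 2:
            raise ValueError("need n_cells >= 1 and n_samples >= 2")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.event_amplitude < 0:
            raise ValueError("event_amplitude must be >= 0")
        if self.event_decay <= 0:
            raise ValueError("event_decay must be positive")
        if self.noise_dist not in ("bounded", "uniform", "gaussian"):
            raise ValueError(f"unknown noise_dist {self.noise_dist!r}")
        if self.event_times is not None:
            if len(self.event_times) != self.n_cells:
                raise ValueError("event_times must list one entry per cell")
            for cell_events in self.event_times:
                for e in cell_events:
                    if not (0 <= e < self.n_samples):
                        raise ValueError(
                            f"event index {e} outside [0, {self.n_samples})"
                        )
        if self.stimulus_index is not None and not (
            0 <= self.stimulus_index < self.n_samples
        ):
            raise ValueError("stimulus_index outside the trace")


def _transient(n: int, start: int, amplitude: float, decay: float) -> np.ndarray:
    k = np.arange(n)
    out = np.zeros(n)
    tail = k >= start
    out[tail] = amplitude * np.exp(-(k[tail] - start) / decay)
    return out


def generate_traces(
    config: TraceSimConfig,
) -> tuple[list[FluorescenceTrace], list[list[int]]]:
    """Generate traces = baseline + noise + summed transients, plus the
    per-cell ground-truth event start indices."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    times = np.arange(config.n_samples) * config.sample_interval
    stim = (
        None
        if config.stimulus_index is None
        else config.stimulus_index * config.sample_interval
    )
    events = config.event_times or [[] for _ in range(config.n_cells)]
    traces: list[FluorescenceTrace] = []
    truth: list[list[int]] = []
    for ci in range(config.n_cells):
        if config.noise_dist == "bounded":
            # arcsine-distributed: exact SD = noise_sd, hard bound sqrt(2)*SD
            phase = rng.uniform(0.0, 2.0 * np.pi, config.n_samples)
            noise = np.sqrt(2.0) * config.noise_sd * np.sin(phase)
        elif config.noise_dist == "uniform":
            half = np.sqrt(3.0) * config.noise_sd
            noise = rng.uniform(-half, half, config.n_samples)
        else:
            noise = rng.normal(0.0, config.noise_sd, config.n_samples)
        values = config.baseline + noise
        for e in events[ci]:
            values = values + _transient(
                config.n_samples, int(e), config.event_amplitude, config.event_decay
            )
        traces.append(
            FluorescenceTrace(
                cell_id=f"cell{ci:03d}",
                times=times.copy(),
                values=values,
                stimulus_time=stim,
            )
        )
        truth.append(sorted(int(e) for e in events[ci]))
    return traces, truth


# ---------------------------------------------------------------------------
# image stacks

def generate_image_stack(
    n_frames: int,
    height: int,
    width: int,
    blob_path: list[tuple[float, float]],
    blob_amplitude: float,
    background_level: float,
    seed: int = 0,
    blob_sigma: float = 1.5,
    noise_sd: float = 0.0,
    roi: RoiSpec | None = None,
    frame_interval: float = 1.0,
) -> tuple[ImageStack, np.ndarray | None]:
    """Render a Gaussian blob moving along ``blob_path`` over a flat
    background and return the stack plus, if ``roi`` is given, the
    per-frame integrated density of the noise-free render inside it.

    ``blob_path`` holds one ``(row, col)`` center per frame (a single
    center is reused for all frames).  Centers must lie inside the frame.
    """
    if n_frames < 1 or height < 1 or width < 1:
        raise ValueError("need n_frames, height, width >= 1")
    if blob_amplitude < 0 or background_level < 0 or noise_sd < 0:
        raise ValueError("amplitude, background and noise must be >= 0")
    centers = np.asarray(blob_path, dtype=float)
    if centers.ndim == 1:
        centers = centers[None, :]
    if len(centers) == 1:
        centers = np.repeat(centers, n_frames, axis=0)
    if centers.shape != (n_frames, 2):
        raise ValueError("blob_path must give one (row, col) center per frame")
    if (
        (centers[:, 0] < 0).any()
        or (centers[:, 0] > height - 1).any()
        or (centers[:, 1] < 0).any()
        or (centers[:, 1] > width - 1).any()
    ):
        raise ValueError("blob centers must lie inside the frame")
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(height, dtype=float),
                         np.arange(width, dtype=float), indexing="ij")
    clean = np.empty((n_frames, height, width))
    for f, (cr, ccol) in enumerate(centers):
        blob = blob_amplitude * np.exp(
            -((rr - cr) ** 2 + (cc - ccol) ** 2) / (2.0 * blob_sigma ** 2)
        )
        clean[f] = background_level + blob
    pixels = clean if noise_sd == 0 else clean + rng.normal(0, noise_sd, clean.shape)
    pixels = np.clip(pixels, 0.0, None)
    stack = ImageStack(
        pixels=pixels, frame_times=np.arange(n_frames) * float(frame_interval)
    )
    truth = None
    if roi is not None:
        mask = rasterize_roi(roi, height, width)
        truth = clean[:, mask].sum(axis=1)
    return stack, truth


# ---------------------------------------------------------------------------
# behavior

@dataclass
class BehaviorSimConfig:
    """Configuration of the shiver-behavior generator.

    ``shiver_intervals`` are non-overlapping ``(start, end)`` windows in
    seconds within ``[0, duration]`` during which a pure tone at
    ``shiver_frequency`` (well above the detector's 5 Hz high-pass) is
    emitted; outside them the signal is Gaussian noise only.
    """

    duration: float = 20.0        # seconds (cold-water scoring window)
    sample_rate: float = 100.0    # Hz
    shiver_intervals: list[tuple[float, float]] = field(default_factory=list)
    shiver_frequency: float = 15.0  # Hz
    shiver_amplitude: float = 1.0   # displacement units
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ValueError("duration and sample_rate must be positive")
        if self.noise_sd < 0 or self.shiver_amplitude < 0:
            raise ValueError("noise_sd and shiver_amplitude must be >= 0")
        prev_end = -np.inf
        for start, end in sorted(self.shiver_intervals):
            if not (0.0 <= start < end <= self.duration):
                raise ValueError(
                    f"interval ({start}, {end}) outside [0, {self.duration}]"
                )
            if start < prev_end:
                raise ValueError("shiver intervals must not overlap")
            prev_end = end


def generate_behavior(
    config: BehaviorSimConfig, animal_id: str = "sim", group: str = "other"
) -> tuple[BehaviorTrace, float]:
    """Generate a displacement trace with tone bursts in the configured
    intervals, plus the true shiver fraction (total burst time /
    duration)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    sig = (
        rng.normal(0.0, config.noise_sd, n)
        if config.noise_sd > 0
        else np.zeros(n)
    )
    for start, end in config.shiver_intervals:
        m = (t >= start) & (t < end)
        sig[m] += config.shiver_amplitude * np.sin(
            2.0 * np.pi * config.shiver_frequency * (t[m] - start)
        )
    true_fraction = sum(e - s for s, e in config.shiver_intervals) / config.duration
    return BehaviorTrace(animal_id=animal_id, times=t, signal=sig, group=group), float(
        true_fraction
    )


# ---------------------------------------------------------------------------
# sheath measurement tables

def generate_sheath_groups(
    n_sensory: int = 12,
    n_nonsensory: int = 11,
    mean_length: tuple[float, float] = (187.78, 94.67),
    sd_length: tuple[float, float] = (52.65, 32.77),
    mean_width: tuple[float, float] = (5.01, 7.49),
    sd_width: tuple[float, float] = (0.80, 1.36),
    sheaths_per_cell: int = 3,
    within_cell_cv: float = 0.10,
    day: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Sheath table for a sensory vs non-sensory class comparison.

    Per-cell mean lengths/widths are drawn from class Gaussians
    (defaults reproduce the reported class magnitudes: sensory sheaths
    long and thin, non-sensory short and wide; SDs are the reported
    SEMs scaled by sqrt(n)); each cell then contributes
    ``sheaths_per_cell`` measurements with ``within_cell_cv`` relative
    scatter.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n_cells, ml, sl, mw, sw in (
        ("sensory_olc", n_sensory, mean_length[0], sd_length[0],
         mean_width[0], sd_width[0]),
        ("nonsensory_olc", n_nonsensory, mean_length[1], sd_length[1],
         mean_width[1], sd_width[1]),
    ):
        for ci in range(n_cells):
            cell_len = max(rng.normal(ml, sl), 1.0)
            cell_wid = max(rng.normal(mw, sw), 0.2)
            for si in range(sheaths_per_cell):
                rows.append(
                    {
                        "fish_id": f"{cls[:1]}fish{ci:02d}",
                        "cell_id": f"{cls[:1]}cell{ci:02d}",
                        "cell_class": cls,
                        "day": day,
                        "sheath_id": f"s{si}",
                        "length_um": max(
                            rng.normal(cell_len, within_cell_cv * cell_len), 0.5
                        ),
                        "width_um": max(
                            rng.normal(cell_wid, within_cell_cv * cell_wid), 0.1
                        ),
                    }
                )
    return pd.DataFrame(rows)


def generate_sheath_timecourse(
    fish_id: str = "fish01",
    days: tuple[int, ...] = (3, 4, 5, 6),
    n_sheaths_per_day: int = 4,
    mean_length: float = 187.78,
    sd_length: float = 20.0,
    mean_width: float = 5.01,
    sd_width: float = 0.5,
    day_length_shift: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sheath table for one fish followed across days.

    With ``day_length_shift = 0`` (default) day means are equal, i.e.
    the stable-sheath null used for calibration; a non-zero shift adds
    that many um per day to the length mean.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for di, day in enumerate(days):
        for si in range(n_sheaths_per_day):
            rows.append(
                {
                    "fish_id": fish_id,
                    "cell_id": f"{fish_id}_cell0",
                    "cell_class": "sensory_olc",
                    "day": int(day),
                    "sheath_id": f"d{day}s{si}",
                    "length_um": max(
                        rng.normal(mean_length + di * day_length_shift, sd_length), 0.5
                    ),
                    "width_um": max(rng.normal(mean_width, sd_width), 0.1),
                }
            )
    return pd.DataFrame(rows)
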