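"""End-to-end orchestration: simulate -> measure -> features -> cluster ->
calcium -> morphometry -> behavior, driven by a single config.

Every run writes per-stage CSVs plus the fully resolved configuration
(YAML) next to the outputs for provenance; identical config + seed give
byte-identical outputs.  Stages read only their declared inputs, so
they can be toggled and re-run independently.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import behavior as beh
from . import calcium as cal
from . import clustering as clu
from . import morphometry as mor
from . import synthetic as syn
from . import tracks as trk

__all__ = ["PipelineConfig", "run", "ALL_STAGES"]

ALL_STAGES = (
    "simulate",
    "features",
    "cluster",
    "calcium",
    "morphometry",
    "behavior",
)

logger = logging.getLogger("olcquant.pipeline")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


def _default_behavior_groups() -> dict[str, float]:
    # per-group true shiver fractions used by the simulate stage
    return {
        "intact": 0.575,
        "ablation_control": 0.5375,
        "sensory_olc_ablated": 0.025,
    }


@dataclass
class PipelineConfig:
    """All stage toggles and parameters, with recorded defaults.

    Round-trips losslessly through YAML via :meth:`to_yaml` /
    :meth:`from_yaml`.
    """

    out_dir: str = "olcquant_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    # simulate
    tracks: syn.TrackSimConfig = field(default_factory=syn.TrackSimConfig)
    traces: syn.TraceSimConfig = field(default_factory=syn.TraceSimConfig)
    behavior_sim: syn.BehaviorSimConfig = field(default_factory=syn.BehaviorSimConfig)
    behavior_groups: dict[str, float] = field(default_factory=_default_behavior_groups)
    n_behavior_per_group: int = 4
    n_trace_animals: int = 5

    # features
    angle_threshold: float = 90.0   # degrees
    min_step: float = 2.0           # um jitter filter

    # cluster
    k_max: int = 8
    n_restarts: int = 20
    standardize: bool = True
    elbow_method: str = "knee"

    # calcium
    z_threshold: float = 2.0
    min_gap_samples: int = 1

    # behavior scoring
    window_s: float = 20.0
    hp_cutoff: float = 5.0
    rms_window: float = 0.5
    amp_threshold: float = 0.5

    def to_yaml(self, path=None) -> str:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        text = yaml.safe_dump(_plain(dataclasses.asdict(self)), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        try:
            is_file = Path(source).exists()
        except OSError:
            is_file = False
        text = Path(source).read_text() if is_file else str(source)
        obj = yaml.safe_load(text)
        return cls.from_dict(obj)

    @classmethod
    def from_dict(cls, obj: dict) -> "PipelineConfig":
        obj = dict(obj)
        for key, sub_cls in (
            ("tracks", syn.TrackSimConfig),
            ("traces", syn.TraceSimConfig),
            ("behavior_sim", syn.BehaviorSimConfig),
        ):
            if key in obj and isinstance(obj[key], dict):
                obj[key] = sub_cls(**obj[key])
        cfg = cls(**obj)
        # YAML turns tuples into lists; normalize for the generators
        cfg.tracks.cluster_specs = [tuple(s) for s in cfg.tracks.cluster_specs]
        cfg.behavior_sim.shiver_intervals = [
            tuple(i) for i in cfg.behavior_sim.shiver_intervals
        ]
        return cfg


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs input {path.name} (run the simulate stage "
            f"or place the file in {path.parent})"
        )
    return path


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    # migration tracks with ground-truth labels
    tcfg = dataclasses.replace(cfg.tracks, seed=cfg.seed)
    tracks, labels = syn.generate_tracks(tcfg)
    trk.write_tracks_csv(tracks, out / "tracks.csv")
    pd.DataFrame(
        {"track_id": [t.track_id for t in tracks], "true_cluster": labels}
    ).to_csv(out / "true_labels.csv", index=False)

    # calcium traces; default cohort: first half of the cells fire once
    # after the stimulus, the rest stay silent
    ccfg = dataclasses.replace(cfg.traces, seed=cfg.seed + 1)
    if ccfg.event_times is None:
        stim = ccfg.stimulus_index if ccfg.stimulus_index is not None else 30
        ccfg.stimulus_index = stim
        onset = min(stim + 5, ccfg.n_samples - 1)
        ccfg.event_times = [
            [onset] if ci < ccfg.n_cells // 2 else [] for ci in range(ccfg.n_cells)
        ]
    traces, truth = syn.generate_traces(ccfg)
    for ci, tr in enumerate(traces):
        tr.animal_id = f"animal{ci % cfg.n_trace_animals}"
    cal.traces_to_frame(traces).to_csv(out / "traces.csv", index=False)
    pd.DataFrame(
        {
            "cell_id": [tr.cell_id for tr in traces],
            "true_event_starts": [";".join(map(str, ev)) for ev in truth],
        }
    ).to_csv(out / "trace_truth.csv", index=False)

    # behavior cohort: one trace per animal with a group-specific burst
    rows, truth_rows = [], []
    bi = 0
    for group, frac in cfg.behavior_groups.items():
        for ai in range(cfg.n_behavior_per_group):
            dur = cfg.behavior_sim.duration
            intervals = [(2.0, 2.0 + frac * dur)] if frac > 0 else []
            bcfg = dataclasses.replace(
                cfg.behavior_sim,
                shiver_intervals=intervals,
                seed=cfg.seed + 100 + bi,
            )
            trace, true_frac = syn.generate_behavior(
                bcfg, animal_id=f"{group}_{ai}", group=group
            )
            for ti, si in zip(trace.times, trace.signal):
                rows.append((trace.animal_id, group, float(ti), float(si)))
            truth_rows.append((trace.animal_id, group, true_frac))
            bi += 1
    pd.DataFrame(rows, columns=["animal_id", "group", "t_s", "signal"]).to_csv(
        out / "behavior.csv", index=False
    )
    pd.DataFrame(
        truth_rows, columns=["animal_id", "group", "true_fraction"]
    ).to_csv(out / "behavior_truth.csv", index=False)

    # sheath tables for the morphometry statistics
    syn.generate_sheath_groups(seed=cfg.seed + 200).to_csv(
        out / "sheaths.csv", index=False
    )
    pd.concat(
        [
            syn.generate_sheath_timecourse(
                fish_id=f"fish{fi:02d}", seed=cfg.seed + 300 + fi
            )
            for fi in range(6)
        ],
        ignore_index=True,
    ).to_csv(out / "sheath_timecourse.csv", index=False)
    logger.info("[simulate] wrote fixtures to %s", out)


def _stage_features(cfg: PipelineConfig, out: Path) -> None:
    tracks = trk.read_tracks_csv(_require(out / "tracks.csv", "features"))
    feats = trk.features_table(tracks, cfg.angle_threshold, cfg.min_step)
    feats.to_csv(out / "features.csv", index=False)
    logger.info("[features] %d tracks featurized", len(feats))


def _stage_cluster(cfg: PipelineConfig, out: Path) -> None:
    feats = pd.read_csv(_require(out / "features.csv", "cluster"))
    result = clu.elbow_select_k(
        feats,
        k_max=cfg.k_max,
        seed=cfg.seed,
        n_restarts=cfg.n_restarts,
        standardize=cfg.standardize,
        method=cfg.elbow_method,
    )
    result.labels_frame().to_csv(out / "cluster_labels.csv", index=False)
    pd.DataFrame(
        result.centroids, columns=list(clu.FEATURE_COLUMNS)
    ).to_csv(out / "centroids.csv", index=False)
    pd.DataFrame(
        {"k": list(result.wcss_curve), "wcss": list(result.wcss_curve.values())}
    ).to_csv(out / "wcss.csv", index=False)
    logger.info("[cluster] elbow selected k=%d", result.k)


def _stage_calcium(cfg: PipelineConfig, out: Path) -> None:
    traces = cal.traces_from_frame(
        pd.read_csv(_require(out / "traces.csv", "calcium"))
    )
    results = [
        cal.analyze_trace(tr, cfg.z_threshold, cfg.min_gap_samples) for tr in traces
    ]
    cal.events_to_frame(results).to_csv(out / "events.csv", index=False)
    animals = [tr.animal_id or "unknown" for tr in traces]
    per_animal, overall = cal.percent_active(results, animals)
    summary = per_animal.reset_index()
    summary.to_csv(out / "calcium_summary.csv", index=False)
    cal.activity_heatmap(results).to_csv(out / "heatmap.csv")
    logger.info("[calcium] mean percent active across animals: %.1f%%", overall)


def _stage_morphometry(cfg: PipelineConfig, out: Path) -> None:
    sheaths = pd.read_csv(_require(out / "sheaths.csv", "morphometry"))
    rows = []
    for fld in ("length", "width"):
        cmp_ = mor.group_compare(sheaths, field=fld)
        for cls in cmp_.classes:
            rows.append(
                {
                    "field": fld,
                    "cell_class": cls,
                    "mean": cmp_.means[cls],
                    "sem": cmp_.sems[cls],
                    "n_cells": cmp_.n_cells[cls],
                    "t": cmp_.t,
                    "p": cmp_.p,
                }
            )
    pd.DataFrame(rows).to_csv(out / "morpho_group.csv", index=False)

    tc = pd.read_csv(_require(out / "sheath_timecourse.csv", "morphometry"))
    stab_rows = []
    for fid, res in mor.stability_by_fish(tc, field="length").items():
        stab_rows.append(
            {
                "fish_id": fid,
                "field": res.field,
                "F": res.f_statistic,
                "p": res.p,
                "degenerate": res.degenerate,
            }
        )
    pd.DataFrame(stab_rows).to_csv(out / "morpho_stability.csv", index=False)
    logger.info("[morphometry] group comparison + %d fish stability tests", len(stab_rows))


def _stage_behavior(cfg: PipelineConfig, out: Path) -> None:
    df = pd.read_csv(_require(out / "behavior.csv", "behavior"))
    scores, groups = [], []
    for (aid, grp), g in df.groupby(["animal_id", "group"], sort=True):
        trace = beh.BehaviorTrace(
            animal_id=str(aid),
            times=g["t_s"].to_numpy(),
            signal=g["signal"].to_numpy(),
            group=str(grp),
        )
        trace = beh.normalize_window(trace, cfg.window_s)
        scores.append(
            beh.detect_shiver(trace, cfg.hp_cutoff, cfg.rms_window, cfg.amp_threshold)
        )
        groups.append(str(grp))
    pd.DataFrame(
        {
            "animal_id": [s.animal_id for s in scores],
            "group": groups,
            "shiver_fraction": [s.shiver_fraction for s in scores],
        }
    ).to_csv(out / "behavior_scores.csv", index=False)
    means, pairwise = beh.group_behavior_summary(scores, groups)
    means.reset_index().to_csv(out / "behavior_groups.csv", index=False)
    pairwise.to_csv(out / "behavior_pairwise.csv", index=False)
    logger.info("[behavior] scored %d animals", len(scores))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "cluster": _stage_cluster,
    "calcium": _stage_calcium,
    "morphometry": _stage_morphometry,
    "behavior": _stage_behavior,
}


def run(config: PipelineConfig) -> dict[str, Path]:
    """Execute the enabled stages in pipeline order.

    Returns a mapping of output names to paths.  The fully resolved
    config is written to ``config_resolved.yaml`` in the output
    directory before any stage runs.
    """
    unknown = [s for s in config.stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    for stage in ALL_STAGES:
        if stage in config.stages:
            _STAGE_FUNCS[stage](config, out)
    return {p.name: p for p in sorted(out.iterdir())}
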