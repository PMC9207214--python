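import numpy as np
import pytest

from oracles import brute_direction_changes, brute_path_length
from olcquant.calcium import analyze_trace, epoch_event_counts
from olcquant.roi import RoiSpec, measure_integrated_density
from olcquant.synthetic import (
    BehaviorSimConfig,
    TraceSimConfig,
    TrackSimConfig,
    generate_behavior,
    generate_image_stack,
    generate_sheath_groups,
    generate_sheath_timecourse,
    generate_traces,
    generate_tracks,
)
from olcquant.behavior import detect_shiver
from olcquant.tracks import count_direction_changes, path_length, tracks_to_frame, velocity


class TestTrackGenerator:
    def test_zero_noise_reproduces_targets_exactly(self):
        cfg = TrackSimConfig(cluster_specs=[(100.0, 0, 0.0), (50.0, 3, 0.0)],
                             n_per_cluster=4, seed=5)
        tracks, labels = generate_tracks(cfg)
        targets = {0: (100.0, 0), 1: (50.0, 3)}
        for tr, lab in zip(tracks, labels):
            length, changes = targets[lab]
            assert path_length(tr) == pytest.approx(length, abs=1e-9)
            assert count_direction_changes(tr) == changes

    def test_zero_noise_velocity_is_configured_speed(self):
        cfg = TrackSimConfig(cluster_specs=[(50.0, 0, 0.0)], n_per_cluster=1,
                             n_frames=11, frame_interval=5.0, seed=0)
        tracks, _ = generate_tracks(cfg)
        assert velocity(tracks[0]) == pytest.approx(50.0 / 50.0)

    def test_seed_determinism_byte_identical(self):
        cfg = TrackSimConfig(seed=11)
        a = tracks_to_frame(generate_tracks(cfg)[0]).to_csv(index=False)
        b = tracks_to_frame(generate_tracks(TrackSimConfig(seed=11))[0]).to_csv(index=False)
        assert a == b
        c = tracks_to_frame(generate_tracks(TrackSimConfig(seed=12))[0]).to_csv(index=False)
        assert a != c

    def test_noisy_feature_means_near_targets(self):
        # two well-separated groups, jitter 2 um: feature means stay
        # within 3 across-track SDs of the configured targets, with the
        # features recomputed by the independent brute-force featurizer
        cfg = TrackSimConfig(cluster_specs=[(50.0, 1, 2.0), (300.0, 6, 2.0)],
                             n_per_cluster=15, seed=7)
        tracks, labels = generate_tracks(cfg)
        for ci, (length, changes, _) in enumerate(cfg.cluster_specs):
            pts = [tr.xy for tr, lab in zip(tracks, labels) if lab == ci]
            dists = np.array([brute_path_length(p) for p in pts])
            chgs = np.array([brute_direction_changes(p) for p in pts])
            assert abs(dists.mean() - length) <= 3 * dists.std(ddof=1)
            assert abs(chgs.mean() - changes) <= 3 * max(chgs.std(ddof=1), 0.5)

    @pytest.mark.parametrize(
        "cfg",
        [
            TrackSimConfig(n_frames=1),
            TrackSimConfig(n_per_cluster=0),
            TrackSimConfig(frame_interval=0.0),
            TrackSimConfig(cluster_specs=[(100.0, 0, -1.0)]),
            TrackSimConfig(cluster_specs=[(100.0, 12, 0.0)], n_frames=5),
        ],
    )
    def test_invalid_configs_rejected(self, cfg):
        with pytest.raises(ValueError):
            generate_tracks(cfg)


class TestTraceGenerator:
    def test_no_events_means_empty_truth(self):
        traces, truth = generate_traces(TraceSimConfig(n_cells=4, seed=3))
        assert all(t == [] for t in truth)
        assert all(tr.n_samples == 60 for tr in traces)

    def test_large_event_detected_downstream(self):
        cfg = TraceSimConfig(n_cells=1, noise_sd=2.0, event_amplitude=40.0,
                             event_times=[[30]], seed=9)
        traces, truth = generate_traces(cfg)
        result = analyze_trace(traces[0])
        assert result.is_active
        assert any(s <= truth[0][0] <= e for s, e, _ in result.events)

    def test_post_stimulus_only_events_have_empty_pre_epoch(self):
        cfg = TraceSimConfig(n_cells=3, stimulus_index=30,
                             event_times=[[35], [40, 50], [33]], seed=1)
        traces, truth = generate_traces(cfg)
        for tr, ev in zip(traces, truth):
            assert all(e >= cfg.stimulus_index for e in ev)
            pre, post = epoch_event_counts(analyze_trace(tr), tr)
            assert pre == 0

    def test_noise_sd_realized(self):
        traces, _ = generate_traces(TraceSimConfig(n_cells=1, n_samples=2000,
                                                   noise_sd=5.0, seed=2))
        assert traces[0].values.std(ddof=1) == pytest.approx(5.0, rel=0.1)
        # bounded noise never strays beyond sqrt(2) x SD of baseline
        assert np.abs(traces[0].values - 100.0).max() <= np.sqrt(2) * 5.0 + 1e-9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"noise_sd": 0.0},
            {"noise_sd": -1.0},
            {"event_times": [[70]], "n_cells": 1},
            {"event_times": [[0], [1]], "n_cells": 1},
            {"noise_dist": "laplace"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_traces(TraceSimConfig(**kwargs))

    def test_seed_determinism(self):
        a, _ = generate_traces(TraceSimConfig(seed=4))
        b, _ = generate_traces(TraceSimConfig(seed=4))
        np.testing.assert_array_equal(a[0].values, b[0].values)


class TestImageStackGenerator:
    def test_zero_amplitude_gives_background_times_area(self):
        roi = RoiSpec("r", "polygon",
                      [[-0.5, -0.5], [-0.5, 3.5], [3.5, 3.5], [3.5, -0.5]])
        stack, truth = generate_image_stack(
            n_frames=3, height=8, width=8, blob_path=[(4, 4)],
            blob_amplitude=0.0, background_level=2.0, roi=roi, seed=0,
        )
        np.testing.assert_allclose(truth, 2.0 * 16)

    def test_noisy_stack_measured_close_to_analytic_truth(self):
        roi = RoiSpec("r", "polygon",
                      [[1.5, 1.5], [1.5, 8.5], [8.5, 8.5], [8.5, 1.5]])
        stack, truth = generate_image_stack(
            n_frames=5, height=12, width=12, blob_path=[(5, 5)],
            blob_amplitude=50.0, background_level=10.0, blob_sigma=1.5,
            noise_sd=0.5, roi=roi, seed=8,
        )
        measured = measure_integrated_density(stack, roi).values
        area = 49  # 7x7 pixel centers inside
        assert np.all(np.abs(measured - truth) <= 5 * 0.5 * np.sqrt(area))

    def test_blob_off_frame_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            generate_image_stack(2, 5, 5, [(10, 2)], 1.0, 0.0)


class TestBehaviorGenerator:
    def test_no_intervals_zero_fraction(self):
        trace, frac = generate_behavior(BehaviorSimConfig(seed=0))
        assert frac == 0.0
        assert trace.duration == pytest.approx(20.0)

    def test_half_window_interval(self):
        cfg = BehaviorSimConfig(shiver_intervals=[(0.0, 10.0)], seed=0)
        _, frac = generate_behavior(cfg)
        assert frac == pytest.approx(0.5)

    def test_overlapping_intervals_rejected(self):
        cfg = BehaviorSimConfig(shiver_intervals=[(0.0, 10.0), (5.0, 15.0)])
        with pytest.raises(ValueError, match="overlap"):
            generate_behavior(cfg)

    def test_interval_outside_duration_rejected(self):
        cfg = BehaviorSimConfig(shiver_intervals=[(15.0, 25.0)])
        with pytest.raises(ValueError, match="outside"):
            generate_behavior(cfg)

    def test_detector_recovers_noiseless_burst(self):
        cfg = BehaviorSimConfig(shiver_intervals=[(4.0, 14.0)], noise_sd=0.0,
                                seed=6)
        trace, frac = generate_behavior(cfg)
        score = detect_shiver(trace)
        assert abs(score.shiver_fraction - frac) <= 0.05


class TestSheathGenerators:
    def test_group_table_matches_configured_magnitudes(self):
        df = generate_sheath_groups(seed=0)
        per_cell = df.groupby(["cell_class", "cell_id"])["length_um"].mean()
        sens = per_cell.loc["sensory_olc"]
        nons = per_cell.loc["nonsensory_olc"]
        assert len(sens) == 12 and len(nons) == 11
        assert sens.mean() > nons.mean()

    def test_timecourse_has_requested_days(self):
        df = generate_sheath_timecourse(days=(3, 4, 5, 6), n_sheaths_per_day=4,
                                        seed=1)
        assert sorted(df["day"].unique()) == [3, 4, 5, 6]
        assert (df.groupby("day").size() == 4).all()
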