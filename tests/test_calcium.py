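import numpy as np
import pytest

from oracles import brute_event_runs, brute_zscore
from olcquant.calcium import (
    EventCallResult,
    FluorescenceTrace,
    activity_heatmap,
    analyze_trace,
    call_events,
    epoch_event_counts,
    percent_active,
    traces_from_frame,
    traces_to_frame,
    zscore_trace,
)
from olcquant.synthetic import TraceSimConfig, generate_traces


def mk_trace(values, dt=2.0, stimulus_time=None, cell_id="c0"):
    values = np.asarray(values, float)
    return FluorescenceTrace(cell_id=cell_id, times=np.arange(len(values)) * dt,
                             values=values, stimulus_time=stimulus_time)


class TestZScore:
    def test_simple_sequence(self):
        np.testing.assert_allclose(zscore_trace(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0])

    def test_constant_trace_degenerate(self):
        result = analyze_trace(mk_trace([5.0] * 10))
        assert result.degenerate
        assert result.n_peaks == 0 and not result.is_active
        np.testing.assert_array_equal(result.z_series, 0.0)

    def test_matches_two_pass_oracle(self, rng):
        values = rng.normal(50, 7, 60)
        np.testing.assert_allclose(zscore_trace(values), brute_zscore(values),
                                   atol=1e-12)

    def test_mean_zero_sd_one_contract(self, rng):
        for _ in range(10):
            z = zscore_trace(rng.uniform(0, 100, 40))
            assert abs(z.mean()) < 1e-9
            assert abs(z.std(ddof=1) - 1.0) < 1e-9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            zscore_trace(np.array([1.0]))


class TestCallEvents:
    def test_all_subthreshold_inactive(self):
        r = call_events(np.array([0.0, 1.5, -1.0, 1.9]))
        assert r.n_peaks == 0 and not r.is_active and r.events == []

    def test_threshold_is_inclusive(self):
        r = call_events(np.array([0.0, 2.0, 0.0]))
        assert r.n_peaks == 1 and r.is_active
        assert r.events == [(1, 1, 2.0)]

    def test_contiguous_run_is_one_event(self):
        r = call_events(np.array([0, 2.5, 3.0, 2.1, 0, 0, 2.2], dtype=float))
        assert r.n_peaks == 2
        assert r.events[0] == (1, 3, 3.0)
        assert r.events[1][0] == 6

    def test_gap_merging(self):
        z = np.array([3.0, 1.0, 3.0])
        assert call_events(z, min_gap_samples=1).n_peaks == 2
        merged = call_events(z, min_gap_samples=2)
        assert merged.n_peaks == 1
        assert merged.events[0][:2] == (0, 2)

    def test_matches_run_scanner_oracle(self, rng):
        for _ in range(30):
            z = rng.uniform(-4, 4, 80)
            gap = int(rng.integers(1, 4))
            r = call_events(z, min_gap_samples=gap)
            assert [(s, e) for s, e, _ in r.events] == brute_event_runs(z, 2.0, gap)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            call_events(np.array([0.0, np.nan]))

    def test_affine_rescaling_invariance(self, rng):
        values = rng.normal(100, 5, 60)
        values[20:23] += 40
        base = analyze_trace(mk_trace(values))
        scaled = analyze_trace(mk_trace(3.7 * values + 12.0))
        assert [(s, e) for s, e, _ in base.events] == \
            [(s, e) for s, e, _ in scaled.events]
        np.testing.assert_allclose([p for _, _, p in base.events],
                                   [p for _, _, p in scaled.events], atol=1e-9)

    def test_event_samples_all_supra_threshold(self, rng):
        z = rng.uniform(-4, 4, 100)
        r = call_events(z)
        for s, e, peak in r.events:
            assert np.all(z[s:e + 1] >= 2.0)
            assert peak == z[s:e + 1].max()


class TestEpochCounts:
    def test_all_events_before_stimulus(self):
        values = np.zeros(30)
        values[5] = 50.0
        trace = mk_trace(values, stimulus_time=40.0)
        r = analyze_trace(trace)
        assert epoch_event_counts(r, trace) == (r.n_peaks, 0)

    def test_stimulus_before_trace_start(self):
        values = np.zeros(30)
        values[5] = 50.0
        trace = mk_trace(values, stimulus_time=-10.0)
        r = analyze_trace(trace)
        assert epoch_event_counts(r, trace) == (0, r.n_peaks)

    def test_counts_sum_to_n_peaks(self, rng):
        values = rng.normal(100, 3, 60)
        values[[10, 30, 50]] += 30
        trace = mk_trace(values, stimulus_time=60.0)
        r = analyze_trace(trace)
        pre, post = epoch_event_counts(r, trace)
        assert pre + post == r.n_peaks
        assert r.epoch_counts == (pre, post)

    def test_generator_truth_post_stimulus(self):
        cfg = TraceSimConfig(n_cells=1, stimulus_index=30, event_times=[[40, 50]],
                             seed=2)
        traces, truth = generate_traces(cfg)
        r = analyze_trace(traces[0])
        pre, post = epoch_event_counts(r, traces[0])
        assert pre == 0
        assert post == len(truth[0])

    def test_missing_stimulus_rejected(self):
        trace = mk_trace(np.zeros(10))
        with pytest.raises(ValueError, match="stimulus"):
            epoch_event_counts(analyze_trace(trace), trace)


def _result(active, cell_id="c"):
    return EventCallResult(cell_id=cell_id, z_series=np.zeros(3),
                           n_peaks=int(active), is_active=active)


class TestPercentActive:
    def test_none_active(self):
        per, mean = percent_active([_result(False) for _ in range(5)], ["a1"] * 5)
        assert per["a1"] == 0.0 and mean == 0.0

    def test_three_of_four(self):
        res = [_result(True), _result(True), _result(True), _result(False)]
        per, mean = percent_active(res, ["a1"] * 4)
        assert per["a1"] == pytest.approx(75.0)

    def test_known_truth_cohort(self):
        cfg = TraceSimConfig(n_cells=6,
                             event_times=[[10], [], [20], [], [30], [40]],
                             seed=5)
        traces, truth = generate_traces(cfg)
        results = [analyze_trace(tr) for tr in traces]
        animals = ["a1", "a1", "a1", "a2", "a2", "a2"]
        per, mean = percent_active(results, animals)
        # truth: a1 has 2/3 active, a2 has 2/3 active
        assert per["a1"] == pytest.approx(100 * 2 / 3)
        assert per["a2"] == pytest.approx(100 * 2 / 3)
        assert mean == pytest.approx(100 * 2 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_active([], [])


class TestActivityHeatmap:
    def test_single_cell_row_equals_z_series(self, rng):
        values = rng.normal(0, 1, 20)
        r = analyze_trace(mk_trace(values))
        hm = activity_heatmap([r])
        np.testing.assert_allclose(hm.loc["c0"].to_numpy(), r.z_series)

    def test_rows_match_recomputed_zscores(self, rng):
        traces = [mk_trace(rng.normal(50, 5, 30), cell_id=f"c{i}") for i in range(4)]
        hm = activity_heatmap([analyze_trace(t) for t in traces])
        for t in traces:
            np.testing.assert_allclose(hm.loc[t.cell_id].to_numpy(),
                                       zscore_trace(t.values))

    def test_constant_traces_all_zero(self):
        rs = [analyze_trace(mk_trace([3.0] * 10, cell_id=f"c{i}")) for i in range(3)]
        assert (activity_heatmap(rs).to_numpy() == 0).all()

    def test_ragged_lengths_need_flag(self, rng):
        rs = [analyze_trace(mk_trace(rng.normal(0, 1, n), cell_id=f"c{n}"))
              for n in (10, 12)]
        with pytest.raises(ValueError, match="truncate"):
            activity_heatmap(rs)
        hm = activity_heatmap(rs, truncate_to_shortest=True)
        assert hm.shape == (2, 10)


class TestTraceIO:
    def test_frame_round_trip(self, rng):
        traces = [
            FluorescenceTrace(cell_id=f"c{i}", times=np.arange(5) * 2.0,
                              values=rng.normal(100, 5, 5), animal_id="a0",
                              cell_class="drg_neuron", stimulus_time=4.0)
            for i in range(2)
        ]
        loaded = traces_from_frame(traces_to_frame(traces))
        for a, b in zip(loaded, traces):
            assert a.cell_id == b.cell_id
            assert a.animal_id == "a0" and a.cell_class == "drg_neuron"
            assert a.stimulus_time == 4.0
            np.testing.assert_allclose(a.values, b.values)
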