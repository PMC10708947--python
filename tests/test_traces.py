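"""Unit and property tests for the calcium-trace pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import graftquant as gq
from graftquant import traces as tr
from graftquant.errors import DegenerateBaselineError, InputError

from conftest import brute_force_baseline

DT = 1.0 / 30.33


class TestBaseline:
    def test_constant_trace_baseline_is_constant(self):
        x = np.full(500, 7.5)
        assert np.allclose(gq.compute_baseline(x, DT), 7.5)

    def test_alternating_trace_baseline_is_lower_level(self):
        # alternating 0/10: the lowest half of any full window is all zeros
        x = np.tile([0.0, 10.0], 1000)
        f0 = gq.compute_baseline(x, DT, window_s=30.0, fraction=0.5)
        full = int(round(30.0 / DT))
        assert np.allclose(f0[full:], 0.0)

    def test_first_frame_equals_first_sample(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 2, 100)
        f0 = gq.compute_baseline(x, DT)
        assert f0[0] == x[0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(100, 5, 400)
            got = gq.compute_baseline(x, DT, window_s=2.0, fraction=0.5)
            want = brute_force_baseline(x, DT, window_s=2.0, fraction=0.5)
            np.testing.assert_allclose(got, want, rtol=0, atol=1e-9)

    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 0.9))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_property(self, seed, fraction):
        rng = np.random.default_rng(seed)
        x = rng.uniform(1, 10, 120)
        got = gq.compute_baseline(x, DT, window_s=1.0, fraction=fraction)
        want = brute_force_baseline(x, DT, window_s=1.0, fraction=fraction)
        np.testing.assert_allclose(got, want, rtol=0, atol=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(50, 3, 300)
        c = 17.3
        np.testing.assert_allclose(
            gq.compute_baseline(x + c, DT), gq.compute_baseline(x, DT) + c, atol=1e-9
        )

    def test_empty_trace_rejected(self):
        with pytest.raises(InputError):
            gq.compute_baseline(np.array([]), DT)


class TestDff:
    def test_equal_trace_and_baseline_give_zero(self):
        x = np.full(50, 3.0)
        assert np.allclose(gq.compute_dff(x, x), 0.0)

    def test_double_baseline_gives_one(self):
        f0 = np.linspace(1, 2, 50)
        assert np.allclose(gq.compute_dff(2 * f0, f0), 1.0)

    def test_zero_baseline_raises_with_frame(self):
        f0 = np.ones(10)
        f0[4] = 0.0
        with pytest.raises(DegenerateBaselineError, match="frame 4"):
            gq.compute_dff(np.ones(10), f0)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        x = np.full(200, 2.5)
        assert np.allclose(gq.smooth_dff(x, DT, 0.8), 2.5)

    def test_impulse_becomes_plateau(self):
        dt = 0.1
        w = 9  # round(0.8 / 0.1) = 8 -> forced odd 9
        x = np.zeros(101)
        x[50] = 1.0
        sm = gq.smooth_dff(x, dt, 0.8)
        assert np.allclose(sm[50 - 4 : 50 + 5], 1.0 / w)
        assert sm[50 - 5] == 0.0

    def test_window_equal_dt_is_identity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        assert np.allclose(gq.smooth_dff(x, DT, DT), x)


class TestDetectPeaks:
    def test_all_zero_series_yields_no_candidates(self):
        assert len(gq.detect_peaks(np.zeros(1000), DT)) == 0

    def test_single_noise_free_transient_found_at_kernel_peak(self):
        # a realistic recording length: the detection threshold is sd of the
        # whole curve / 0.2, so the quiet majority of the trace must dominate
        t = np.arange(0, 330, DT)
        onset = 20.0
        dff = 10.0 * gq.double_exp_kernel(t - onset, 2.0, 5.0)
        sm = gq.smooth_dff(dff, DT, 0.8)
        cand = gq.detect_peaks(sm, DT)
        assert len(cand) == 1
        expected = int(round((onset + gq.kernel_peak_time(2.0, 5.0)) / DT))
        assert abs(int(cand["peak_frame"].iloc[0]) - expected) <= 1

    def test_transient_below_noise_threshold_not_detected(self):
        # amplitude 0.01 on noise sd 0.1: threshold is 5 * sd >> peak
        rng = np.random.default_rng(4)
        t = np.arange(0, 60, DT)
        dff = 0.01 * gq.double_exp_kernel(t - 20.0, 2.0, 5.0)
        dff += rng.normal(0, 0.1, t.size)
        sm = gq.smooth_dff(dff, DT, 0.8)
        cand = gq.detect_peaks(sm, DT)
        peak_frame = int(round((20.0 + gq.kernel_peak_time(2.0, 5.0)) / DT))
        assert not np.any(np.abs(cand["peak_frame"] - peak_frame) < 30)


class TestRejectArtifacts:
    @staticmethod
    def _candidates(roi, frame, amp):
        return pd.DataFrame(
            {"roi_index": [roi], "peak_frame": [frame], "amplitude_dff": [amp]}
        )

    def test_peak_kept_when_other_rois_silent(self):
        field = np.zeros((10, 100))
        field[0, 50] = 10.0
        out = gq.reject_artifacts(self._candidates(0, 50, 10.0), field, 0.15)
        assert not out["rejected"].iloc[0]
        assert out["rejection_threshold_dff"].iloc[0] == 0.0

    def test_simultaneous_field_wide_deflection_rejected(self):
        # all 50 ROIs at 5: AVGo ~ 5, STDo ~ 0 -> threshold ~ 33 > 5
        field = np.zeros((50, 100))
        field[:, 50] = 5.0
        out = gq.reject_artifacts(self._candidates(0, 50, 5.0), field, 0.15)
        assert out["rejected"].iloc[0]
        assert out["rejection_threshold_dff"].iloc[0] == pytest.approx(5.0 / 0.15)

    def test_small_background_in_others_keeps_peak(self):
        # others at |mean| 0.1 with sd 0.05 -> threshold = 0.15/0.15 = 1 < 10
        field = np.zeros((3, 100))
        field[0, 50] = 10.0
        field[1, 50] = 0.15
        field[2, 50] = 0.05  # mean 0.1, sample sd ~0.0707
        out = gq.reject_artifacts(self._candidates(0, 50, 10.0), field, 0.15)
        assert not out["rejected"].iloc[0]
        assert out["rejection_threshold_dff"].iloc[0] == pytest.approx(
            (0.1 + np.std([0.15, 0.05], ddof=1)) / 0.15
        )

    def test_single_roi_field_keeps_candidates_with_warning(self):
        field = np.zeros((1, 100))
        field[0, 50] = 10.0
        with pytest.warns(UserWarning, match="single-ROI"):
            out = gq.reject_artifacts(self._candidates(0, 50, 10.0), field, 0.15)
        assert not out["rejected"].iloc[0]


class TestKinetics:
    def test_symmetric_triangle(self):
        # 0 -> 10 over 5 s and back: 10% crossing at 0.5 s on each side
        dt = 0.1
        up = np.linspace(0, 10, 51)
        x = np.concatenate([up, up[-2::-1], np.zeros(20)])
        rise, decay, duration = gq.measure_kinetics(x, 50, dt)
        assert rise == pytest.approx(4.5, abs=dt)
        assert decay == pytest.approx(4.5, abs=dt)
        assert duration == pytest.approx(9.0, abs=2 * dt)

    def test_exponential_decay_gives_tau_ln10(self):
        dt = 0.02
        tau = 3.0
        t = np.arange(0, 60, dt)
        x = np.zeros(t.size)
        p = 100
        x[p:] = 10.0 * np.exp(-(t[p:] - t[p]) / tau)
        _, decay, _ = gq.measure_kinetics(x, p, dt)
        assert decay == pytest.approx(tau * np.log(10.0), abs=dt)

    def test_peak_at_last_frame_censors_decay(self):
        x = np.concatenate([np.zeros(50), np.linspace(0, 10, 50)])
        rise, decay, duration = gq.measure_kinetics(x, 99, 0.1)
        assert np.isfinite(rise)
        assert np.isnan(decay) and np.isnan(duration)


class TestAnalyzeField:
    def test_noise_free_transients_all_recovered(self):
        # one staggered transient per ROI, no noise, no artifacts: the
        # pipeline must return exactly one accepted event per ROI at the
        # kernel peak
        n_rois, n_frames = 6, 10_000
        t = np.arange(n_frames) * DT
        f = np.full((n_rois, n_frames), 100.0)
        onsets = 60.0 + 40.0 * np.arange(n_rois)
        for r, onset in enumerate(onsets):
            f[r] += 10.0 * 100.0 * gq.double_exp_kernel(t - onset, 2.0, 5.0)
        traces = gq.TraceSet(
            fluorescence=f,
            frame_interval_s=DT,
            roi_kind=np.array(["neurite"] * n_rois, dtype=object),
        )
        table = gq.analyze_field(traces)
        acc = table.accepted
        assert len(acc) == n_rois
        assert len(table.events) == n_rois  # nothing rejected either
        tp = gq.kernel_peak_time(2.0, 5.0)
        for r, onset in enumerate(onsets):
            match = acc[acc["roi_id"] == traces.roi_ids[r]]
            assert len(match) == 1
            assert match["peak_time_s"].iloc[0] == pytest.approx(onset + tp, abs=0.1)
            assert match["amplitude_dff"].iloc[0] == pytest.approx(10.0, rel=0.02)

    def test_artifact_only_field_yields_no_accepted_events(self):
        params = gq.TraceSimParams(
            n_rois=20,
            n_frames=6000,
            events_per_roi_rate=0.0,
            artifact_rate_per_min=3.0,
            noise_sd=0.3,
            seed=13,
        )
        traces, truth = gq.simulate_trace_set(params)
        assert len(truth.artifacts) > 0
        table = gq.analyze_field(traces)
        # only events during the baseline warm-up (first 30 s) may leak
        acc = table.accepted
        assert (acc["peak_time_s"] >= 30.0).sum() == 0

    def test_empty_trace_set_rejected(self):
        with pytest.raises(InputError):
            gq.TraceSet(
                fluorescence=np.empty((0, 10)),
                frame_interval_s=DT,
                roi_kind=np.array([], dtype=object),
            )

    def test_scale_invariance_of_detection(self):
        params = gq.TraceSimParams(
            n_rois=4, n_frames=4000, seed=21, events_per_roi_rate=1.0
        )
        traces, _ = gq.simulate_trace_set(params)
        table1 = gq.analyze_field(traces)
        scaled = gq.TraceSet(
            fluorescence=traces.fluorescence * 7.3,
            frame_interval_s=traces.frame_interval_s,
            roi_kind=traces.roi_kind,
            roi_ids=traces.roi_ids,
        )
        table2 = gq.analyze_field(scaled)
        pd.testing.assert_frame_equal(table1.events, table2.events)

    @pytest.mark.parametrize("which", ["sensitivity1", "sensitivity2"])
    def test_accepted_count_monotone_in_sensitivities(self, which, default_field):
        # threshold = sd/sensitivity1 and rejection threshold =
        # (AVGo+STDo)/sensitivity2 both fall as the sensitivity rises, so the
        # accepted-event count is non-decreasing in either
        _, traces, _ = default_field
        sub = gq.TraceSet(
            fluorescence=traces.fluorescence[:12, :4000],
            frame_interval_s=traces.frame_interval_s,
            roi_kind=traces.roi_kind[:12],
        )
        counts = []
        for v in (0.05, 0.15, 0.5):
            params = gq.DetectionParams(**{which: v})
            counts.append(len(gq.analyze_field(sub, params).accepted))
        assert counts == sorted(counts)


class TestSummaries:
    @staticmethod
    def _table(n_rois, kinds, active_rois):
        rois = pd.DataFrame(
            {
                "roi_id": [f"r{i}" for i in range(n_rois)],
                "roi_kind": kinds,
                "n_events": [1 if i in active_rois else 0 for i in range(n_rois)],
            }
        )
        rois["active"] = rois["n_events"] > 0
        events = pd.DataFrame(columns=tr.EVENT_COLUMNS)
        return gq.EventTable(events=events, rois=rois)

    def test_proportion_active(self):
        table = self._table(50, ["neurite"] * 50, {0, 1, 2, 3})
        summary, _ = gq.summarize_events(table)
        row = summary[summary["roi_kind"] == "neurite"].iloc[0]
        assert row["proportion_active"] == pytest.approx(0.08)

    def test_no_events_gives_zero_everywhere(self):
        table = self._table(10, ["soma"] * 5 + ["neurite"] * 5, set())
        summary, events = gq.summarize_events(table)
        assert (summary["proportion_active"] == 0).all()
        assert len(events) == 0

    def test_groups_are_independent(self):
        t1 = self._table(10, ["soma"] * 10, {0})
        t2 = self._table(20, ["soma"] * 20, set(range(10)))
        summary, _ = gq.summarize_events({"3mpi": t1, "6mpi": t2})
        by_group = summary.set_index("group")["proportion_active"]
        assert by_group["3mpi"] == pytest.approx(0.1)
        assert by_group["6mpi"] == pytest.approx(0.5)

    def test_unknown_kind_rejected(self):
        table = self._table(2, ["soma", "axon"], set())
        with pytest.raises(InputError):
            gq.summarize_events(table)


def test_recording_durations_match_acquisition_protocol():
    assert round(gq.recording_duration_s(5000, 30.33)) == 165
    assert round(gq.recording_duration_s(10000, 30.33)) == 330
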