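"""Kinematic chain: speed, sigma filter, low-pass, segmentation, scoring."""

import numpy as np
import pytest

from tmteeg import kinematics as K
from tmteeg import synth
from tmteeg.kinematics import SpeedSeries, StylusTrace


def brute_force_sigma(t, v, window_ms=151.0, k_sd=2.0):
    """O(n*w) reference implementation of the sliding sigma filter."""
    out = v.copy()
    for i in range(len(v)):
        sel = np.abs(t - t[i]) <= window_ms / 2.0
        w = v[sel]
        mean, sd = w.mean(), w.std()
        if abs(v[i] - mean) > k_sd * sd:
            keep = np.abs(w - mean) <= k_sd * sd
            out[i] = w[keep].mean() if keep.any() else np.median(w)
    return out


class TestComputeSpeed:
    def test_constant_position_gives_zero(self):
        t = np.arange(0, 1000, 25.0)
        trace = StylusTrace(t, np.full(t.size, 5.0), np.full(t.size, 7.0), np.ones(t.size))
        assert np.all(K.compute_speed(trace).v_px_s == 0.0)

    def test_linear_motion_gives_constant_speed(self):
        t = np.arange(0, 2000, 25.0)
        trace = StylusTrace(t, 100.0 * t / 1000.0, np.zeros(t.size), np.ones(t.size))
        np.testing.assert_allclose(K.compute_speed(trace).v_px_s, 100.0)

    def test_matches_per_pair_oracle(self, rng):
        t = np.cumsum(rng.uniform(20, 30, size=200))
        x = rng.normal(0, 50, size=200).cumsum()
        y = rng.normal(0, 50, size=200).cumsum()
        trace = StylusTrace(t, x, y, np.ones(200))
        got = K.compute_speed(trace).v_px_s
        expected = np.array(
            [
                np.hypot(x[i + 1] - x[i], y[i + 1] - y[i]) / ((t[i + 1] - t[i]) / 1000.0)
                for i in range(199)
            ]
        )
        np.testing.assert_array_equal(got, expected)

    def test_pen_up_pairs_are_zeroed(self):
        t = np.arange(0, 250, 25.0)
        pen = np.ones(t.size)
        pen[4:6] = 0
        trace = StylusTrace(t, t.copy(), np.zeros(t.size), pen)
        v = K.compute_speed(trace).v_px_s
        assert v[3] == 0.0 and v[4] == 0.0 and v[5] == 0.0
        assert v[0] > 0

    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(K.DataError):
            StylusTrace([0.0, 0.0, 10.0], [0, 1, 2], [0, 0, 0], [1, 1, 1])


class TestSigmaFilter:
    def test_constant_series_unchanged(self):
        t = np.arange(0, 2000, 25.0)
        s = SpeedSeries(t, np.full(t.size, 100.0))
        np.testing.assert_array_equal(K.sigma_filter(s).v_px_s, s.v_px_s)

    def test_spike_replaced_by_local_level(self):
        t = np.arange(0, 2000, 25.0)
        v = np.full(t.size, 100.0)
        v[40] = 1e4
        out = K.sigma_filter(SpeedSeries(t, v)).v_px_s
        assert out[40] == pytest.approx(100.0, rel=1e-6)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 150
        t = np.cumsum(rng.uniform(20, 30, size=n))
        v = np.abs(rng.normal(100, 40, size=n))
        v[rng.integers(0, n, size=4)] *= 20  # spikes
        got = K.sigma_filter(SpeedSeries(t, v)).v_px_s
        expected = brute_force_sigma(t, v)
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_idempotent_on_spike_free_series(self, rng):
        t = np.arange(0, 3000, 25.0)
        v = 100.0 + 5.0 * np.sin(2 * np.pi * t / 1500.0)
        once = K.sigma_filter(SpeedSeries(t, v))
        twice = K.sigma_filter(once)
        np.testing.assert_allclose(twice.v_px_s, once.v_px_s)


class TestSigmaFilterProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.floats(0.0, 1000.0), min_size=10, max_size=60), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_agrees_with_oracle_on_arbitrary_series(self, values, seed):
        rng = np.random.default_rng(seed)
        v = np.asarray(values)
        t = np.cumsum(rng.uniform(20.0, 30.0, size=v.size))
        got = K.sigma_filter(SpeedSeries(t, v)).v_px_s
        np.testing.assert_allclose(got, brute_force_sigma(t, v), rtol=1e-9, atol=1e-9)

    @given(st.floats(0.5, 20.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_output_scales_linearly(self, gain):
        rng = np.random.default_rng(0)
        v = np.abs(rng.normal(100, 40, size=80))
        t = np.arange(80) * 25.0
        base = K.sigma_filter(SpeedSeries(t, v)).v_px_s
        scaled = K.sigma_filter(SpeedSeries(t, gain * v)).v_px_s
        np.testing.assert_allclose(scaled, gain * base, rtol=1e-9)


class TestLowpassResample:
    def test_dc_preserved(self):
        t = np.arange(0, 5000, 25.0)
        out = K.lowpass_and_resample(SpeedSeries(t, np.full(t.size, 123.0)))
        np.testing.assert_allclose(out.v_px_s, 123.0, rtol=1e-6)
        assert np.allclose(np.diff(out.t_ms), 1.0)

    def test_passband_and_stopband(self):
        t = np.arange(0, 20000, 25.0)
        for freq, min_gain, max_gain in ((1.0, 0.9, 1.1), (15.0, 0.0, 0.05)):
            v = 200.0 + 100.0 * np.sin(2 * np.pi * freq * t / 1000.0)
            out = K.lowpass_and_resample(SpeedSeries(t, v))
            inner = (out.t_ms > 2000) & (out.t_ms < 18000)
            amp = (out.v_px_s[inner].max() - out.v_px_s[inner].min()) / 2.0
            assert min_gain * 100.0 <= amp <= max_gain * 100.0 + 1e-9

    def test_too_short_series_rejected(self):
        t = np.arange(0, 100, 25.0)
        with pytest.raises(K.DataError):
            K.lowpass_and_resample(SpeedSeries(t, np.zeros(t.size)))


def hann_burst(t_ms, start_ms, dur_ms, peak):
    u = (t_ms - start_ms) / dur_ms
    v = peak * np.sin(np.pi * np.clip(u, 0, 1)) ** 2
    v[(u < 0) | (u > 1)] = 0.0
    return v


class TestSegmentation:
    def test_two_bursts_recovered_near_truth(self):
        t = np.arange(0, 5000.0)
        v = hann_burst(t, 1000, 600, 100.0) + hann_burst(t, 3000, 600, 100.0)
        seg = K.segment_by_threshold(SpeedSeries(t, v), expected_links=2)
        assert seg.n_links_found == 2
        thr = seg.threshold_px_s
        # analytic crossing times of the found threshold on a Hann bell
        off = 600.0 / np.pi * np.arcsin(np.sqrt(thr / 100.0))
        for (a, b), start in zip(seg.linking_intervals, (1000.0, 3000.0)):
            assert a == pytest.approx(start + off, abs=5.0)
            assert b == pytest.approx(start + 600.0 - off, abs=5.0)

    def test_mask_partition_is_exact(self):
        t = np.arange(0, 4000.0)
        v = hann_burst(t, 500, 500, 80.0) + hann_burst(t, 2000, 500, 80.0)
        seg = K.segment_by_threshold(SpeedSeries(t, v), 2)
        total = sum(b - a for a, b in seg.linking_intervals) + sum(
            b - a for a, b in seg.nonlinking_intervals
        )
        assert total == pytest.approx(seg.completion_ms)

    def test_all_zero_speed_fails(self):
        t = np.arange(0, 1000.0)
        with pytest.raises(K.SegmentationError):
            K.segment_by_threshold(SpeedSeries(t, np.zeros(t.size)), 1)

    def test_threshold_exceeds_fastest_nonlink_excursion(self):
        t = np.arange(0, 6000.0)
        v = (
            hann_burst(t, 500, 600, 100.0)
            + hann_burst(t, 2300, 800, 19.7)  # slow, sustained non-link excursion
            + hann_burst(t, 4000, 600, 100.0)
        )
        seg = K.segment_by_threshold(SpeedSeries(t, v), 2)
        assert seg.threshold_px_s > 19.7

    def test_coordinate_scaling_invariance(self, simulated_trial):
        trace, _, seq = simulated_trial
        scaled = StylusTrace(trace.t_ms, 2 * trace.x_px, 2 * trace.y_px, trace.pen_down)

        def run(tr):
            s = K.lowpass_and_resample(K.sigma_filter(K.compute_speed(tr)))
            return K.segment_by_threshold(s, len(seq))

        s1, s2 = run(trace), run(scaled)
        assert s2.threshold_px_s == pytest.approx(2 * s1.threshold_px_s, abs=2.0)
        for (a1, b1), (a2, b2) in zip(s1.linking_intervals, s2.linking_intervals):
            assert a2 == pytest.approx(a1, abs=15.0)
            assert b2 == pytest.approx(b1, abs=15.0)


class TestLinkScoring:
    def _trace_visiting(self, layout, order, dwell_ms=300, move_ms=400):
        """Piecewise trace pausing at each item of ``order`` (item indices)."""
        xy = np.array([(s.x, s.y) for s in layout.items])
        t, x, y = [0.0], [xy[order[0], 0]], [xy[order[0], 1]]
        seg_bounds = []
        for a, b in zip(order, order[1:]):
            t0 = t[-1]
            # dwell
            for dt in np.arange(25, dwell_ms, 25):
                t.append(t0 + dt), x.append(xy[a, 0]), y.append(xy[a, 1])
            t1 = t[-1]
            for dt in np.arange(25, move_ms + 25, 25):
                frac = dt / move_ms
                t.append(t1 + dt)
                x.append(xy[a, 0] + frac * (xy[b, 0] - xy[a, 0]))
                y.append(xy[a, 1] + frac * (xy[b, 1] - xy[a, 1]))
            seg_bounds.append((t1, t[-1]))
        trace = StylusTrace(np.array(t), np.array(x), np.array(y), np.ones(len(t)))
        seg = K.SegmentationResult(
            [(a, b) for a, b in seg_bounds],
            [],
            10.0,
        )
        return trace, seg

    def test_in_order_sequence_all_correct(self, layout_a):
        trace, seg = self._trace_visiting(layout_a, [0, 1, 2, 3])
        links = K.extract_links(seg, trace, layout_a)
        assert [e.correct for e in links] == [True, True, True]
        assert [e.target_label for e in links] == ["2", "3", "4"]

    def test_skip_ahead_is_error_then_corrected(self, layout_a):
        # 1 -> 2 -> 4 -> 3: the 2->4 link is an error, 4->3 corrects it
        trace, seg = self._trace_visiting(layout_a, [0, 1, 3, 2])
        links = K.extract_links(seg, trace, layout_a)
        assert [e.correct for e in links] == [True, False, True]
        assert links[1].target_label == "4"
        assert links[2].target_label == "3"

    def test_crossed_item_without_pause_ignored(self, layout_a):
        # single linking interval passing near item 2's circle en route 1 -> 3;
        # no segmentation boundary there, so only one (correct?) link toward 3
        trace, seg = self._trace_visiting(layout_a, [0, 2])
        links = K.extract_links(seg, trace, layout_a)
        assert len(links) == 1
        assert links[0].target_label == "3"

    def test_unresolved_link_flagged(self, layout_a):
        xy = np.array([(s.x, s.y) for s in layout_a.items])
        far = xy.mean(axis=0) + 500.0  # nowhere near any item
        t = np.arange(0, 1000, 25.0)
        x = np.linspace(xy[0, 0], far[0], t.size)
        y = np.linspace(xy[0, 1], far[1], t.size)
        trace = StylusTrace(t, x, y, np.ones(t.size))
        seg = K.SegmentationResult([(100.0, 900.0)], [], 10.0)
        links = K.extract_links(seg, trace, layout_a)
        assert len(links) == 1
        assert not links[0].resolved and not links[0].correct


class TestTrialMetrics:
    def _links(self, n_correct, n_error=0, end_ms=30000.0):
        links = [
            K.LinkEvent(i * 100.0, i * 100.0 + 50.0, 300.0, "a", "b", True)
            for i in range(n_correct)
        ]
        links += [
            K.LinkEvent(0.0, 50.0, 300.0, "a", "b", False) for _ in range(n_error)
        ]
        if links:
            links[-1].end_ms = end_ms
        return links

    def _seg(self):
        return K.SegmentationResult([(0.0, 100.0)], [(100.0, 200.0)], 5.0)

    def test_incomplete_trial_uses_block_duration(self):
        m = K.compute_trial_metrics(self._seg(), self._links(10), 40.0)
        assert m.spl_s == pytest.approx(4.0)
        assert m.completion_time_s == 40.0

    def test_complete_trial_uses_final_link_time(self):
        m = K.compute_trial_metrics(self._seg(), self._links(24, end_ms=31200.0), 40.0)
        assert m.completion_time_s == pytest.approx(31.2)
        assert m.spl_s == pytest.approx(1.3)

    def test_errors_counted_in_totals(self):
        m = K.compute_trial_metrics(self._seg(), self._links(10, n_error=2), 40.0)
        assert m.n_total_links == 12
        assert m.n_errors == 2
        assert m.n_correct_links == 10

    def test_zero_correct_links_rejected(self):
        with pytest.raises(K.DataError):
            K.compute_trial_metrics(self._seg(), self._links(0, n_error=2), 40.0)
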