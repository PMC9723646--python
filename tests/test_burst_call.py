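"""Burst-calling state machine: hand-executed cases, filters, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ms2burst.burst_call import (
    BurstCallConfig,
    burst_properties,
    default_start_threshold,
    detect_bursts,
    smooth_trace,
)


def cfg(**kw):
    defaults = dict(start_threshold=2.0)
    defaults.update(kw)
    return BurstCallConfig(**defaults)


def make_pulse_trace(n, pulses, height=10.0):
    """Zero trace with rectangular pulses at inclusive (start, end) pairs."""
    tr = np.zeros(n)
    for s, e in pulses:
        tr[s : e + 1] = height
    return tr


class TestSmoothTrace:
    def test_constant_unchanged(self):
        tr = np.full(20, 3.7)
        np.testing.assert_allclose(smooth_trace(tr, 5), tr)

    def test_unit_impulse_spreads_to_one_fifth(self):
        tr = np.zeros(21)
        tr[10] = 1.0
        sm = smooth_trace(tr, 5)
        np.testing.assert_allclose(sm[8:13], 0.2)
        assert sm[7] == 0.0 and sm[13] == 0.0

    def test_matches_exhaustive_mean_loop(self):
        rng = np.random.default_rng(0)
        tr = rng.random(30)
        sm = smooth_trace(tr, 5)
        for t in range(30):
            lo, hi = max(0, t - 2), min(30, t + 3)
            assert sm[t] == pytest.approx(tr[lo:hi].mean())

    def test_window_validation(self):
        with pytest.raises(ValueError):
            smooth_trace(np.zeros(10), 4)
        with pytest.raises(ValueError):
            smooth_trace(np.zeros(3), 5)


class TestDetectBursts:
    def test_all_zero_trace_no_bursts(self):
        assert detect_bursts(np.zeros(50), cfg()) == []

    def test_rectangular_pulse_hand_executed(self):
        # pulse height 10 frames 10..29; threshold 2; end rule: first frame
        # below 0.55*10; smoothing makes edges ramp 2,4,6,8,10 / 8,6,4,2
        raw = make_pulse_trace(60, [(10, 29)], height=10.0)
        sm = smooth_trace(raw, 5)
        bursts = detect_bursts(sm, cfg())
        assert len(bursts) == 1
        b = bursts[0]
        # hand execution: start at t=9 (sm=4>2); running peak 10;
        # first frame < 5.5 is t=30 (sm=4); candidate [9,29]; +2 -> [11,31]
        assert (b.start_frame, b.end_frame) == (11, 31)
        assert b.duration_frames >= 5
        assert b.amplitude == pytest.approx(10.0)

    def test_short_pulse_rejected_as_false_positive(self):
        # only 3 frames above threshold -> candidate shorter than 5 frames
        raw = make_pulse_trace(40, [(10, 12)], height=10.0)
        sm = smooth_trace(raw, 5)  # peak 6 over frames 10..12, ramps 2,4 outside
        assert detect_bursts(sm, cfg(start_threshold=5.0)) == []

    def test_opening_decline_not_a_burst(self):
        # trace starts high and decays monotonically: no burst at start
        tr = np.concatenate([np.linspace(10, 0, 25), np.zeros(15)])
        bursts = detect_bursts(tr, cfg())
        assert all(b.start_frame > 5 for b in bursts)
        assert bursts == []

    def test_two_separated_pulses_two_bursts(self):
        raw = make_pulse_trace(80, [(10, 25), (50, 65)], height=10.0)
        sm = smooth_trace(raw, 5)
        bursts = detect_bursts(sm, cfg())
        assert len(bursts) == 2
        assert bursts[0].end_frame < bursts[1].start_frame

    def test_emitted_bursts_satisfy_rules_by_construction(self):
        rng = np.random.default_rng(3)
        config = cfg(start_threshold=1.5)
        for _ in range(50):
            tr = np.abs(rng.normal(0, 1, 120)) + make_pulse_trace(
                120, [(20, 40), (70, 95)], height=rng.uniform(3, 20)
            )
            tr -= tr.min()
            sm = smooth_trace(tr, 5)
            bursts = detect_bursts(sm, config)
            prev_end = -1
            for b in bursts:
                assert b.duration_frames >= config.min_duration
                assert b.start_frame > prev_end  # ordered, non-overlapping
                prev_end = b.end_frame
                # within-burst smoothed max reaches the start threshold
                assert sm[b.start_frame : b.end_frame + 1].max() >= config.start_threshold * 0.55

    def test_determinism(self):
        rng = np.random.default_rng(11)
        tr = np.abs(rng.normal(0, 2, 200))
        sm = smooth_trace(tr, 5)
        b1 = detect_bursts(sm, cfg())
        b2 = detect_bursts(sm, cfg())
        assert [(b.start_frame, b.end_frame) for b in b1] == [
            (b.start_frame, b.end_frame) for b in b2
        ]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0), st.integers(0, 2**31 - 1))
    def test_scale_equivariance(self, c, seed):
        # scaling trace and threshold together leaves intervals unchanged
        rng = np.random.default_rng(seed)
        tr = np.abs(rng.normal(0, 1, 100)) + make_pulse_trace(100, [(30, 55)], 8.0)
        tr -= tr.min()
        sm = smooth_trace(tr, 5)
        b1 = detect_bursts(sm, cfg(start_threshold=2.0))
        b2 = detect_bursts(sm * c, cfg(start_threshold=2.0 * c))
        assert [(b.start_frame, b.end_frame) for b in b1] == [
            (b.start_frame, b.end_frame) for b in b2
        ]

    def test_recovery_on_simulated_on_off_traces(self):
        # ON >= 8 frames, OFF gaps >= 10 frames, SNR >= 10:
        # recall and precision >= 0.9 with >= 50% interval overlap
        rng = np.random.default_rng(17)
        height, noise_sd = 1000.0, 100.0
        config = cfg(start_threshold=0.3 * height)
        hits = n_true = n_det = 0
        for _ in range(60):
            n = 150
            intervals = []
            t = rng.integers(5, 15)
            while t + 8 < n - 5:
                length = int(rng.integers(8, 16))
                end = min(t + length - 1, n - 1)
                intervals.append((int(t), end))
                t = end + 1 + rng.integers(10, 25)
            raw = make_pulse_trace(n, intervals, height) + rng.normal(0, noise_sd, n)
            raw = np.clip(raw, 0.0, None)  # measurement floor, as in extraction
            raw -= raw.min()
            sm = smooth_trace(raw, 5)
            detected = [(b.start_frame, b.end_frame) for b in detect_bursts(sm, config)]
            n_true += len(intervals)
            n_det += len(detected)
            for s, e in intervals:
                for ds, de in detected:
                    ov = min(e, de) - max(s, ds) + 1
                    if ov >= 0.5 * min(e - s + 1, de - ds + 1):
                        hits += 1
                        break
        recall = hits / n_true
        precision = hits / n_det
        assert recall >= 0.9, f"recall {recall:.3f}"
        assert precision >= 0.9, f"precision {precision:.3f}"


class TestBurstProperties:
    def test_zero_bursts_summary(self):
        raw = np.array([1.0, 2.0, 3.0])
        s = burst_properties(raw, raw, [], frame_interval=10.0, track_id=7)
        assert s.n_bursts == 0
        assert np.isnan(s.mean_amplitude)
        assert s.total_output == 6.0

    def test_single_pulse_properties(self):
        raw = make_pulse_trace(60, [(10, 29)], height=10.0)
        sm = smooth_trace(raw, 5)
        bursts = detect_bursts(sm, cfg())
        s = burst_properties(raw, sm, bursts, frame_interval=16.8)
        assert s.n_bursts == 1
        assert s.mean_amplitude == pytest.approx(10.0, rel=0.1)
        assert s.total_output == pytest.approx(200.0)
        assert s.mean_duration_s == s.mean_duration_frames * 16.8

    def test_burst_frequency_increases_with_k_on(self):
        # detected burst count rises monotonically across k_on scalings
        from ms2burst.synth import TelegraphParams, simulate_telegraph

        base_kon = 1 / 200.0
        means = []
        for mult, seed in ((0.5, 1), (1.0, 2), (2.0, 3)):
            params = TelegraphParams(
                k_on=base_kon * mult, k_off=1 / 60.0, loading_rate=0.3, dwell_time=100.0
            )
            counts = []
            ss = np.random.SeedSequence(seed)
            for child in ss.spawn(200):
                res = simulate_telegraph(
                    params, 200, 16.8, rng=np.random.default_rng(child)
                )
                sm = smooth_trace(res.trace, 5)
                counts.append(len(detect_bursts(sm, cfg(start_threshold=3.0))))
            means.append(np.mean(counts))
        assert means[0] < means[1] < means[2]


class TestThresholdAndConfig:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            BurstCallConfig(smooth_window=4)
        with pytest.raises(ValueError):
            BurstCallConfig(end_fraction=1.5)
        with pytest.raises(ValueError):
            BurstCallConfig(min_duration=0)

    def test_default_threshold_tracks_signal_scale(self):
        rng = np.random.default_rng(0)
        traces = [np.abs(rng.normal(0, 100, 200)) for _ in range(20)]
        thr1 = default_start_threshold(traces)
        thr2 = default_start_threshold([5 * t for t in traces])
        assert thr2 == pytest.approx(5 * thr1)

    def test_missing_frames_split_segments(self):
        from ms2burst.burst_call import call_traceset
        from ms2burst.spot_quant import TraceSet

        raw = make_pulse_trace(60, [(10, 25), (40, 55)], height=10.0)
        gap = raw.copy()
        gap[30:35] = np.nan
        ts = TraceSet(
            start_frame={1: 0},
            raw={1: gap},
            baseline_sub={1: gap},
            fit_ok={1: np.isfinite(gap)},
            frame_interval=16.8,
        )
        bursts, summaries, bt, st_ = call_traceset(ts, cfg())
        assert len(bursts) == 2
        assert summaries[0].total_output == pytest.approx(np.nansum(gap))
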