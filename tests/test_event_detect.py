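"""Baseline estimation, 10x-SD peak detection, kinetics and rates."""

import dataclasses

import numpy as np
import pytest

from cawave import (
    Cell,
    SynthConfig,
    generate_traces,
)
from cawave.event_detect import (
    BaselineStats,
    DetectionParams,
    detect_events,
    detect_peaks,
    estimate_baseline,
    peak_kinetics,
    peak_rate,
    steady_state,
)
from cawave.synthgen import event_waveform

DT = 2.0


def flat_baseline(f0=100.0, sigma=1.0, n=600):
    return BaselineStats(f0=f0, sigma=sigma, frames=np.arange(n))


class TestEstimateBaseline:
    def test_constant_trace(self):
        b = estimate_baseline(np.full(100, 42.0))
        assert b.f0 == 42.0 and b.sigma == 0.0

    def test_gaussian_trace_recovers_moments(self):
        """Sampling distribution: on N(100, 5) traces of 600 frames the
        robust estimates land within +-0.6 / +-0.5 for >= 90 % of seeds."""
        hits_f0 = hits_sig = 0
        n_seeds = 50
        for seed in range(n_seeds):
            trace = np.random.default_rng(seed).normal(100.0, 5.0, 600)
            b = estimate_baseline(trace)
            hits_f0 += abs(b.f0 - 100.0) < 0.6
            hits_sig += abs(b.sigma - 5.0) < 0.5
        assert hits_f0 / n_seeds >= 0.9
        assert hits_sig / n_seeds >= 0.9

    def test_robust_to_large_peak(self, rng):
        """A 50-sigma peak over 20 % of frames must not move the estimates
        away from what the peak-free complement itself gives."""
        noise = rng.normal(100.0, 5.0, 600)
        clean = estimate_baseline(noise[:480])
        contaminated = noise.copy()
        contaminated[480:] += 250.0
        b = estimate_baseline(contaminated)
        assert b.f0 == pytest.approx(clean.f0, abs=0.6)
        assert b.sigma == pytest.approx(clean.sigma, abs=0.6)

    def test_fallback_when_exclusion_removes_too_much(self, rng):
        # events cover 35 % of frames; with a 70 % floor on usable baseline
        # frames the iterative exclusion falls back to the global estimate
        trace = rng.normal(100.0, 1.0, 200)
        trace[130:] += 500.0
        b = estimate_baseline(trace, DetectionParams(baseline_min_fraction=0.7))
        assert b.fallback
        assert not estimate_baseline(trace).fallback

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline(np.arange(5.0))


class TestDetectPeaks:
    @pytest.mark.parametrize("amp_sigma, n_expected", [(9.0, 0), (12.0, 1)])
    def test_threshold_oracle(self, amp_sigma, n_expected):
        t = np.arange(0, 600, DT)
        trace = 100.0 + event_waveform(t, 200.0, amp_sigma, 4.0, 10.0)
        events = detect_peaks(trace, flat_baseline(n=t.size), DetectionParams(), DT)
        assert len(events) == n_expected

    def test_flat_trace_has_no_events(self):
        assert detect_peaks(np.full(300, 100.0), BaselineStats(100.0, 0.0, np.arange(300)),
                            DetectionParams(), DT) == []

    def test_degenerate_sigma_on_varying_trace_rejected(self):
        trace = np.full(300, 100.0)
        trace[50] = 200.0
        with pytest.raises(ValueError):
            detect_peaks(trace, BaselineStats(100.0, 0.0, np.arange(300)),
                         DetectionParams(), DT)

    def test_two_transients_recovered_at_planted_onsets(self, rng):
        t = np.arange(0, 600, DT)
        onsets = [100.0, 150.0]
        trace = 100.0 + rng.normal(0, 1.0, t.size)
        for o in onsets:
            trace += event_waveform(t, o, 20.0, 2.0, 5.0)
        base = estimate_baseline(trace)
        events = detect_peaks(trace, base, DetectionParams(), DT)
        assert len(events) == 2
        for ev, o in zip(events, onsets):
            assert abs(ev.onset_s - o) <= DT + 1e-9
            assert ev.amp_ratio >= 10.0

    def test_event_at_recording_end_flagged_incomplete(self):
        t = np.arange(0, 600, DT)
        trace = 100.0 + event_waveform(t, 590.0, 50.0, 2.0, 100.0)
        events = detect_peaks(trace, flat_baseline(n=t.size), DetectionParams(), DT)
        assert len(events) == 1 and not events[0].complete

    def test_threshold_monotonicity(self, rng):
        """Raising threshold_k never increases the event count."""
        t = np.arange(0, 1200, DT)
        trace = 100.0 + rng.normal(0, 1.0, t.size)
        for o in rng.uniform(30, 1100, 12):
            trace += event_waveform(t, o, rng.uniform(8, 40), 2.0, 5.0)
        base = estimate_baseline(trace)
        counts = [
            len(detect_peaks(trace, base, DetectionParams(threshold_k=k), DT))
            for k in (5.0, 8.0, 10.0, 12.0, 15.0, 20.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_time_shift_equivariance(self):
        t = np.arange(0, 600, DT)
        trace = 100.0 + event_waveform(t, 100.0, 30.0, 2.0, 8.0)
        m = 25
        shifted = np.concatenate([np.full(m, 100.0), trace])[: t.size]
        base = flat_baseline(n=t.size)
        ev = detect_peaks(trace, base, DetectionParams(), DT)[0]
        ev_s = detect_peaks(shifted, base, DetectionParams(), DT)[0]
        assert ev_s.onset_s - ev.onset_s == pytest.approx(m * DT)
        assert ev_s.peak_s - ev.peak_s == pytest.approx(m * DT)

    def test_amplitude_equivariance(self):
        """Scaling trace and baseline together preserves times and kinetics."""
        t = np.arange(0, 600, DT)
        trace = 100.0 + event_waveform(t, 100.0, 30.0, 4.0, 8.0)
        base = flat_baseline(n=t.size)
        c = 3.7
        base_c = BaselineStats(c * base.f0, c * base.sigma, base.frames)
        p = DetectionParams()
        ev = detect_peaks(trace, base, p, DT)[0]
        ev_c = detect_peaks(c * trace, base_c, p, DT)[0]
        assert ev_c.onset_s == pytest.approx(ev.onset_s)
        assert ev_c.peak_s == ev.peak_s
        k = peak_kinetics(trace, ev, base, p, DT)
        k_c = peak_kinetics(c * trace, ev_c, base_c, p, DT)
        assert k_c == pytest.approx(k)


class TestPeakKinetics:
    def test_rise_time_of_linear_ramp(self):
        """4-s noiseless ramp to 100 sigma: half-max sits 2 s after baseline
        departure."""
        dt = 0.1
        t = np.arange(0, 300, dt)
        trace = 100.0 + event_waveform(t, 50.0, 100.0, 4.0, 10.0)
        base = flat_baseline(n=t.size)
        ev = detect_peaks(trace, base, DetectionParams(), dt)[0]
        rise, _ = peak_kinetics(trace, ev, base, DetectionParams(), dt)
        assert rise == pytest.approx(2.0, abs=1e-6)

    def test_decay_time_matches_closed_form(self):
        """tau * ln(100/10) = 27.19 s for a 100-sigma transient, tau 11.81."""
        dt = 0.1
        t = np.arange(0, 300, dt)
        trace = 100.0 + event_waveform(t, 50.0, 100.0, 1.0, 11.81)
        base = flat_baseline(n=t.size)
        ev = detect_peaks(trace, base, DetectionParams(), dt)[0]
        _, decay = peak_kinetics(trace, ev, base, DetectionParams(), dt)
        assert decay == pytest.approx(11.81 * np.log(10.0), abs=0.1)
        assert decay == pytest.approx(27.2, abs=0.1)

    def test_single_sample_spike_decays_within_one_frame(self):
        trace = np.full(300, 100.0)
        trace[150] = 200.0
        base = flat_baseline(n=300)
        ev = detect_peaks(trace, base, DetectionParams(), DT)[0]
        _, decay = peak_kinetics(trace, ev, base, DetectionParams(), DT)
        assert 0 < decay <= DT


class TestSteadyState:
    def test_constant(self):
        assert steady_state(np.full(200, 12.5), DT) == 12.5

    def test_event_adds_area_over_window(self):
        n_win = int(300.0 / DT)
        t = np.arange(0, 400, DT)
        wf = event_waveform(t, 50.0, 30.0, 2.0, 10.0)
        trace = 100.0 + wf
        area = wf[:n_win].sum()
        assert steady_state(trace, DT) == pytest.approx(100.0 + area / n_win)

    def test_window_order_invariant(self, rng):
        trace = rng.uniform(0, 10, 150)
        perm = trace.copy()
        rng.shuffle(perm)
        assert steady_state(perm, DT) == pytest.approx(steady_state(trace, DT))

    def test_window_must_fit(self):
        with pytest.raises(ValueError):
            steady_state(np.zeros(100), DT, window_start=0.0)


class TestPeakRate:
    def test_rate_is_count_over_duration(self):
        events = [dataclasses.replace(_ev(), roi=i % 5) for i in range(450)]
        assert peak_rate(events, 600.0).peaks_per_s == pytest.approx(0.75)

    def test_empty(self):
        assert peak_rate([], 600.0).peaks_per_s == 0.0

    def test_region_rates_sum_to_total(self):
        events = [dataclasses.replace(_ev(), roi=i % 10) for i in range(200)]
        total = peak_rate(events, 100.0).peaks_per_s
        left = peak_rate(events, 100.0, "IS", region_rois=range(5)).peaks_per_s
        right = peak_rate(events, 100.0, "OS", region_rois=range(5, 10)).peaks_per_s
        assert left + right == pytest.approx(total)


def _ev():
    from cawave.event_detect import CalciumEvent

    return CalciumEvent(roi=0, onset_s=1.0, peak_s=2.0, amplitude=15.0, amp_ratio=15.0)


def test_end_to_end_recall_and_precision_at_15_sigma():
    """On generated traces with 15x-SD transients, detection recovers
    >= 90 % of planted events with >= 90 % precision."""
    cells = [Cell(5.5 + 11.0 * (i % 8), 5.5 + 11.0 * (i // 8)) for i in range(32)]
    cfg = SynthConfig(
        field_width_px=56 * 8,
        field_height_px=56 * 4,
        duration=600.0,
        cells=cells,
        transient_rate=0.005,
        transient_amplitude=15.0,
        rise_duration=2.0,
        decay_tau=5.0,
        seed=13,
    )
    tm, truth = generate_traces(cfg)
    events = detect_events(tm, DetectionParams(min_separation=0.0))
    assert truth.n_events >= 50
    matched_gt = 0
    used = set()
    for gt_ev in truth.events.itertuples():
        det = events[(events["roi"] == gt_ev.roi)
                     & (np.abs(events["onset_s"] - gt_ev.onset_s) < 6.0)]
        if len(det):
            matched_gt += 1
            used.add((gt_ev.roi, det.index[0]))
    recall = matched_gt / truth.n_events
    precision = len({i for _, i in used}) / len(events)
    assert recall >= 0.9
    assert precision >= 0.9
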