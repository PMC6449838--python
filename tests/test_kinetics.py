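"""F/F0 normalization, event detection, MP/SP labeling, half-max kinetics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from vsmcquant import (
    FluorescenceTrace,
    StimulusProtocol,
    classify_events,
    detect_events,
    event_count_per_roi,
    measure_all_kinetics,
    measure_kinetics,
    normalize_trace,
    responding_fraction,
)
from vsmcquant import synthetic as syn
from vsmcquant.types import MP, SP, UNCLASSIFIED, CalciumEvent


def _raw(values, fi=1.0, roi_id=0):
    return FluorescenceTrace(roi_id=roi_id, raw=np.asarray(values, float),
                             frame_interval=fi)


class TestNormalize:
    def test_constant_trace_normalizes_to_one(self, protocol):
        tr = normalize_trace(_raw(np.full(300, 640.0)), protocol)
        np.testing.assert_allclose(tr.normalized, 1.0)
        assert tr.f0 == 640.0

    def test_scale_invariance(self, protocol):
        rng = np.random.default_rng(2)
        raw = 500 + 50 * rng.random(300)
        a = normalize_trace(_raw(raw), protocol).normalized
        b = normalize_trace(_raw(7.3 * raw), protocol).normalized
        np.testing.assert_allclose(a, b)

    def test_baseline_500_peak_1500_gives_peak_3(self, protocol, pulse_trace):
        tr = pulse_trace(onset=100, peak=110, amplitude=3.0, half_max_duration=10.0)
        scaled = _raw(500.0 * tr.raw)
        assert normalize_trace(scaled, protocol).normalized.max() == pytest.approx(3.0)

    def test_short_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            normalize_trace(_raw(np.ones(100)), StimulusProtocol(2.0, 50.0))

    def test_zero_baseline_rejected(self, protocol):
        with pytest.raises(ValueError, match="F0"):
            normalize_trace(_raw(np.zeros(300)), protocol)


class TestDetectEvents:
    def test_constant_trace_yields_no_events(self, protocol):
        tr = _raw(np.full(300, 1.0)).with_f0(1.0, 60)
        assert detect_events(tr, protocol=protocol) == []

    def test_three_separated_pulses_found_at_truth(self, protocol):
        noise = 0.02
        events = [
            syn.EventSpec(130, 140, 1.0 + 10 * noise + 1.0, 14.0),
            syn.EventSpec(250, 258, 1.0 + 10 * noise + 0.8, 12.0),
            syn.EventSpec(380, 392, 1.0 + 10 * noise + 1.2, 16.0),
        ]
        gt = syn.TraceGroundTruth(roi_id=0, events=events, noise_sd=noise)
        tr = syn.generate_trace(gt, 600.0, 1.0, seed=4)
        found = detect_events(tr, protocol=protocol)
        assert len(found) == 3
        for ev, true in zip(found, events):
            assert abs(ev.peak_index * 1.0 - true.peak_time) <= 1.0

    def test_merged_maxima_without_half_max_dip_count_once(self, protocol):
        # two bumps whose valley stays above the half-max level merge
        y = np.ones(300)
        y[140:161] += np.concatenate([
            np.linspace(0, 2.0, 10, endpoint=False),
            [2.0, 1.9, 2.0],
            np.linspace(2.0, 0, 8, endpoint=False),
        ])
        tr = _raw(y).with_f0(1.0, 60)
        assert len(detect_events(tr, protocol=protocol)) == 1

    def test_spurious_event_rate_on_pure_noise_documented(self, protocol):
        """On pure noise the per-frame flag rate stays below alpha (the
        threshold uses the unsmoothed baseline SD but is applied to the
        smoothed trace, a conservative test) and the fraction of traces
        with any spurious event stays small."""
        rng = np.random.default_rng(99)
        alpha, n_traces, n_frames = 0.01, 400, 600
        n_events = 0
        traces_with_event = 0
        exceed = 0
        total = 0
        from scipy.ndimage import uniform_filter1d
        from scipy.stats import norm

        for _ in range(n_traces):
            tr = _raw(1.0 + 0.03 * rng.standard_normal(n_frames)).with_f0(1.0, 60)
            found = detect_events(tr, alpha=alpha, protocol=protocol)
            n_events += len(found)
            traces_with_event += bool(found)
            sm = uniform_filter1d(tr.normalized, 3, mode="nearest")
            thr = 1 + norm.ppf(1 - alpha) * tr.normalized[:60].std(ddof=1)
            exceed += (sm > thr).sum()
            total += n_frames
        rate = exceed / total
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / total)
        assert traces_with_event / n_traces < 0.05


class TestClassifyEvents:
    def _events(self, onsets, drug=120.0):
        evs = [
            CalciumEvent(roi_id=0, onset_index=int(t), peak_index=int(t) + 5,
                         peak_value=2.0, onset_time=float(t))
            for t in onsets
        ]
        return evs

    def test_mp_then_two_sps(self, protocol):
        evs = classify_events(self._events([140, 270, 320]), protocol)
        assert [e.label for e in evs] == [MP, SP, SP]

    def test_single_event_in_window_is_mp_without_sps(self, protocol):
        evs = classify_events(self._events([170]), protocol)
        assert [e.label for e in evs] == [MP]

    def test_first_event_outside_window_means_no_mp(self, protocol):
        evs = classify_events(self._events([270]), protocol)
        assert [e.label for e in evs] == [UNCLASSIFIED]

    def test_pre_drug_events_stay_unclassified(self, protocol):
        evs = classify_events(self._events([80, 140, 270]), protocol)
        assert [e.label for e in evs] == [UNCLASSIFIED, MP, SP]

    def test_at_most_one_mp_and_sps_follow_it(self, protocol):
        rng = np.random.default_rng(3)
        for _ in range(50):
            onsets = np.sort(
                rng.choice(np.arange(10, 500, 7), rng.integers(0, 6), replace=False)
            ).astype(float)
            evs = classify_events(self._events(onsets), protocol)
            labels = [e.label for e in evs]
            assert labels.count(MP) <= 1
            if MP in labels:
                mp_peak = evs[labels.index(MP)].peak_index
                assert all(e.peak_index > mp_peak for e in evs if e.label == SP)


class TestMeasureKinetics:
    def test_symmetric_triangle_half_max_kinetics(self, protocol, pulse_trace):
        tr = pulse_trace(onset=100, peak=110, amplitude=3.0,
                         half_max_duration=10.0, shape="triangle")
        ev = detect_events(tr, protocol=protocol)[0]
        k = measure_kinetics(tr, ev)
        assert k.time_to_peak == pytest.approx(5.0, abs=1e-9)
        assert k.decay == pytest.approx(5.0, abs=1e-9)
        assert k.duration == pytest.approx(10.0, abs=1e-9)

    def test_exponential_fall_decay_is_one_half_life(self, protocol, pulse_trace):
        tr = pulse_trace(onset=100, peak=110, amplitude=3.0,
                         half_max_duration=9.0, shape="exp")
        ev = detect_events(tr, protocol=protocol)[0]
        k = measure_kinetics(tr, ev)
        assert k.time_to_peak == pytest.approx(5.0, abs=1e-9)
        assert k.decay == pytest.approx(4.0, abs=0.05)

    def test_pulse_truncated_at_recording_end_is_censored(self, protocol):
        y = np.ones(200)
        y[150:] = np.linspace(1.0, 3.0, 50)  # still rising at the end
        tr = _raw(y).with_f0(1.0, 60)
        ev = CalciumEvent(roi_id=0, onset_index=150, peak_index=199,
                          peak_value=3.0, onset_time=175.0)
        k = measure_kinetics(tr, ev)
        assert k.censored and k.decay is None and k.duration is None

    def test_duration_identity_for_uncensored_events(self, protocol):
        traces = syn.generate_population(50, seed=21, noise_sd=0.02)
        checked = 0
        for tr in traces:
            evs = detect_events(tr, protocol=protocol)
            for k in measure_all_kinetics(tr, evs):
                if not k.censored:
                    assert k.duration == pytest.approx(k.time_to_peak + k.decay,
                                                       abs=1e-12)
                    checked += 1
        assert checked > 20

    @given(scale=st.floats(min_value=1e-3, max_value=1e4))
    def test_kinetics_invariant_to_raw_intensity_scale(self, scale):
        protocol = StimulusProtocol(60, 120)
        gt = syn.TraceGroundTruth(roi_id=0, events=[syn.EventSpec(130, 142, 2.4, 15.0)])
        base = syn.generate_trace(gt, 300.0, 1.0)
        ref_ev = detect_events(base, protocol=protocol)[0]
        ref = measure_kinetics(base, ref_ev)
        scaled = normalize_trace(_raw(scale * base.raw), protocol)
        ev = detect_events(scaled, protocol=protocol)[0]
        k = measure_kinetics(scaled, ev)
        assert k.time_to_peak == pytest.approx(ref.time_to_peak, rel=1e-9)
        assert k.decay == pytest.approx(ref.decay, rel=1e-9)

    def test_doubling_frame_interval_doubles_kinetics(self, protocol, pulse_trace):
        tr1 = pulse_trace(onset=100, peak=110, amplitude=3.0, half_max_duration=12.0)
        tr2 = FluorescenceTrace(roi_id=0, raw=tr1.raw, frame_interval=2.0, f0=1.0)
        e1 = detect_events(tr1, protocol=protocol)[0]
        e2 = detect_events(tr2, protocol=StimulusProtocol(120, 240))[0]
        k1 = measure_kinetics(tr1, e1)
        k2 = measure_kinetics(tr2, e2)
        assert k2.time_to_peak == pytest.approx(2 * k1.time_to_peak)
        assert k2.decay == pytest.approx(2 * k1.decay)
        assert k2.duration == pytest.approx(2 * k1.duration)

    def test_flat_peak_at_baseline_rejected(self):
        tr = _raw(np.ones(100)).with_f0(1.0, 20)
        ev = CalciumEvent(roi_id=0, onset_index=40, peak_index=50,
                          peak_value=1.0, onset_time=40.0)
        with pytest.raises(ValueError, match="baseline"):
            measure_kinetics(tr, ev)


class TestCountsAndFractions:
    @pytest.mark.parametrize(
        "n_resp, n_total, expected",
        [(50, 200, 0.25), (0, 33, 0.0), (7, 7, 1.0)],
    )
    def test_responding_fraction(self, n_resp, n_total, expected):
        assert responding_fraction(n_resp, n_total) == pytest.approx(expected)

    def test_responding_fraction_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            responding_fraction(5, 0)
        with pytest.raises(ValueError):
            responding_fraction(10, 5)

    def test_event_count_excludes_unclassified(self, protocol):
        evs = [
            CalciumEvent(0, 80, 85, 2.0, 80.0, label=UNCLASSIFIED),
            CalciumEvent(0, 140, 145, 2.0, 140.0, label=MP),
            CalciumEvent(0, 260, 265, 2.0, 260.0, label=SP),
            CalciumEvent(1, 150, 155, 2.0, 150.0, label=MP),
        ]
        assert event_count_per_roi(evs) == {0: 2, 1: 1}

    def test_population_count_histogram_recovered(self, protocol):
        traces = syn.generate_population(400, event_count_mean=2.0, seed=17)
        true_counts = []
        rec_counts = []
        for tr in traces:
            evs = detect_events(tr, protocol=protocol)
            classify_events(evs, protocol)
            rec = sum(1 for e in evs if e.label in (MP, SP))
            rec_counts.append(rec)
            true_counts.append(len(tr.ground_truth.events))
        assert rec_counts == true_counts
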