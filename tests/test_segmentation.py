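"""Segmentation: contact detection, side labels, cycle splitting, resampling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gaitsym.preprocess import estimate_tilt, extract_ap, lowpass_filter, to_earth_frame
from gaitsym.segmentation import (GaitCycle, GaitEvent, NoGaitError,
                                  SegmentationError, SidesIndeterminateError,
                                  detect_initial_contacts, dominant_step_period,
                                  label_sides, mean_waveform, split_cycles,
                                  time_normalize, trim_edge_events)
from gaitsym.simulate import GaitSimParams, simulate_trace


def _pipeline_front(trace):
    filt = lowpass_filter(trace)
    earth = to_earth_frame(filt, estimate_tilt(filt))
    return extract_ap(earth), earth


class TestDominantPeriod:
    def test_recovers_step_frequency(self):
        fs = 100.0
        t = np.arange(3000) / fs
        ap = np.sin(2 * np.pi * 1.8 * t)  # 1.8 Hz steps
        period = dominant_step_period(ap, fs)
        assert period == pytest.approx(1 / 1.8, rel=0.05)

    def test_constant_signal_raises(self):
        with pytest.raises(NoGaitError):
            dominant_step_period(np.ones(2000), 100.0)

    def test_white_noise_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(NoGaitError):
            dominant_step_period(rng.normal(size=4000), 100.0)


class TestDetector:
    def test_symmetric_trial_exact_contacts(self, symmetric_params):
        """Noiseless integer-sample strides: detected times equal ground truth."""
        trace, gt = simulate_trace(symmetric_params, 0)
        ap, _ = _pipeline_front(trace)
        events = detect_initial_contacts(ap, None, trace.fs)
        truth = np.sort(np.concatenate([gt.ic_times["left"], gt.ic_times["right"]]))
        detected = np.array([e.time for e in events])
        # keep detections inside the steady-state walk
        inside = detected[(detected >= truth[0] - 1e-9) & (detected <= truth[-1] + 1e-9)]
        assert len(inside) == len(truth)
        np.testing.assert_allclose(inside, truth, atol=1.0 / trace.fs + 1e-9)

    def test_no_gait_in_quiet_standing(self):
        rng = np.random.default_rng(1)
        ap = rng.normal(0, 0.05, 2000)
        with pytest.raises(NoGaitError):
            detect_initial_contacts(ap, None, 100.0)

    def test_too_short_signal(self):
        with pytest.raises(NoGaitError):
            detect_initial_contacts(np.sin(np.arange(50)), None, 100.0)


class TestSides:
    def _events_from(self, trace):
        ap, earth = _pipeline_front(trace)
        events = detect_initial_contacts(ap, None, trace.fs)
        return label_sides(events, earth.ml, trace.fs), earth

    def test_labels_match_ground_truth(self, study_params):
        trace, gt = simulate_trace(study_params, 11)
        events, _ = self._events_from(trace)
        for ev in events:
            dl = np.min(np.abs(gt.ic_times["left"] - ev.time))
            dr = np.min(np.abs(gt.ic_times["right"] - ev.time))
            if min(dl, dr) > 0.1:  # lead-in/out extras have no truth entry
                continue
            assert ev.side == ("left" if dl < dr else "right")

    def test_alternation_always_enforced(self, study_params):
        for seed in range(5):
            trace, _ = simulate_trace(study_params, seed)
            events, _ = self._events_from(trace)
            sides = [e.side for e in events]
            assert all(a != b for a, b in zip(sides, sides[1:]))

    def test_flat_ml_raises(self):
        events = [GaitEvent(100, 1.0), GaitEvent(150, 1.5)]
        with pytest.raises(SidesIndeterminateError):
            label_sides(events, np.zeros(300), 100.0)

    def test_single_event_rejected(self):
        with pytest.raises(SegmentationError):
            label_sides([GaitEvent(10, 0.1)], np.ones(100), 100.0)

    def test_polarity_convention_flips_labels(self):
        """Inverting ml_positive_is_right swaps every label."""
        t = np.arange(1000) / 100.0
        ml = np.sin(2 * np.pi * 1.0 * t)
        events = [GaitEvent(int(100 * x), x) for x in (0.25, 0.75, 1.25, 1.75)]
        a = label_sides(events, ml, 100.0, positive_is_right=True)
        b = label_sides(events, ml, 100.0, positive_is_right=False)
        assert [e.side for e in a] == [
            {"left": "right", "right": "left"}[e.side] for e in b]


class TestTrimSplit:
    def _labelled(self, n):
        return [GaitEvent(50 * i, 0.5 * i, "left" if i % 2 == 0 else "right")
                for i in range(n)]

    def test_trim_removes_boundary_events(self):
        events = self._labelled(8)
        trimmed = trim_edge_events(events, 1)
        assert trimmed == events[1:-1]

    def test_trim_zero_noop(self):
        events = self._labelled(4)
        assert trim_edge_events(events, 0) == events

    def test_trim_too_few_raises(self):
        with pytest.raises(SegmentationError):
            trim_edge_events(self._labelled(2), 1)

    def test_split_counts_and_sides(self):
        cycles = split_cycles(self._labelled(9), fs=100.0)
        # 5 left events -> 4 left cycles; 4 right events -> 3 right cycles
        assert sum(c.side == "left" for c in cycles) == 4
        assert sum(c.side == "right" for c in cycles) == 3
        for c in cycles:
            assert c.duration == pytest.approx(1.0)

    def test_duration_gate_drops_outliers(self):
        events = self._labelled(9)
        # delay one left contact to stretch a cycle past the gate
        events[4] = GaitEvent(480, 4.8, events[4].side)
        cycles = split_cycles(events, fs=100.0, duration_gate=(0.6, 2.5))
        assert all(0.6 <= c.duration <= 2.5 for c in cycles)

    def test_unlabelled_events_rejected(self):
        events = [GaitEvent(0, 0.0), GaitEvent(50, 0.5), GaitEvent(100, 1.0)]
        with pytest.raises(SegmentationError):
            split_cycles(events, fs=100.0)


class TestNormalize:
    def test_identity_on_matching_length(self):
        ap = np.sin(np.linspace(0, 4 * np.pi, 500))
        cyc = GaitCycle("left", 100, 201, 1.01)
        norm = time_normalize(ap, cyc, n_points=101)
        # 101 samples resampled onto a 101-point grid: unchanged
        np.testing.assert_allclose(norm.waveform, ap[100:201], atol=1e-12)

    @given(st.integers(20, 300))
    def test_endpoints_preserved(self, length):
        rng = np.random.default_rng(length)
        ap = rng.normal(size=400)
        cyc = GaitCycle("right", 10, 10 + length, length / 100.0)
        if length < 4:
            return
        norm = time_normalize(ap, cyc, n_points=101)
        assert norm.waveform[0] == pytest.approx(ap[10])
        assert norm.waveform[-1] == pytest.approx(ap[10 + length - 1])

    def test_out_of_bounds_rejected(self):
        with pytest.raises(SegmentationError):
            time_normalize(np.zeros(50), GaitCycle("left", 10, 80, 0.7))

    def test_too_short_cycle_rejected(self):
        with pytest.raises(SegmentationError):
            time_normalize(np.zeros(50), GaitCycle("left", 0, 3, 0.03))


class TestMeanWaveform:
    def test_pointwise_mean(self):
        from gaitsym.segmentation import NormalizedCycle

        cycles = [NormalizedCycle("left", np.full(101, 1.0)),
                  NormalizedCycle("left", np.full(101, 3.0)),
                  NormalizedCycle("right", np.full(101, 9.0))]
        mean = mean_waveform(cycles, "left", min_cycles=1)
        assert mean.n_cycles == 2
        np.testing.assert_allclose(mean.waveform, 2.0)

    def test_missing_side_raises(self):
        from gaitsym.segmentation import NormalizedCycle

        with pytest.raises(SegmentationError):
            mean_waveform([NormalizedCycle("left", np.zeros(101))], "right")
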