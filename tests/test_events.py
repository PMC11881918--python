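"""Normalization, iterative peak detection, event classification, metrics."""

import numpy as np
import pytest

from myoflow.core import Trace
from myoflow.events import (CONTRACTION_FIRST, RELAXATION_FIRST,
                            ContractionEvent, contraction_count,
                            detect_events, evaluate_detection, event_metrics,
                            filter_events, iterative_peak_detection,
                            match_events, normalize_trace,
                            peak_boundary_markers)
from myoflow.synthetic import (EventSchedule, ScheduledEvent, SimConfig,
                               generate_displacement_trace,
                               generate_event_schedule)


def tr(values, dt=1.0):
    return Trace(values=np.asarray(values, dtype=float), dt=dt)


class TestNormalize:
    def test_forced_by_the_rule(self):
        out = normalize_trace(tr([2, -4, 1]))
        np.testing.assert_allclose(out.values, [1.0, -1.0, 0.5])

    def test_all_positive_trace(self):
        out = normalize_trace(tr([1, 2, 4]))
        assert out.values.max() == 1.0 and out.values.min() >= 0

    def test_idempotent(self, rng):
        v = rng.normal(size=50)
        once = normalize_trace(tr(v))
        twice = normalize_trace(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_all_zero_flagged_unchanged(self):
        out = normalize_trace(tr([0, 0, 0]))
        assert out.degenerate
        assert not out.values.any()

    def test_zeros_preserved(self):
        out = normalize_trace(tr([0, 5, 0, -2, 0]))
        assert out.values[0] == 0 and out.values[2] == 0 and out.values[4] == 0


class TestIterativePeakDetection:
    def test_flat_trace_no_peaks(self):
        tern, peaks = iterative_peak_detection(normalize_trace(tr([0] * 10)))
        assert not peaks and not tern.any()

    def test_tall_pulse_found_first_pass_only(self):
        v = [0, 0, 1.0, 1.0, 0, 0, -1.0, 0]
        tern, peaks = iterative_peak_detection(normalize_trace(tr(v)))
        assert all(p.iteration == 1 for p in peaks)
        assert sorted(p.polarity for p in peaks) == [-1, 1]

    def test_small_pulse_survives_erasure_and_is_caught_second_pass(self):
        # 0.30 < 0.35 escapes pass 1, then 0.30 > 0.25 is caught in pass 2
        v = [0, 1.0, 0, 0, 0.30, 0, -1.0, 0]
        tern, peaks = iterative_peak_detection(normalize_trace(tr(v)))
        by_start = {p.start: p for p in peaks}
        assert by_start[1].iteration == 1
        assert by_start[4].iteration == 2
        assert by_start[6].iteration == 1

    def test_rescan_of_residual_finds_nothing(self):
        cfg = SimConfig(seed=19)
        sch = generate_event_schedule(cfg)
        trace, _ = generate_displacement_trace(sch, cfg)
        norm = normalize_trace(trace)
        tern, peaks = iterative_peak_detection(norm)
        residual = norm.values.copy()
        for p in peaks:
            residual[p.start:p.end + 1] = 0.0
        assert (np.abs(residual) <= 0.15).all()

    def test_lower_final_threshold_never_reduces_peak_count(self):
        cfg = SimConfig(seed=20)
        sch = generate_event_schedule(cfg)
        trace, _ = generate_displacement_trace(sch, cfg)
        norm = normalize_trace(trace)
        _, base = iterative_peak_detection(norm, (0.35, 0.25, 0.15))
        _, lower = iterative_peak_detection(norm, (0.35, 0.25, 0.05))
        assert len(lower) >= len(base)

    def test_nonmonotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            iterative_peak_detection(normalize_trace(tr([0, 1, 0])),
                                     (0.25, 0.35, 0.15))


class TestBoundaryMarkers:
    def test_all_zero_ternary_no_markers(self):
        assert peak_boundary_markers(np.zeros(10, dtype=int)) == []

    def test_positive_then_negative_peak_signature(self):
        ternary = np.array([0, 1, 1, 0, -1, -1, 0])
        markers = peak_boundary_markers(ternary)
        assert [v for _, v in markers] == [1, -1, -1, 1]
        assert [i for i, _ in markers] == [1, 3, 4, 6]

    def test_markers_sum_to_zero(self, rng):
        for _ in range(20):
            ternary = rng.choice([-1, 0, 1], size=60)
            ternary[0] = ternary[-1] = 0
            assert sum(v for _, v in peak_boundary_markers(ternary)) == 0

    def test_adjacent_opposite_peaks_decomposed(self):
        ternary = np.array([0, 1, -1, 0])
        markers = peak_boundary_markers(ternary)
        assert [v for _, v in markers] == [1, -1, -1, 1]


class TestMatchEvents:
    def test_contraction_first_quadruple_matched(self):
        markers = [(10, 1), (20, -1), (25, -1), (40, 1)]
        events = match_events(markers, dt=1.0)
        assert len(events) == 1
        assert events[0].signature == CONTRACTION_FIRST
        assert (events[0].start_index, events[0].end_index) == (10, 40)

    def test_two_positive_peaks_do_not_match(self):
        markers = [(10, 1), (20, -1), (30, 1), (40, -1)]
        assert match_events(markers, dt=1.0) == []

    def test_distant_peaks_not_paired(self):
        # legal signature but 30 s of quiescence between the two peaks
        markers = [(10, 1), (12, -1), (42, -1), (50, 1)]
        assert match_events(markers, dt=1.0) == []

    def test_stray_noise_peak_skipped_whole(self):
        # a 1-sample positive noise blip far ahead of a real relaxation-first
        # event: the gap guard stops the blip from stealing the event's
        # first lobe, and the scan skips the blip as a whole peak
        markers = [(5, 1), (6, -1), (20, -1), (28, 1), (30, 1), (38, -1)]
        events = match_events(markers, dt=1.0)
        assert len(events) == 1
        assert events[0].signature == RELAXATION_FIRST
        assert (events[0].start_index, events[0].end_index) == (20, 38)

    def test_synthetic_schedule_fully_recovered(self):
        cfg = SimConfig(seed=21, trace_noise_frac=0.0)
        sch = generate_event_schedule(cfg)
        trace, _ = generate_displacement_trace(sch, cfg)
        events = detect_events(trace)
        assert len(events) == len(sch)
        for ev, true in zip(events, sch.events):
            assert abs(ev.start - true.onset) <= trace.dt
            assert abs(ev.end - true.offset) <= trace.dt


class TestFilterEvents:
    @staticmethod
    def ev(duration):
        return ContractionEvent(start_index=0,
                                end_index=int(duration), dt=1.0)

    def test_bounds_are_strict(self):
        kept = filter_events([self.ev(10), self.ev(20), self.ev(40)])
        assert [e.duration for e in kept] == [20]
        assert filter_events([self.ev(15)]) == []
        assert filter_events([self.ev(30)]) == []

    def test_empty_input_empty_output(self):
        assert filter_events([]) == []


class TestEventMetrics:
    def test_zero_segment_zero_metrics(self):
        raw = tr([0.0] * 20)
        e = event_metrics(ContractionEvent(start_index=2, end_index=10, dt=1.0),
                         raw, refine=False)
        assert e.strength == 0.0 and e.max_velocity == 0.0

    def test_unit_rectangle_strength_is_its_area(self):
        v = np.zeros(30)
        v[5:16] = 1.0  # 10 s of unit value at dt=1
        e = event_metrics(ContractionEvent(start_index=5, end_index=15, dt=1.0),
                         tr(v), refine=False)
        assert e.strength == pytest.approx(10.0)
        assert e.duration == pytest.approx(10.0)

    def test_triangular_ramp_max_velocity(self):
        # rise 0 -> 1 over 4 s at dt = 0.5: slope 0.25 / sample = 0.25 a.u./s
        ramp = np.concatenate([np.linspace(0, 1, 9), np.linspace(1, 0, 9)[1:]])
        e = event_metrics(ContractionEvent(start_index=0, end_index=16, dt=0.5),
                         tr(ramp, dt=0.5), refine=False)
        assert e.max_velocity == pytest.approx(0.25)

    def test_scaling_raw_trace_scales_strength_not_duration(self, rng):
        cfg = SimConfig(seed=22)
        sch = generate_event_schedule(cfg)
        trace, _ = generate_displacement_trace(sch, cfg)
        base = detect_events(trace)
        scaled = detect_events(trace.with_values(3.0 * trace.values))
        assert len(base) == len(scaled)
        for a, b in zip(base, scaled):
            assert b.strength == pytest.approx(3.0 * a.strength, rel=1e-9)
            assert b.max_velocity == pytest.approx(3.0 * a.max_velocity, rel=1e-9)
            assert b.duration == a.duration

    def test_out_of_range_boundaries_rejected(self):
        with pytest.raises(ValueError):
            event_metrics(ContractionEvent(start_index=-1, end_index=5, dt=1.0),
                          tr([0.0] * 10))


class TestDetectEventsProperties:
    def test_filtered_events_never_overlap_and_signatures_legal(self):
        for seed in range(5):
            cfg = SimConfig(seed=seed)
            sch = generate_event_schedule(cfg)
            trace, _ = generate_displacement_trace(sch, cfg)
            events = detect_events(trace)
            for e in events:
                assert e.signature in (CONTRACTION_FIRST, RELAXATION_FIRST)
            for a, b in zip(events, events[1:]):
                assert a.end <= b.start


class TestContractionCount:
    def test_full_window_no_scaling(self):
        events = [ContractionEvent(start_index=0, end_index=1, dt=1.0)] * 6
        count, scaled = contraction_count(events, 600.0)
        assert count == 6.0 and not scaled

    def test_half_window_scaled_and_flagged(self):
        events = [ContractionEvent(start_index=0, end_index=1, dt=1.0)] * 3
        count, scaled = contraction_count(events, 300.0)
        assert count == pytest.approx(6.0) and scaled

    def test_empty_zero(self):
        assert contraction_count([], 600.0) == (0.0, False)


class TestEvaluateDetection:
    @staticmethod
    def schedule(midpoints, duration=20.0):
        events = [ScheduledEvent(onset=m - duration / 2, duration=duration,
                                 amplitude=1.0) for m in midpoints]
        return EventSchedule(events=events, total_duration=600.0)

    @staticmethod
    def predicted(midpoints, duration=20.0, dt=0.5):
        return [ContractionEvent(start_index=int((m - duration / 2) / dt),
                                 end_index=int((m + duration / 2) / dt), dt=dt)
                for m in midpoints]

    def test_identical_lists_perfect_scores(self):
        mids = [50, 150, 250]
        rep = evaluate_detection(self.predicted(mids), self.schedule(mids))
        assert rep.sensitivity == 1.0 and rep.ppv == 1.0

    def test_no_predictions_flagged(self):
        rep = evaluate_detection([], self.schedule([50, 150]))
        assert rep.sensitivity == 0.0 and rep.ppv == 0.0
        assert rep.ppv_undefined

    def test_hand_counted_confusion(self):
        # 10 truths; 8 predictions of which 7 land on truths
        truth_mids = [50 + 40 * i for i in range(10)]
        pred_mids = truth_mids[:7] + [1000 - 480]  # 7 hits + 1 far miss
        rep = evaluate_detection(self.predicted(pred_mids),
                                 self.schedule(truth_mids))
        assert rep.sensitivity == pytest.approx(0.7)
        assert rep.ppv == pytest.approx(7 / 8)

    def test_matching_is_one_to_one(self):
        # two predictions near one truth: only one may match
        rep = evaluate_detection(self.predicted([50, 52]), self.schedule([50]))
        assert rep.n_matched == 1
        assert rep.false_positives == 1
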