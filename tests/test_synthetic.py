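"""Generators: schedules, biphasic traces, movies, dose-response, ramps."""

import dataclasses

import numpy as np
import pytest

from myoflow.synthetic import (ScheduledEvent, SimConfig, biphasic_pulse,
                               generate_contraction_movie,
                               generate_displacement_trace,
                               generate_dose_response,
                               generate_event_schedule,
                               generate_ramp_recording,
                               hill_activation)


class TestEventSchedule:
    def test_zero_rate_gives_empty_schedule(self):
        cfg = SimConfig(event_rate_per_10min=0.0, seed=1)
        assert len(generate_event_schedule(cfg)) == 0

    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(seed=11)
        a = generate_event_schedule(cfg)
        b = generate_event_schedule(cfg)
        assert len(a) == 6
        assert [e.onset for e in a.events] == [e.onset for e in b.events]
        assert [e.amplitude for e in a.events] == [e.amplitude for e in b.events]

    def test_sampled_durations_stay_inside_retention_band(self):
        # brute-force check of the sampler against its stated bounds
        durations = []
        for seed in range(200):
            cfg = SimConfig(seed=seed)
            durations.extend(e.duration for e in generate_event_schedule(cfg).events)
        durations = np.array(durations)
        assert len(durations) > 1000
        assert (durations > 15.0).all() and (durations < 30.0).all()

    def test_events_separated_by_quiescent_gaps(self):
        for seed in range(20):
            sch = generate_event_schedule(SimConfig(seed=seed))
            for a, b in zip(sch.events, sch.events[1:]):
                assert b.onset - a.offset >= 5.0 - 1e-9

    def test_infeasible_rate_raises(self):
        cfg = SimConfig(total_duration=60.0, event_rate_per_10min=60.0, seed=0)
        with pytest.raises(ValueError, match="cannot place"):
            generate_event_schedule(cfg)


class TestDisplacementTrace:
    def test_empty_schedule_no_noise_is_identically_zero(self):
        cfg = SimConfig(event_rate_per_10min=0.0, trace_noise_frac=0.0, seed=2)
        sch = generate_event_schedule(cfg)
        trace, truth = generate_displacement_trace(sch, cfg)
        assert not trace.values.any()
        assert not truth.trace_clean.values.any()

    def test_single_event_has_one_positive_and_one_negative_lobe(self):
        cfg = SimConfig(total_duration=60.0, event_rate_per_10min=10.0,
                        trace_noise_frac=0.0, seed=3)
        sch = generate_event_schedule(cfg)
        assert len(sch) == 1
        trace, _ = generate_displacement_trace(sch, cfg)
        ev = sch.events[0]
        sign = 1 if ev.contraction_first else -1
        v = sign * trace.values
        inside = (trace.times >= ev.onset) & (trace.times <= ev.offset)
        assert v.max() > 0 and v.min() < 0
        assert inside[np.argmax(v)] and inside[np.argmin(v)]
        # positive lobe precedes the rebound
        assert np.argmax(v) < np.argmin(v)
        assert not trace.values[~inside].any()

    @pytest.mark.parametrize("duration,amplitude", [(16.0, 0.5), (24.0, 1.0), (29.0, 1.5)])
    def test_biphasic_pulse_integrates_to_zero(self, duration, amplitude):
        ev = ScheduledEvent(onset=5.0, duration=duration, amplitude=amplitude)
        t = np.linspace(0, 40, 400001)
        pulse = biphasic_pulse(t, ev)
        assert abs(np.trapezoid(pulse, t)) < 1e-6

    def test_quiescent_noise_is_zero_mean(self):
        cfg = SimConfig(event_rate_per_10min=0.0, seed=4)
        sch = generate_event_schedule(cfg)
        trace, _ = generate_displacement_trace(sch, cfg)
        sd = cfg.trace_noise_sd
        assert abs(trace.values.mean()) < 4 * sd / np.sqrt(len(trace))


class TestContractionMovie:
    def test_zero_amplitude_frames_equal_reference_up_to_noise(self):
        cfg = SimConfig(total_duration=10.0, event_rate_per_10min=0.0,
                        movie_noise_frac=0.0, seed=5)
        stack, _ = generate_contraction_movie(cfg)
        assert np.array_equal(stack.frames[0], stack.frames[-1])

    def test_fixed_seed_regenerates_bit_identical_stack(self):
        cfg = SimConfig(total_duration=20.0, seed=6)
        a, _ = generate_contraction_movie(cfg)
        b, _ = generate_contraction_movie(cfg)
        assert np.array_equal(a.frames, b.frames)

    def test_ground_truth_trace_matches_schedule_pulses(self):
        cfg = SimConfig(total_duration=60.0, event_rate_per_10min=10.0,
                        movie_noise_frac=0.0, seed=7)
        stack, truth = generate_contraction_movie(cfg, direction=0.0)
        dx = truth.parameters["dx"]
        np.testing.assert_allclose(dx, truth.trace_clean.values, atol=1e-12)
        assert not truth.parameters["dy"].any()


class TestDoseResponse:
    def test_half_maximum_at_ec50(self):
        pts = generate_dose_response(10.0, 1.5, 4.6, [10.0])
        assert pts[0].fold_increase == pytest.approx(1 + (4.6 - 1) / 2)

    def test_zero_concentration_gives_unit_fold(self):
        pts = generate_dose_response(10.0, 1.5, 4.6, [0.0])
        assert pts[0].fold_increase == pytest.approx(1.0)

    def test_closed_form_at_high_concentration(self):
        # direct formula evaluation: FI = 1 + 3.6 * 100^1.5/(100^1.5 + 10^1.5)
        expected = 1 + 3.6 * 1000.0 / (1000.0 + 10.0 ** 1.5)
        pts = generate_dose_response(10.0, 1.5, 4.6, [100.0])
        assert pts[0].fold_increase == pytest.approx(expected, rel=1e-12)
        np.testing.assert_allclose(
            hill_activation(np.array([100.0]), 10.0, 1.5, 4.6), expected)

    def test_inhibition_decreases_from_plateau_to_one(self):
        pts = generate_dose_response(8.6, 1.2, 4.0, [0.0, 8.6, 1e6],
                                     mode="inhibition")
        fi = [p.fold_increase for p in pts]
        assert fi[0] == pytest.approx(4.0)
        assert fi[1] == pytest.approx(1 + 3.0 / 2)
        assert fi[2] == pytest.approx(1.0, abs=1e-3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            generate_dose_response(10.0, 1.5, 4.6, [-1.0])


class TestRampRecording:
    def test_zero_conductance_zero_current(self):
        rec = generate_ramp_recording(conductance=0.0)
        assert not rec.current.any()

    def test_inward_rectification_at_endpoints(self):
        rec = generate_ramp_recording(conductance=2.0, reversal=0.0)
        assert rec.current[0] < 0  # inward at -80 mV
        assert abs(rec.current[0]) > abs(rec.current[-1])

    def test_current_linear_in_conductance(self):
        a = generate_ramp_recording(conductance=1.0)
        b = generate_ramp_recording(conductance=2.0)
        np.testing.assert_allclose(b.current, 2 * a.current, rtol=1e-12)
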