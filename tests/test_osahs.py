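"""Apnea/hypopnea scoring, AHI, and the status panel."""

import math

import numpy as np
import pytest

import breathflow as bf
from conftest import make_event_protocol


def cycle_train(spacing=5.0, n=24, amp=3.5, t0=2.5):
    """Uniform train of breath cycles (amplitudes mutable for tests)."""
    cycles = []
    for k in range(n):
        cycles.append(bf.BreathCycle(t0 + k * spacing, amp,
                                     math.nan if k == 0 else spacing))
    return cycles


def with_amps(cycles, amps):
    return [bf.BreathCycle(c.peak_time, a, c.interval)
            for c, a in zip(cycles, amps)]


class TestPercentReduction:
    def test_hypopnea_worked_example(self):
        assert bf.percent_reduction(3.5, 1.86) == 47

    def test_apnea_worked_example(self):
        assert bf.percent_reduction(3.5, 0.35) == 90

    def test_no_reduction(self):
        assert bf.percent_reduction(2.2, 2.2) == 0

    def test_amplitude_above_baseline_clamps_to_zero(self):
        assert bf.percent_reduction(2.0, 2.4) == 0

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            bf.percent_reduction(0.0, 1.0)


class TestRollingBaseline:
    def test_constant_amplitudes(self):
        cycles = cycle_train(amp=2.5)
        base = bf.rolling_baseline(cycles, window=10)
        np.testing.assert_allclose(base, 2.5)

    def test_step_drop_holds_predrop_baseline(self):
        # brute-force oracle: during the drop, the trailing window of
        # non-event breaths still holds only pre-drop amplitudes
        amps = [3.0] * 20 + [1.2] * 6 + [3.0] * 4
        cycles = with_amps(cycle_train(n=30), amps)
        base = bf.rolling_baseline(cycles, window=10)
        for i in range(20, 26):
            assert base[i] == pytest.approx(np.median([3.0] * 10))

    def test_single_cycle_is_its_own_baseline(self):
        c = bf.BreathCycle(1.0, 1.7, math.nan)
        base = bf.rolling_baseline([c], window=10)
        assert base[0] == pytest.approx(1.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bf.rolling_baseline([], window=10)


class TestClassifyEvents:
    def test_90pct_18s_span_is_one_apnea(self):
        # breaths vanish between t=87.5 and t=112.5 (the 18 s pause plus
        # the flanking part-cycles) -> a single apnea
        cycles = [c for c in cycle_train(n=24) if not (90 < c.peak_time < 108)]
        base = bf.rolling_baseline(cycles)
        events = bf.classify_events(cycles, base, trace_span=120.0)
        assert [e.kind for e in events] == ["apnea"]
        assert events[0].start == pytest.approx(90.0, abs=3.0)

    def test_47pct_21s_span_is_one_hypopnea(self):
        amps = [3.5] * 6 + [1.86] * 4 + [3.5] * 14
        cycles = with_amps(cycle_train(n=24), amps)
        events = bf.classify_events(cycles, bf.rolling_baseline(cycles),
                                    trace_span=120.0)
        assert [e.kind for e in events] == ["hypopnea"]
        assert events[0].mean_reduction == pytest.approx(0.47, abs=0.01)
        assert events[0].duration == pytest.approx(21.0, abs=3.0)

    def test_9s_span_below_minimum_scores_nothing(self):
        # deep reduction lasting only 9 s (3 breaths at 3 s spacing)
        amps = [3.5] * 10 + [0.18] * 3 + [3.5] * 10
        cycles = with_amps(cycle_train(spacing=3.0, n=23), amps)
        events = bf.classify_events(cycles, bf.rolling_baseline(cycles),
                                    trace_span=70.0)
        assert events == []

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            bf.EventThresholds(hypopnea_lo=0.9, hypopnea_hi=0.3)
        with pytest.raises(ValueError):
            bf.EventThresholds(min_duration=0.0)

    def test_no_breaths_at_all_is_one_long_apnea(self):
        events = bf.classify_events([], np.array([]), trace_span=60.0)
        assert [e.kind for e in events] == ["apnea"]
        assert events[0].duration == pytest.approx(60.0)

    def test_strict_band_drops_unscored_gap(self):
        # with the textbook 30-50 % band, a 70 % reduction is not scored
        strict = bf.EventThresholds(hypopnea_hi=0.5)
        amps = [3.5] * 8 + [1.05] * 4 + [3.5] * 12
        cycles = with_amps(cycle_train(n=24), amps)
        events = bf.classify_events(cycles, bf.rolling_baseline(cycles),
                                    strict, trace_span=120.0)
        assert events == []


class TestComputeAhi:
    def test_no_events_normal(self):
        rep = bf.compute_ahi([], 7.5)
        assert rep.ahi == 0.0 and rep.severity == "normal"

    def test_two_events_in_two_minutes(self):
        evs = [bf.RespiratoryEvent("hypopnea", 30.0, 21.0, 0.47),
               bf.RespiratoryEvent("apnea", 90.0, 18.0, 0.9)]
        rep = bf.compute_ahi(evs, 120.0 / 3600.0)
        assert rep.ahi == pytest.approx(60.0)
        assert rep.severity == "severe"

    def test_twelve_events_two_hours_mild(self):
        evs = [bf.RespiratoryEvent("apnea", 100.0 * k, 12.0, 1.0)
               for k in range(12)]
        rep = bf.compute_ahi(evs, 2.0)
        assert rep.ahi == pytest.approx(6.0) and rep.severity == "mild"

    def test_matches_brute_force_count_over_random_event_lists(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(0, 12))
            evs = [bf.RespiratoryEvent(
                rng.choice(["apnea", "hypopnea"]), float(rng.uniform(0, 3600)),
                float(rng.uniform(10, 40)), float(rng.uniform(0.3, 1.0)))
                for _ in range(n)]
            hours = float(rng.uniform(0.5, 9.0))
            rep = bf.compute_ahi(evs, hours)
            assert rep.ahi == pytest.approx(len(evs) / hours)
            assert rep.n_apnea + rep.n_hypopnea == len(evs)

    def test_nonpositive_hours_rejected(self):
        with pytest.raises(ValueError):
            bf.compute_ahi([], 0.0)


class TestStatusStream:
    def trace(self, dur=120.0, fs=10.0):
        t = np.arange(0, dur, 1 / fs)
        return bf.VoltageTrace(t, np.zeros(len(t)), fs)

    def test_all_green_without_events(self):
        ss = bf.status_stream([], self.trace())
        assert set(ss.status) == {"green"}

    def test_online_latency_of_ten_seconds(self):
        # brute-force replay: a monitor can only latch the colour once the
        # reduction has persisted min_duration, i.e. from start+10 s
        evs = [bf.RespiratoryEvent("hypopnea", 30.0, 21.0, 0.47),
               bf.RespiratoryEvent("apnea", 90.0, 18.0, 0.9)]
        ss = bf.status_stream(evs, self.trace())
        expect = np.full(len(ss.t), "green", dtype="<U6")
        expect[(ss.t >= 40.0) & (ss.t < 51.0)] = "yellow"
        expect[(ss.t >= 100.0) & (ss.t < 108.0)] = "red"
        np.testing.assert_array_equal(ss.status, expect)

    def test_event_shorter_than_latency_never_colours(self):
        evs = [bf.RespiratoryEvent("apnea", 30.0, 10.0, 1.0)]
        ss = bf.status_stream(evs, self.trace())
        assert set(ss.status) == {"green"}


class TestEndToEnd:
    def test_programmed_events_recovered(self):
        """Seeded random protocols: scored count, kinds and onsets
        (within one breath period) match the programme in >=95 % of runs."""
        ok = 0
        n_runs = 60
        for s in range(n_runs):
            proto, programmed = make_event_protocol(s)
            tr = bf.add_noise(bf.transduce(bf.synth_pressure(proto)),
                              bf.NoiseSpec(seed=1000 + s))
            cond = bf.bandpass(tr)
            cycles = bf.detect_breaths(cond)
            scored = bf.classify_events(cycles, bf.rolling_baseline(cycles),
                                        trace_span=tr.duration, trace=cond)
            ok += (len(scored) == len(programmed) and all(
                e.kind == k and abs(e.start - st) <= 5.0
                for e, (k, st, _, _) in zip(scored, programmed)))
        assert ok / n_runs >= 0.95

    def test_no_events_on_constant_amplitude_protocols(self):
        seg = bf.BreathSegment(0.0, 120.0, 0.2, 4.0)
        proto = bf.ScenarioProtocol((seg,), 120.0, 100.0)
        clean = bf.transduce(bf.synth_pressure(proto))
        for seed in range(50):
            cond = bf.bandpass(bf.add_noise(clean, bf.NoiseSpec(seed=seed)))
            cycles = bf.detect_breaths(cond)
            events = bf.classify_events(cycles, bf.rolling_baseline(cycles),
                                        trace_span=120.0, trace=cond)
            assert events == []
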