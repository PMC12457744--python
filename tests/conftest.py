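"""Shared fixtures: packaged scenarios rendered once per session."""

import numpy as np
import pytest

import breathflow as bf


@pytest.fixture(scope="session")
def fig4f_conditioned():
    """The sleep-apnea demo scenario: noised at seed 0, band-passed."""
    proto = bf.scenario_library("fig4f")
    trace = bf.add_noise(bf.transduce(bf.synth_pressure(proto)),
                         bf.NoiseSpec(seed=0))
    return bf.bandpass(trace)


@pytest.fixture(scope="session")
def fig4g_conditioned():
    proto = bf.scenario_library("fig4g")
    trace = bf.add_noise(bf.transduce(bf.synth_pressure(proto)),
                         bf.NoiseSpec(seed=0))
    return bf.bandpass(trace)


@pytest.fixture
def sine_trace():
    """60 s of a clean 0.2 Hz unit sine at 100 Hz sampling."""
    fs = 100.0
    t = np.arange(0, 60, 1 / fs)
    return bf.VoltageTrace(t, np.sin(2 * np.pi * 0.2 * t), fs)


def make_event_protocol(seed):
    """Random sleep protocol with programmed apnea/hypopnea episodes.

    Returns (protocol, [(kind, start_s, duration_s, reduction), ...]).
    Durations are 12-40 s; hypopnea reductions uniform in [0.3, 0.5],
    apnea reductions uniform in [0.9, 1.0]; normal spans of 30-60 s
    separate the events.
    """
    rng = np.random.default_rng(seed)
    rate, depth = 0.2, 4.0
    n_events = rng.integers(1, 4)
    segs, events = [], []
    cur = 30.0 + rng.uniform(0, 10)
    segs.append(bf.BreathSegment(0.0, cur, rate, depth, 0.0, "baseline"))
    for _ in range(n_events):
        dur = rng.uniform(12, 40)
        if rng.random() < 0.5:
            red, kind = rng.uniform(0.3, 0.5), "hypopnea"
        else:
            red, kind = rng.uniform(0.9, 1.0), "apnea"
        segs.append(bf.BreathSegment(cur, dur, rate, depth, red, kind))
        events.append((kind, cur, dur, red))
        cur += dur
        norm = rng.uniform(30, 60)
        segs.append(bf.BreathSegment(cur, norm, rate, depth, 0.0, "baseline"))
        cur += norm
    return bf.ScenarioProtocol(tuple(segs), cur, 100.0), events
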