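"""Apnea/hypopnea event scoring, AHI computation and the status panel logic.

Clinical definitions drive the defaults: an apnea is a (near-)cessation of
breathing lasting at least 10 s — operationalised here as an amplitude
reduction of at least 90 % relative to the rolling baseline, or a span with
no detectable breaths at all, since airflow itself is not observable from an
abdominal sensor.  A hypopnea is a partial amplitude reduction (>= 30 %)
sustained for at least 10 s.  Reductions between 50 % and 90 % are scored as
hypopneas by default; the strict 30-50 % textbook band is selectable via
``EventThresholds(hypopnea_hi=0.5)``.

The apnea-hypopnea index (AHI) is the total number of apneas plus hypopneas
per hour of recording, graded normal/mild/moderate/severe at the standard
5/15/30 events-per-hour cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .dsp import BreathCycle
from .trace import VoltageTrace

__all__ = [
    "EventThresholds",
    "RespiratoryEvent",
    "AHIReport",
    "StatusStream",
    "rolling_baseline",
    "percent_reduction",
    "classify_events",
    "compute_ahi",
    "status_stream",
]

SEVERITY_CUTOFFS = (5.0, 15.0, 30.0)   # events/h: mild, moderate, severe


@dataclass(frozen=True)
class EventThresholds:
    """Scoring thresholds.

    ``hypopnea_lo``/``hypopnea_hi`` bound the hypopnea reduction band,
    ``apnea_reduction`` is the apnea floor, ``min_duration`` the minimum
    event length, ``baseline_window`` the number of trailing normal breaths
    used for the rolling amplitude baseline.
    """

    min_duration: float = 10.0
    hypopnea_lo: float = 0.30
    hypopnea_hi: float = 0.90
    apnea_reduction: float = 0.90
    baseline_window: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.hypopnea_lo < self.hypopnea_hi
                <= self.apnea_reduction <= 1.0):
            raise ValueError(
                "need 0 < hypopnea_lo < hypopnea_hi <= apnea_reduction <= 1")
        if self.min_duration <= 0:
            raise ValueError("min_duration must be positive")
        if self.baseline_window < 1:
            raise ValueError("baseline_window must be >= 1")


@dataclass(frozen=True)
class RespiratoryEvent:
    """A scored apnea or hypopnea span."""

    kind: str             # "apnea" | "hypopnea"
    start: float          # s
    duration: float       # s
    mean_reduction: float # fraction of baseline amplitude lost

    def __post_init__(self) -> None:
        if self.kind not in ("apnea", "hypopnea"):
            raise ValueError("kind must be 'apnea' or 'hypopnea'")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class AHIReport:
    n_apnea: int
    n_hypopnea: int
    hours: float
    ahi: float            # events per hour
    severity: str         # normal | mild | moderate | severe


@dataclass(frozen=True)
class StatusStream:
    """Per-sample three-state monitor output (green/yellow/red)."""

    t: np.ndarray
    status: np.ndarray    # array of 'green'|'yellow'|'red'


# --------------------------------------------------------------------------
# baseline and reduction
# --------------------------------------------------------------------------

def rolling_baseline(cycles: Sequence[BreathCycle],
                     window: int = 10,
                     candidate_drop: float = 0.30) -> np.ndarray:
    """Per-cycle baseline amplitude from trailing *normal* breaths.

    The baseline for cycle i is the median amplitude of the last ``window``
    cycles whose amplitude did not itself look event-like (reduced by more
    than ``candidate_drop`` from the then-current baseline); excluding
    in-event breaths prevents the baseline from collapsing during long
    events.  The first ``window`` cycles use a leading global estimate:
    the 75th percentile of the leading window, which stays anchored to
    normal breathing even when an event begins before ``window`` normal
    breaths have accumulated (reductions only ever pull amplitudes down,
    so the contamination is one-sided).
    """
    if len(cycles) == 0:
        raise ValueError("need at least one cycle")
    amps = np.array([c.amplitude for c in cycles], dtype=float)
    lead = float(np.percentile(amps[: max(1, min(window, len(amps)))], 75.0))
    normals: List[float] = []
    out = np.empty(len(amps))
    for i, a in enumerate(amps):
        if i < window or not normals:
            base = lead
        else:
            base = float(np.median(normals[-window:]))
        out[i] = base
        if base <= 0 or a >= (1.0 - candidate_drop) * base:
            normals.append(a)
    return out


def percent_reduction(baseline: float, amplitude: float) -> int:
    """Amplitude reduction relative to baseline, as a rounded percentage.

    Negative reductions (amplitude above baseline) clamp to 0.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return max(int(round(100.0 * (1.0 - amplitude / baseline))), 0)


# --------------------------------------------------------------------------
# event classification
# --------------------------------------------------------------------------

def _typical_interval(cycles: Sequence[BreathCycle]) -> float:
    iv = [c.interval for c in cycles if not math.isnan(c.interval)]
    return float(np.median(iv)) if iv else math.nan


def _refine_gap(trace: VoltageTrace, t_last_peak: float, t_next_peak: float,
                typ: float, base_amp: float) -> Tuple[float, float]:
    """Sample-level cessation boundaries inside a breath-free gap.

    The rolling peak-to-trough envelope (window = one typical breath
    period) is thresholded at half the local baseline amplitude; the
    contiguous sub-threshold span containing the gap is the cessation.
    For a sinusoid-like breath train the entry and exit crossings are
    displaced symmetrically by the same sliver of breath visible in the
    window, so the measured span is an unbiased estimate of the true
    cessation duration — unlike peak bookkeeping, whose edge error is up
    to one breath period.
    """
    from scipy.ndimage import maximum_filter1d, minimum_filter1d
    i0 = int(np.searchsorted(trace.t, t_last_peak))
    i1 = int(np.searchsorted(trace.t, t_next_peak))
    if i1 - i0 < 4 or not np.isfinite(typ) or typ <= 0:
        return t_last_peak, t_next_peak
    w = max(3, int(round(0.5 * typ * trace.fs)))
    pad = 2 * w
    a = max(i0 - pad, 0)
    b = min(i1 + pad, len(trace))
    seg = trace.v[a:b]
    env = maximum_filter1d(seg, w, mode="nearest") \
        - minimum_filter1d(seg, w, mode="nearest")
    below = env < 0.5 * base_amp
    mid = (i0 + i1) // 2 - a
    if not below[min(mid, len(below) - 1)]:
        return t_last_peak + 0.5 * typ, t_next_peak - 0.5 * typ
    lo = mid
    while lo > 0 and below[lo - 1]:
        lo -= 1
    hi = mid
    while hi < len(below) - 1 and below[hi + 1]:
        hi += 1
    # the envelope only crosses once roughly half a window of breath is
    # visible, clipping each edge by ~w/4; widen symmetrically to undo it
    edge = 0.25 * w / trace.fs
    s = max(float(trace.t[a + lo]) - edge, t_last_peak)
    e = min(float(trace.t[a + hi]) + edge, t_next_peak)
    return s, e


def classify_events(cycles: Sequence[BreathCycle],
                    baseline: np.ndarray,
                    thresholds: EventThresholds = EventThresholds(),
                    trace_span: Optional[float] = None,
                    trace: Optional[VoltageTrace] = None
                    ) -> List[RespiratoryEvent]:
    """Score apnea and hypopnea events from the breath-cycle series.

    Two detection routes feed a common candidate pool:

    * *reduced-breath runs*: runs of consecutive detected cycles whose
      amplitude reduction (vs. the rolling baseline) reaches
      ``hypopnea_lo``; once entered, a run persists while the reduction
      stays above 80 % of the entry threshold (hysteresis, so a single
      breath flickering across the threshold does not split one clinical
      event into two sub-threshold fragments).  The run's span is bounded
      by the midpoints to the surrounding normal breaths;
    * *breath-free gaps*: spacings between consecutive detected breaths
      more than twice the typical interval (no detectable breathing) count
      as full-cessation spans; when the conditioned voltage ``trace`` is
      supplied their boundaries are refined at sample level (post-peak
      trough to rising-edge crossing), otherwise they are trimmed by half
      a typical interval at each edge.

    Overlapping candidates from the two routes (e.g. a near-total
    reduction whose residual breaths are intermittently detectable) are
    merged into one event.  Spans shorter than ``min_duration`` are then
    discarded; the kind of a surviving event is apnea when it contains a
    full cessation of at least ``min_duration`` (or covering three
    quarters of the event) or its duration-weighted mean reduction
    reaches ``apnea_reduction``; hypopnea when the mean reduction falls
    inside the hypopnea band.
    """
    if not isinstance(thresholds, EventThresholds):
        raise TypeError("thresholds must be an EventThresholds")
    n = len(cycles)
    if n == 0:
        if trace_span is not None and trace_span >= thresholds.min_duration:
            # a record with no detectable breathing at all is one long apnea
            return [RespiratoryEvent("apnea", 0.0, trace_span, 1.0)]
        return []
    baseline = np.asarray(baseline, dtype=float)
    if len(baseline) != n:
        raise ValueError("baseline must align with cycles")
    amps = np.array([c.amplitude for c in cycles])
    times = np.array([c.peak_time for c in cycles])
    # reductions are compared to thresholds at whole-percent resolution,
    # matching percent_reduction's integer bookkeeping (a measured 29.6 %
    # drop counts as the clinical 30 %)
    red = np.round(np.clip(1.0 - amps / np.maximum(baseline, 1e-12),
                           0.0, 1.0), 2)
    typ = _typical_interval(cycles)
    half = 0.5 * typ if not math.isnan(typ) else 0.0
    exit_thr = 0.8 * thresholds.hypopnea_lo

    # candidates: (start, end, mean_reduction, full_cessation_duration)
    cands: List[Tuple[float, float, float, float]] = []

    # --- reduced-breath runs -------------------------------------------
    i = 0
    scanned = 0
    while i < n:
        if red[i] >= thresholds.hypopnea_lo:
            # hysteresis in both directions: the event spans every adjacent
            # breath still above the exit threshold
            j = i
            while (j + 1 < n and red[j + 1] >= exit_thr
                   and (math.isnan(typ)
                        or times[j + 1] - times[j] <= 2.0 * typ)):
                j += 1
            while (i - 1 >= scanned and red[i - 1] >= exit_thr
                   and (math.isnan(typ)
                        or times[i] - times[i - 1] <= 2.0 * typ)):
                i -= 1
            start = 0.5 * (times[i - 1] + times[i]) if i > 0 else times[i] - half
            end = 0.5 * (times[j] + times[j + 1]) if j + 1 < n else times[j] + half
            cands.append((max(start, 0.0), end, float(np.mean(red[i:j + 1])),
                          0.0))
            i = j + 1
            scanned = i
        else:
            i += 1
            scanned = i

    # --- breath-free gaps ----------------------------------------------
    if not math.isnan(typ):
        base_amp = float(np.median(amps))
        for k in range(n - 1):
            gap = times[k + 1] - times[k]
            if gap > 2.0 * typ:
                if trace is not None:
                    s_g, e_g = _refine_gap(trace, times[k], times[k + 1],
                                           typ, base_amp)
                else:
                    s_g, e_g = times[k] + half, times[k + 1] - half
                cands.append((s_g, e_g, 1.0, e_g - s_g))
        if times[0] > 2.0 * typ:
            cands.append((0.0, times[0] - half, 1.0, times[0] - half))
        if trace_span is not None and trace_span - times[-1] > 2.0 * typ:
            cands.append((times[-1] + half, trace_span, 1.0,
                          trace_span - times[-1] - half))

    # --- merge overlaps, filter, classify -------------------------------
    cands.sort()
    merged: List[List[float]] = []
    for (s, e, r, cess) in cands:
        if merged and s <= merged[-1][1] + 1e-9:
            m = merged[-1]
            # duration-weighted mean reduction over the union
            w0, w1 = m[1] - m[0], e - s
            m[2] = (m[2] * w0 + r * w1) / max(w0 + w1, 1e-12)
            m[1] = max(m[1], e)
            m[3] = max(m[3], cess)
        else:
            merged.append([s, e, r, cess])

    events: List[RespiratoryEvent] = []
    for s, e, r, cess in merged:
        if trace_span is not None:
            e = min(e, trace_span)
        dur = e - s
        if dur < thresholds.min_duration:
            continue
        if (cess >= thresholds.min_duration or cess >= 0.75 * dur
                or r >= thresholds.apnea_reduction):
            events.append(RespiratoryEvent("apnea", s, dur, min(r, 1.0)))
        elif thresholds.hypopnea_lo <= r < thresholds.hypopnea_hi:
            events.append(RespiratoryEvent("hypopnea", s, dur, r))
        # under a strict hypopnea band (hypopnea_hi < apnea_reduction),
        # mean reductions in the unscored gap are deliberately dropped
    return events


# --------------------------------------------------------------------------
# AHI and status panel
# --------------------------------------------------------------------------

def compute_ahi(events: Sequence[RespiratoryEvent], hours: float,
                cutoffs: Tuple[float, float, float] = SEVERITY_CUTOFFS
                ) -> AHIReport:
    """Apneas + hypopneas per hour, with clinical severity grading."""
    if hours <= 0:
        raise ValueError("hours must be positive")
    if not (0 < cutoffs[0] < cutoffs[1] < cutoffs[2]):
        raise ValueError("severity cutoffs must be increasing and positive")
    n_a = sum(1 for e in events if e.kind == "apnea")
    n_h = sum(1 for e in events if e.kind == "hypopnea")
    ahi = (n_a + n_h) / hours
    if ahi < cutoffs[0]:
        sev = "normal"
    elif ahi < cutoffs[1]:
        sev = "mild"
    elif ahi < cutoffs[2]:
        sev = "moderate"
    else:
        sev = "severe"
    return AHIReport(n_apnea=n_a, n_hypopnea=n_h, hours=hours,
                     ahi=ahi, severity=sev)


def status_stream(events: Sequence[RespiratoryEvent], trace: VoltageTrace,
                  thresholds: EventThresholds = EventThresholds()
                  ) -> StatusStream:
    """Three-state monitor stream with online latching semantics.

    A monitor watching the signal live cannot know a reduction will last
    10 s until 10 s have elapsed, so within each scored event the yellow
    (hypopnea) or red (apnea) state begins only ``min_duration`` after the
    event's onset and holds until the event ends; everything else is green.
    """
    status = np.full(len(trace), "green", dtype="<U6")
    for ev in events:
        colour = "red" if ev.kind == "apnea" else "yellow"
        on = ev.start + thresholds.min_duration
        mask = (trace.t >= on) & (trace.t < ev.end)
        status[mask] = colour
    return StatusStream(t=trace.t, status=status)
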