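"""Spirometry surrogates from a single forced-exhalation voltage curve.

During one maximal exhalation the sensor's cumulative voltage tracks the
exhaled volume, so voltage-domain analogues of the classic spirometry
indices can be read off the curve:

* ``v_total`` — total voltage excursion, the forced-vital-capacity (FVC)
  surrogate;
* ``v_1s``   — excursion at one second after exhalation onset, the FEV1
  surrogate;
* ``max_slope`` — maximum (smoothed) dv/dt, the peak-expiratory-flow (PEF)
  surrogate;
* ``ratio``  — v_1s / v_total, the FEV1/FVC analogue.

Exhalation onset follows standard spirometry practice: back-extrapolation
of the tangent at the maximum-slope point down to the pre-rise baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .trace import VoltageTrace

__all__ = ["SpiroSurrogates", "detect_onset", "spiro_surrogates"]

#: Savitzky-Golay smoothing used for the derivative (window in samples)
SG_WINDOW = 5
SG_ORDER = 2


@dataclass(frozen=True)
class SpiroSurrogates:
    """Voltage-domain spirometry indices for one forced exhalation."""

    v_total: float    # V
    v_1s: float       # V
    max_slope: float  # V/s
    ratio: float      # dimensionless, v_1s / v_total
    onset: float      # s

    def __post_init__(self) -> None:
        if not (0.0 <= self.v_1s <= self.v_total + 1e-9):
            raise ValueError("need 0 <= v_1s <= v_total")
        if self.max_slope < 0:
            raise ValueError("max_slope must be >= 0")


def _smoothed_derivative(curve: VoltageTrace) -> np.ndarray:
    n = len(curve)
    win = min(SG_WINDOW, n if n % 2 == 1 else n - 1)
    if win < SG_ORDER + 2:
        return np.gradient(curve.v, curve.t)
    return savgol_filter(curve.v, win, SG_ORDER, deriv=1, delta=1.0 / curve.fs)


def _baseline_before(curve: VoltageTrace, t_on: float, window_s: float = 0.5
                     ) -> float:
    mask = (curve.t >= t_on - window_s) & (curve.t < t_on)
    if mask.sum() >= 3:
        return float(np.median(curve.v[mask]))
    return float(curve.v[0])


def detect_onset(curve: VoltageTrace) -> float:
    """Back-extrapolated exhalation onset time.

    The tangent at the maximum-slope point is extended down to the pre-rise
    baseline level; their intersection is the onset (clamped to the start
    of the record).  The baseline is the median of the 0.5 s preceding the
    onset, resolved by a short fixed-point iteration seeded with the first
    sample's value.  A flat curve raises ``ValueError``.
    """
    if curve.duration < 2.0:
        raise ValueError("exhalation record must last >= 2 s")
    v = curve.v
    swing = float(np.max(v) - np.min(v))
    deriv = _smoothed_derivative(curve)
    i_max = int(np.argmax(deriv))
    slope = float(deriv[i_max])
    if swing <= 1e-12 or slope <= 1e-9 * max(swing, 1.0) / curve.duration:
        raise ValueError("no exhalation detected (flat curve)")
    t_on = float(curve.t[0])
    baseline = float(v[0])
    for _ in range(3):
        t_on_new = curve.t[i_max] - (v[i_max] - baseline) / slope
        t_on_new = float(max(t_on_new, curve.t[0]))
        baseline = _baseline_before(curve, t_on_new)
        if abs(t_on_new - t_on) < 0.5 / curve.fs:
            t_on = t_on_new
            break
        t_on = t_on_new
    return t_on


def spiro_surrogates(curve: VoltageTrace) -> SpiroSurrogates:
    """Extract all voltage-domain spirometry surrogates from one curve.

    Raises if no rise is detectable or if the record ends less than one
    second after the detected onset.
    """
    onset = detect_onset(curve)
    baseline = _baseline_before(curve, onset)
    if onset + 1.0 > curve.t[-1] + 1e-9:
        raise ValueError(
            f"record ends {curve.t[-1]:.2f}s, before onset+1s ({onset + 1.0:.2f}s)")
    v_total = float(np.max(curve.v) - baseline)
    v_1s = float(np.interp(onset + 1.0, curve.t, curve.v) - baseline)
    v_1s = min(max(v_1s, 0.0), v_total)
    deriv = _smoothed_derivative(curve)
    max_slope = float(np.max(deriv))
    ratio = v_1s / v_total if v_total > 0 else math.nan
    return SpiroSurrogates(v_total=v_total, v_1s=v_1s, max_slope=max_slope,
                           ratio=ratio, onset=onset)
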