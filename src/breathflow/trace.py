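"""Uniformly sampled signal containers shared across the pipeline.

A :class:`VoltageTrace` is the universal currency of the package: the
simulator produces one, the conditioning and detection stages consume and
return them, and the CSV reader/writer in :mod:`breathflow.io` round-trips
them.  A :class:`PressureTrace` is the pre-transduction abdominal pressure
signal produced by the scenario renderer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PressureTrace", "VoltageTrace"]

#: relative tolerance on grid uniformity (fraction of the sample step)
GRID_RTOL = 1e-6


def _check_uniform(t: np.ndarray, fs: float) -> None:
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be 1-D with at least two samples")
    dt = np.diff(t)
    step = 1.0 / fs
    if np.any(np.abs(dt - step) > GRID_RTOL * step + 1e-12):
        raise ValueError(
            f"time grid is not uniform at fs={fs} Hz "
            f"(max deviation {np.max(np.abs(dt - step)):.3g} s)"
        )


@dataclass(frozen=True)
class PressureTrace:
    """Abdominal pressure vs. time on a uniform grid.

    Attributes
    ----------
    t : ndarray, seconds
    p : ndarray, kPa; non-negative everywhere
    fs : float, sampling rate in Hz
    """

    t: np.ndarray
    p: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "p", p)
        if len(t) != len(p):
            raise ValueError("t and p must have equal length")
        _check_uniform(t, self.fs)
        if np.any(p < -1e-12):
            raise ValueError("pressure must be non-negative")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return len(self.t) / self.fs


@dataclass(frozen=True)
class VoltageTrace:
    """Sensor voltage vs. time on a uniform grid.

    Attributes
    ----------
    t : ndarray, seconds (strictly increasing, step 1/fs)
    v : ndarray, volts
    fs : float, sampling rate in Hz
    """

    t: np.ndarray
    v: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.v, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "v", v)
        if len(t) != len(v):
            raise ValueError("t and v must have equal length")
        _check_uniform(t, self.fs)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return len(self.t) / self.fs

    def crop(self, t0: float, t1: float) -> "VoltageTrace":
        """Return the sub-trace with t0 <= t < t1 (times preserved)."""
        mask = (self.t >= t0 - 1e-12) & (self.t < t1 - 1e-12)
        if mask.sum() < 2:
            raise ValueError(f"crop window [{t0}, {t1}) contains <2 samples")
        return VoltageTrace(self.t[mask], self.v[mask], self.fs)

    def with_values(self, v: np.ndarray) -> "VoltageTrace":
        return VoltageTrace(self.t, np.asarray(v, dtype=float), self.fs)
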