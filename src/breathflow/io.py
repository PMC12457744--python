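"""Trace file formats, run configuration, and the end-to-end pipeline.

Traces travel as two-column CSV (``time_s,voltage_v``) with a ``# fs=<Hz>``
comment header; events as JSONL; reports and manifests as JSON.  A persisted
:class:`RunConfig` re-runs to byte-identical outputs because every stochastic
stage is keyed by the single config seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .dsp import (DEFAULT_BAND, bandpass, breath_stats, detect_breaths, stft)
from .osahs import (EventThresholds, classify_events, compute_ahi,
                    rolling_baseline, status_stream)
from .simulate import (NoiseSpec, TransductionParams, add_noise,
                       scenario_library, synth_pressure, transduce)
from .trace import VoltageTrace

__all__ = ["read_trace", "write_trace", "RunConfig", "run_pipeline",
           "PipelineError", "write_events_jsonl"]

#: tolerated relative mismatch between the fs header and the time column
FS_TOLERANCE = 1e-3


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names the culprit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def write_trace(trace: VoltageTrace, path) -> None:
    """Write a trace as ``# fs=<Hz>`` + ``time_s,voltage_v`` CSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={trace.fs!r}\n")
        fh.write("time_s,voltage_v\n")
        for ti, vi in zip(trace.t, trace.v):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def read_trace(path) -> VoltageTrace:
    """Read and validate a trace CSV written by :func:`write_trace`.

    Raises on a missing/NaN value (naming the row), a missing ``# fs=``
    header or column header, a non-uniform time grid, or an fs header that
    disagrees with the time column by more than 0.1 %.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# fs="):
        raise ValueError(f"{path}: missing '# fs=<Hz>' header comment")
    fs = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(df.columns) != ["time_s", "voltage_v"]:
        raise ValueError(f"{path}: expected header 'time_s,voltage_v', "
                         f"got {list(df.columns)}")
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: NaN/missing value at data row {bad[0]}")
    t = df["time_s"].to_numpy(float)
    v = df["voltage_v"].to_numpy(float)
    dt = np.diff(t)
    if len(dt) == 0:
        raise ValueError(f"{path}: need at least two samples")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > 1e-6 * med + 1e-12):
        raise ValueError(f"{path}: non-uniform time grid")
    if abs(1.0 / med - fs) > FS_TOLERANCE * fs:
        raise ValueError(
            f"{path}: fs header {fs} Hz inconsistent with time step "
            f"{med:.6g} s ({1.0 / med:.6g} Hz)")
    return VoltageTrace(t, v, fs)


def write_events_jsonl(events, path) -> None:
    with open(path, "w") as fh:
        for e in events:
            fh.write(json.dumps({"kind": e.kind, "start_s": round(e.start, 6),
                                 "duration_s": round(e.duration, 6),
                                 "mean_reduction": round(e.mean_reduction, 6)})
                     + "\n")


# --------------------------------------------------------------------------
# run configuration and orchestration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    scenario: str = "fig4f"                    # library name or trace CSV path
    seed: int = 0
    outdir: str = "breathflow_out"
    transduction: TransductionParams = field(default_factory=TransductionParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    thresholds: EventThresholds = field(default_factory=EventThresholds)
    band: tuple = DEFAULT_BAND
    hours: Optional[float] = None              # analysis span; default = record

    def to_json(self) -> str:
        d = asdict(self)
        d["band"] = list(self.band)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["transduction"] = TransductionParams(**d.get("transduction", {}))
        d["noise"] = NoiseSpec(**d.get("noise", {}))
        d["thresholds"] = EventThresholds(**d.get("thresholds", {}))
        d["band"] = tuple(d.get("band", DEFAULT_BAND))
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Dict:
    """Run simulate/load -> condition -> detect -> score -> AHI -> status.

    All artifacts (trace, cycles, events, AHI report, status stream) are
    written under ``config.outdir`` together with a manifest recording the
    config, seeds, package version, thresholds and output hashes.  If a
    labelled-segment scenario is used, per-segment breathing statistics and
    STFT dominant frequencies are included in the report.  A stage failure
    raises :class:`PipelineError` naming the stage, after persisting a
    partial manifest.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"config": json.loads(config.to_json()),
                      "version": __version__, "outputs": {}, "stages": []}

    def _fail(stage: str, err: Exception):
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, str(err)) from err

    protocol = None
    try:
        if config.scenario.endswith(".csv"):
            trace = read_trace(config.scenario)
        else:
            protocol = scenario_library(config.scenario)
            pressure = synth_pressure(protocol)
            clean = transduce(pressure, config.transduction)
            trace = add_noise(clean, dataclasses.replace(config.noise,
                                                         seed=config.seed))
        manifest["stages"].append("acquire")
    except Exception as e:                     # noqa: BLE001
        _fail("acquire", e)

    try:
        cond = bandpass(trace, *config.band)
        manifest["stages"].append("condition")
    except Exception as e:                     # noqa: BLE001
        _fail("condition", e)

    try:
        cycles = detect_breaths(cond)
        stats = breath_stats(cycles)
        manifest["stages"].append("detect")
    except Exception as e:                     # noqa: BLE001
        _fail("detect", e)

    try:
        base = rolling_baseline(cycles, config.thresholds.baseline_window,
                                config.thresholds.hypopnea_lo) \
            if cycles else np.array([])
        events = classify_events(cycles, base, config.thresholds,
                                 trace_span=trace.duration, trace=cond)
        manifest["stages"].append("score")
    except Exception as e:                     # noqa: BLE001
        _fail("score", e)

    try:
        hours = config.hours if config.hours is not None \
            else trace.duration / 3600.0
        ahi = compute_ahi(events, hours)
        status = status_stream(events, trace, config.thresholds)
        manifest["stages"].append("ahi")
    except Exception as e:                     # noqa: BLE001
        _fail("ahi", e)

    # per-segment statistics for labelled scenarios
    segment_stats: List[Dict] = []
    if protocol is not None:
        for seg in protocol.segments:
            seg_cycles = [c for c in cycles
                          if seg.start <= c.peak_time < seg.end]
            st = breath_stats(seg_cycles)
            entry = {"label": seg.label, "start_s": seg.start,
                     "duration_s": seg.duration,
                     "n_breaths": st.n_breaths,
                     "mean_interval_s": st.mean_interval,
                     "mean_amplitude_v": st.mean_amplitude,
                     "rate_per_min": st.rate_per_min}
            if seg.duration >= 8.0:
                spec = stft(cond.crop(seg.start, seg.end),
                            window=min(10.0, seg.duration), hop=2.0)
                entry["dominant_frequency_hz"] = spec.dominant_frequency
            segment_stats.append(entry)

    # ---- artifacts -----------------------------------------------------
    write_trace(trace, outdir / "trace.csv")
    pd.DataFrame({"peak_time_s": [c.peak_time for c in cycles],
                  "amplitude_v": [c.amplitude for c in cycles],
                  "interval_s": [c.interval for c in cycles]}).to_csv(
        outdir / "cycles.csv", index=False)
    write_events_jsonl(events, outdir / "events.jsonl")
    ahi_dict = asdict(ahi)
    (outdir / "ahi.json").write_text(json.dumps(ahi_dict, indent=2))
    pd.DataFrame({"time_s": status.t, "status": status.status}).to_csv(
        outdir / "status.csv", index=False)
    for name in ("trace.csv", "cycles.csv", "events.jsonl", "ahi.json",
                 "status.csv"):
        manifest["outputs"][name] = _sha256(outdir / name)
    manifest["thresholds"] = asdict(config.thresholds)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    report = {
        "stats": asdict(stats),
        "events": [asdict(e) for e in events],
        "ahi": ahi_dict,
        "segments": segment_stats,
        "outdir": str(outdir),
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=float))
    return report
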