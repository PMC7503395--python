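"""Shared data model and calibrated trace/table input-output.

Canonical units at API boundaries: mV, pA, MOhm, pF, ms. Time axes are kept
in seconds internally. A trace on disk is a two-column CSV (``time_s,
signal``) with a ``#``-prefixed unit header, accompanied by a JSON sidecar
carrying the protocol metadata (signal kind, step window and amplitude,
holding level). Vendor formats (ABF, HEKA .dat) are deliberately not parsed;
convert externally to this CSV/JSON pair to enter the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ProtocolError, SchemaError, UnitError

__all__ = [
    "Trace",
    "StepProtocolSet",
    "read_trace_table",
    "write_trace",
    "write_results_table",
    "read_results_table",
]

_SIGNAL_UNITS = {"voltage": "mV", "current": "pA"}


@dataclass
class Trace:
    """A calibrated, uniformly sampled recording with protocol metadata.

    Parameters
    ----------
    samples
        Signal values, mV for ``signal_kind='voltage'``, pA for ``'current'``.
    sampling_interval
        Sample spacing in seconds (> 0).
    signal_kind
        ``'voltage'`` or ``'current'``.
    baseline_window, step_window
        ``(t0, t1)`` in seconds, within the record; ``t_on < t_off``.
    step_amplitude
        Command-step amplitude: mV in voltage clamp, pA in current clamp.
    holding_level
        Pre-step holding command (mV or pA).
    meta
        Free-form metadata; synthetic generators store their ground truth here.
    """

    samples: np.ndarray
    sampling_interval: float
    signal_kind: str
    baseline_window: tuple[float, float]
    step_window: tuple[float, float]
    step_amplitude: float
    holding_level: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise FormatError("trace must be a 1-D array with >= 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("trace contains non-finite samples")
        if not self.sampling_interval > 0:
            raise FormatError("sampling_interval must be > 0")
        if self.signal_kind not in _SIGNAL_UNITS:
            raise FormatError(f"unknown signal_kind {self.signal_kind!r}")
        dur = self.duration
        for name, (a, b) in (
            ("baseline_window", self.baseline_window),
            ("step_window", self.step_window),
        ):
            if not (0.0 <= a < b <= dur + 1e-12):
                raise FormatError(f"{name}={a, b} outside [0, {dur:.6g}] or inverted")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size * self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (first sample at t = 0)."""
        return np.arange(self.samples.size) * self.sampling_interval

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        return int(round(t / self.sampling_interval))

    def with_samples(self, samples: np.ndarray) -> "Trace":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class StepProtocolSet:
    """An ordered family of step responses at strictly increasing amplitudes."""

    traces: list[Trace]
    injected_amplitudes: np.ndarray
    step_duration: float = 0.5
    inter_step_hold: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.injected_amplitudes = np.asarray(self.injected_amplitudes, dtype=float)
        if len(self.traces) != self.injected_amplitudes.size:
            raise ProtocolError("one amplitude per trace required")
        if self.injected_amplitudes.size and np.any(
            np.diff(self.injected_amplitudes) <= 0
        ):
            raise ProtocolError("injected amplitudes must be strictly increasing")
        if not self.step_duration > 0:
            raise ProtocolError("step_duration must be > 0")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(zip(self.injected_amplitudes, self.traces))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_trace_table(
    path,
    schema: dict | None = None,
    *,
    max_jitter_frac: float = 0.5,
) -> Trace:
    """Read a trace CSV and its JSON sidecar into a :class:`Trace`.

    ``schema`` may remap column names, e.g. ``{"time": "t", "signal": "I_pA"}``.
    Non-uniform time axes are rejected (never silently interpolated) when the
    jitter exceeds ``max_jitter_frac`` of the median sampling interval.
    """
    path = Path(path)
    schema = schema or {}
    time_col = schema.get("time", "time_s")
    signal_col = schema.get("signal", "signal")

    df = pd.read_csv(path, comment="#")
    for col in (time_col, signal_col):
        if col not in df.columns:
            raise SchemaError(f"column {col!r} not found in {path.name}")

    side = _sidecar_path(path)
    if not side.exists():
        raise SchemaError(f"sidecar {side.name} missing for {path.name}")
    meta = json.loads(side.read_text())
    for key in ("signal_kind", "step_amplitude", "step_on_s", "step_off_s"):
        if key not in meta:
            raise SchemaError(f"sidecar missing key {key!r}")
    if meta["signal_kind"] not in _SIGNAL_UNITS:
        raise UnitError(f"sidecar signal_kind {meta['signal_kind']!r} is not a known unit system")

    t = df[time_col].to_numpy(float)
    if t.size < 2:
        raise FormatError("trace shorter than 2 samples")
    dt_all = np.diff(t)
    if np.any(dt_all <= 0):
        raise FormatError("time column is not strictly increasing")
    dt = float(np.median(dt_all))
    if np.max(np.abs(dt_all - dt)) > max_jitter_frac * dt:
        raise FormatError("non-uniform sampling (jitter exceeds 0.5 sample); resample explicitly")

    base = meta.get("baseline_window_s")
    if base is None:
        base = [0.0, meta["step_on_s"]]
    return Trace(
        samples=df[signal_col].to_numpy(float),
        sampling_interval=dt,
        signal_kind=meta["signal_kind"],
        baseline_window=(float(base[0]), float(base[1])),
        step_window=(float(meta["step_on_s"]), float(meta["step_off_s"])),
        step_amplitude=float(meta["step_amplitude"]),
        holding_level=float(meta.get("holding", 0.0)),
        meta=meta.get("extra", {}),
    )


def write_trace(trace: Trace, path) -> None:
    """Write ``trace`` as the CSV/JSON pair read back by :func:`read_trace_table`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    unit = _SIGNAL_UNITS[trace.signal_kind]
    with open(path, "w") as fh:
        fh.write(f"# units: time_s=s, signal={unit}\n")
        pd.DataFrame({"time_s": trace.times, "signal": trace.samples}).to_csv(
            fh, index=False, float_format="%.12g"
        )
    meta = {
        "signal_kind": trace.signal_kind,
        "step_amplitude": trace.step_amplitude,
        "step_on_s": trace.step_window[0],
        "step_off_s": trace.step_window[1],
        "baseline_window_s": list(trace.baseline_window),
        "holding": trace.holding_level,
        "extra": _jsonable(trace.meta),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results_table(records: Sequence[dict], path, units: dict | None = None) -> None:
    """Write keyed feature records as a CSV with stable column order.

    All records must share one key set; a ``#`` unit header line is emitted
    when ``units`` maps column names to unit strings.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = list(records)
    if records:
        keys = list(records[0].keys())
        for rec in records[1:]:
            if list(rec.keys()) != keys:
                raise SchemaError("records have heterogeneous key sets")
    else:
        keys = list(units.keys()) if units else []
    with open(path, "w") as fh:
        if units:
            fh.write("# units: " + ", ".join(f"{k}={v}" for k, v in units.items()) + "\n")
        pd.DataFrame(records, columns=keys).to_csv(fh, index=False)


def read_results_table(path) -> pd.DataFrame:
    """Read a results CSV written by :func:`write_results_table`."""
    return pd.read_csv(path, comment="#")
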