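"""Protocol-level firing analysis: spikes, rheobase, f-I curve, gain.

Rheobase is the smallest amplitude of a 5 pA-incremented, 500 ms step family
that elicits at least one action potential. The f-I (input-output) curve is
spike count divided by step duration per amplitude, and the gain is the
maximum finite-difference slope of that curve (dAP frequency / dI_input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .exceptions import (
    InsufficientDataError,
    LowerBoundWarning,
    ProtocolError,
    RheobaseNotFoundError,
)
from .trace_io import StepProtocolSet, Trace

__all__ = [
    "SpikeTrain",
    "FICurve",
    "FiringSummary",
    "detect_spikes",
    "find_rheobase",
    "fi_curve",
    "io_gain",
    "max_firing_frequency",
]


@dataclass
class SpikeTrain:
    """Spike times (s, strictly increasing, within the step window) of one step."""

    spike_times: np.ndarray
    spike_peak_indices: np.ndarray
    step_amplitude: float

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, float)
        self.spike_peak_indices = np.asarray(self.spike_peak_indices, int)
        if self.spike_times.size >= 2 and np.any(np.diff(self.spike_times) <= 0):
            raise ProtocolError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class FICurve:
    currents: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.currents = np.asarray(self.currents, float)
        self.frequencies = np.asarray(self.frequencies, float)
        if self.currents.size != self.frequencies.size:
            raise ProtocolError("currents and frequencies must have equal lengths")
        if np.any(np.diff(self.currents) <= 0):
            raise ProtocolError("currents must be strictly increasing")
        if np.any(self.frequencies < 0):
            raise ProtocolError("frequencies must be >= 0")


@dataclass
class FiringSummary:
    rheobase: float
    max_frequency: float
    gain: float
    current_at_max_gain: float
    Erest: float | None = None
    flags: list[str] = field(default_factory=list)


def detect_spikes(
    trace: Trace,
    *,
    crossing_mV: float = 0.0,
    prominence_mV: float = 20.0,
    refractory_ms: float = 1.0,
    max_peak_lag_ms: float = 2.0,
    restrict_to_step: bool = True,
) -> SpikeTrain:
    """Detect APs as upward 0 mV crossings backed by a prominent local maximum.

    A crossing counts as a spike only if a local maximum with prominence
    >= ``prominence_mV`` follows within ``max_peak_lag_ms`` (slow large-
    amplitude oscillations are thereby rejected). Spike time is the crossing
    time; an empty train is a valid result.
    """
    v = trace.samples
    dt = trace.sampling_interval
    distance = max(int(round(refractory_ms * 1e-3 / dt)), 1)
    peaks, _ = find_peaks(v, height=crossing_mV, prominence=prominence_mV,
                          distance=distance)
    times, kept = [], []
    max_lag = int(round(max_peak_lag_ms * 1e-3 / dt))
    for pk in peaks:
        # walk back to the upward crossing of the detection level
        j = pk
        while j > 0 and v[j - 1] > crossing_mV:
            j -= 1
        if j == 0 or pk - j > max_lag:
            continue
        t_cross = (j - 1 + (crossing_mV - v[j - 1]) / (v[j] - v[j - 1])) * dt
        if restrict_to_step:
            t_on, t_off = trace.step_window
            if not (t_on <= t_cross <= t_off):
                continue
        if times and t_cross - times[-1] < refractory_ms * 1e-3:
            continue
        times.append(t_cross)
        kept.append(pk)
    return SpikeTrain(
        spike_times=np.array(times),
        spike_peak_indices=np.array(kept, dtype=int),
        step_amplitude=trace.step_amplitude,
    )


def find_rheobase(steps: StepProtocolSet, **detect_kwargs) -> float:
    """Smallest injected amplitude whose trace contains at least one spike (pA)."""
    spiking = []
    for amp, tr in steps:
        train = detect_spikes(tr, **detect_kwargs)
        spiking.append(train.n_spikes > 0)
    spiking = np.asarray(spiking)
    if not spiking.any():
        raise RheobaseNotFoundError("no step elicited a spike")
    k = int(np.argmax(spiking))
    if k == 0:
        warnings.warn("first step already spiking: rheobase is an upper bound",
                      LowerBoundWarning, stacklevel=2)
    return float(steps.injected_amplitudes[k])


def fi_curve(steps: StepProtocolSet, **detect_kwargs) -> FICurve:
    """Firing frequency (spike count / step duration) per injected amplitude."""
    counts = np.array([detect_spikes(tr, **detect_kwargs).n_spikes for _, tr in steps])
    return FICurve(
        currents=steps.injected_amplitudes.copy(),
        frequencies=counts / steps.step_duration,
    )


def io_gain(curve: FICurve, *, smooth: bool = False) -> tuple[float, float]:
    """Input-output gain: maximum finite-difference slope of the f-I curve.

    Returns ``(gain Hz/pA, current at max gain pA)``; the current is the
    midpoint of the maximizing interval. ``smooth=True`` applies a 3-point
    moving average to the frequencies first.
    """
    if curve.currents.size < 3:
        raise InsufficientDataError("io_gain needs >= 3 f-I points")
    f = curve.frequencies
    if smooth:
        f = np.convolve(np.pad(f, 1, mode="edge"), np.ones(3) / 3, mode="valid")
    slopes = np.diff(f) / np.diff(curve.currents)
    k = int(np.argmax(slopes))
    mid = 0.5 * (curve.currents[k] + curve.currents[k + 1])
    return float(slopes[k]), float(mid)


def max_firing_frequency(steps: StepProtocolSet, **detect_kwargs) -> float:
    """Maximum of the f-I curve (Hz); 0 for an all-silent family."""
    if len(steps) < 1:
        raise ProtocolError("need at least one step")
    return float(np.max(fi_curve(steps, **detect_kwargs).frequencies))
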