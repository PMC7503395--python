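"""Single-AP phase-plane metrics.

The phase plot pairs dV/dt (V/s, central differences) with voltage. AP
threshold is the voltage at the first upward crossing of the 20 V/s
criterion before the peak; max/min dV/dt are the global slope extrema;
half-width is the duration at half amplitude between threshold and peak.
The rising phase of the phase plot is decomposed into the initial-segment
(IS) component -- the first (lower-voltage) local dV/dt maximum, generated
at the axon initial segment -- and the somatodendritic (SD) component, the
absolute dV/dt maximum. Immature APs show a single (IS-only) component.
After-potentials are classified mono-phasic (slow AHP only) or tri-phasic
(fast AHP, ADP, slow AHP), with amplitudes referenced to AP threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .exceptions import NoAPError, ParameterError, ShapeError
from .trace_io import Trace

__all__ = [
    "PhasePlot",
    "APFeatures",
    "ISSDComponents",
    "AfterPotentialProfile",
    "phase_plot",
    "ap_threshold",
    "slope_extrema",
    "ap_half_width",
    "is_sd_components",
    "ahp_adp_profile",
    "analyze_ap",
]


@dataclass
class PhasePlot:
    """Paired, time-ordered (V, dV/dt) samples around one AP."""

    voltage: np.ndarray  # mV
    dvdt: np.ndarray  # V/s
    sampling_interval: float  # s
    window: tuple[float, float]  # s, in trace time
    peak_index: int  # index of the AP peak within the window arrays

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, float)
        self.dvdt = np.asarray(self.dvdt, float)
        if self.voltage.shape != self.dvdt.shape:
            raise ParameterError("voltage and dvdt must be paired")
        if not np.all(np.isfinite(self.dvdt)):
            raise ParameterError("dvdt contains non-finite values")


@dataclass
class APFeatures:
    threshold: float  # mV
    peak: float  # mV
    max_dvdt: float  # V/s
    min_dvdt: float  # V/s
    half_width: float  # ms
    amplitude: float  # mV, threshold -> peak

    def __post_init__(self) -> None:
        if not self.peak > self.threshold:
            raise ParameterError("peak must exceed threshold")
        if not (self.max_dvdt > 0 > self.min_dvdt):
            raise ParameterError("slope extrema must straddle zero")
        if not self.half_width > 0:
            raise ParameterError("half_width must be > 0")


@dataclass
class ISSDComponents:
    is_peak: float  # V/s
    sd_peak: float | None  # V/s, absent for monophasic APs
    ratio: float | None  # is/sd, absent for monophasic APs
    biphasic: bool
    is_voltage: float | None = None  # mV at the IS peak
    sd_voltage: float | None = None

    def __post_init__(self) -> None:
        if self.biphasic:
            if self.sd_peak is None or self.is_peak > self.sd_peak * (1 + 1e-12):
                raise ParameterError("biphasic requires is_peak <= sd_peak")
        elif self.sd_peak is not None:
            raise ParameterError("monophasic must not carry an SD peak")


@dataclass
class AfterPotentialProfile:
    shape_class: str  # 'mono' or 'tri'
    ahp_slow_mono: float  # mV relative to threshold (negative below)
    ahp_fast: float | None = None
    adp: float | None = None
    resolved: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shape_class == "mono":
            if self.ahp_fast is not None or self.adp is not None:
                raise ParameterError("mono-phasic profile carries only ahp_slow_mono")
        elif self.shape_class == "tri":
            if self.ahp_fast is None or self.adp is None:
                raise ParameterError("tri-phasic profile needs all three amplitudes")
        else:
            raise ParameterError(f"unknown shape_class {self.shape_class!r}")


def phase_plot(
    trace: Trace,
    spike_peak_index: int,
    *,
    window_ms: tuple[float, float] = (5.0, 10.0),
    smooth: bool = False,
    savgol_window: int = 7,
    savgol_order: int = 3,
) -> PhasePlot:
    """Phase plot (dV/dt vs V) in a window around one spike peak.

    ``window_ms = (before, after)`` the peak. dV/dt is computed by central
    differences on the raw voltage, or on a Savitzky-Golay-smoothed copy when
    ``smooth`` is set. The window is clipped at the trace limits only if it
    still contains the peak with >= 1 ms margin; otherwise a boundary error
    is raised.
    """
    dt = trace.sampling_interval
    k0 = spike_peak_index - int(round(window_ms[0] * 1e-3 / dt))
    k1 = spike_peak_index + int(round(window_ms[1] * 1e-3 / dt))
    if k0 < 0 or k1 > trace.n_samples:
        margin = int(round(1e-3 / dt))
        if spike_peak_index - max(k0, 0) < margin or min(k1, trace.n_samples) - spike_peak_index < margin:
            raise ParameterError("analysis window clipped at the trace boundary")
        k0, k1 = max(k0, 0), min(k1, trace.n_samples)
    v = trace.samples[k0:k1]
    if smooth:
        wl = min(savgol_window, v.size - (v.size + 1) % 2)
        v = savgol_filter(v, wl, savgol_order)
    dvdt = np.gradient(v, dt) * 1e-3  # mV/s -> V/s
    return PhasePlot(
        voltage=v,
        dvdt=dvdt,
        sampling_interval=dt,
        window=(k0 * dt, k1 * dt),
        peak_index=int(np.argmax(v)),
    )


def ap_threshold(pp: PhasePlot, criterion_vps: float = 20.0) -> float:
    """Voltage at the first upward crossing of the dV/dt criterion before the peak.

    Linearly interpolated between samples; the conventional criterion is
    dV/dt > 20 V/s.
    """
    d = pp.dvdt[: pp.peak_index + 1]
    v = pp.voltage[: pp.peak_index + 1]
    above = d >= criterion_vps
    if not above.any():
        raise NoAPError(f"dV/dt never reaches {criterion_vps} V/s before the peak")
    k = int(np.argmax(above))
    if k == 0:
        return float(v[0])
    frac = (criterion_vps - d[k - 1]) / (d[k] - d[k - 1])
    return float(v[k - 1] + frac * (v[k] - v[k - 1]))


def slope_extrema(pp: PhasePlot) -> tuple[float, float]:
    """Global (max_dvdt, min_dvdt) of the phase plot, in V/s."""
    return float(np.max(pp.dvdt)), float(np.min(pp.dvdt))


def ap_half_width(trace: Trace, threshold_mV: float, peak_index: int) -> float:
    """AP width (ms) at half amplitude between threshold and peak, interpolated."""
    v = trace.samples
    dt = trace.sampling_interval
    v_peak = v[peak_index]
    if not threshold_mV < v_peak:
        raise ParameterError("threshold must lie below the peak voltage")
    v_half = threshold_mV + 0.5 * (v_peak - threshold_mV)

    i = peak_index
    while i > 0 and v[i - 1] >= v_half:
        i -= 1
    if i == 0 and v[0] >= v_half:
        raise ShapeError("rising flank never crosses the half-amplitude level")
    t_rise = (i - 1 + (v_half - v[i - 1]) / (v[i] - v[i - 1])) * dt

    j = peak_index
    while j < v.size - 1 and v[j + 1] >= v_half:
        j += 1
    if j == v.size - 1:
        raise ShapeError("repolarization never reaches the half-amplitude level")
    t_fall = (j + (v_half - v[j]) / (v[j + 1] - v[j])) * dt
    return float((t_fall - t_rise) * 1e3)


def is_sd_components(
    pp: PhasePlot,
    *,
    min_prominence_vps: float = 10.0,
    criterion_vps: float = 20.0,
    smooth: bool = True,
    savgol_window: int = 7,
    savgol_order: int = 3,
) -> ISSDComponents:
    """Decompose the rising phase into IS and SD dV/dt components.

    Local dV/dt maxima over the rising phase (threshold crossing to peak) are
    found after optional Savitzky-Golay smoothing. With >= 2 maxima of
    prominence >= ``min_prominence_vps``: IS = first (lower-voltage) maximum,
    SD = absolute maximum, biphasic. With a single maximum the AP is
    monophasic and the maximum is attributed to the AIS.
    """
    d_full = pp.dvdt
    above = d_full[: pp.peak_index + 1] >= criterion_vps
    if not above.any():
        raise ShapeError("no rising phase exceeding the threshold criterion")
    k_thr = int(np.argmax(above))
    seg = d_full[k_thr : pp.peak_index + 1]
    if seg.size < 3:
        raise ShapeError("rising phase too short to decompose")
    d = seg
    if smooth and seg.size >= 5:
        wl = min(savgol_window, seg.size - (seg.size + 1) % 2)
        if wl >= savgol_order + 2:
            d = savgol_filter(seg, wl, savgol_order)
    peaks, _ = find_peaks(d, prominence=min_prominence_vps)
    v_seg = pp.voltage[k_thr : pp.peak_index + 1]
    if peaks.size == 0:
        # monotonically rising dvdt: the absolute maximum is the only component
        k = int(np.argmax(d))
        return ISSDComponents(is_peak=float(seg[k]), sd_peak=None, ratio=None,
                              biphasic=False, is_voltage=float(v_seg[k]))
    if peaks.size == 1:
        k = int(peaks[0])
        return ISSDComponents(is_peak=float(seg[k]), sd_peak=None, ratio=None,
                              biphasic=False, is_voltage=float(v_seg[k]))
    k_is = int(peaks[0])
    k_sd = int(peaks[np.argmax(d[peaks])])
    is_peak = float(seg[k_is])
    sd_peak = float(max(seg[k_sd], is_peak))
    return ISSDComponents(
        is_peak=is_peak, sd_peak=sd_peak, ratio=is_peak / sd_peak, biphasic=True,
        is_voltage=float(v_seg[k_is]), sd_voltage=float(v_seg[k_sd]),
    )


def ahp_adp_profile(
    trace: Trace,
    spike_peak_index: int,
    threshold_mV: float,
    *,
    window_ms: float = 100.0,
    min_prominence_mV: float = 0.5,
    smooth_ms: float = 1.0,
    next_spike_peak_index: int | None = None,
) -> AfterPotentialProfile:
    """Classify the after-potential as mono- or tri-phasic and measure it.

    The analysis window runs from the downward threshold recrossing after the
    peak to ``window_ms`` later (or to the next spike). After-potentials are
    millisecond-scale, so the window is low-passed with a ``smooth_ms``
    moving average before peak finding (recording noise otherwise fabricates
    prominent extrema). Tri-phasic means: a local minimum (fast AHP), then a
    local maximum (ADP), then a later minimum (slow AHP), all with prominence
    >= ``min_prominence_mV``. Amplitudes are signed voltages relative to
    threshold (negative below).
    """
    v = trace.samples
    dt = trace.sampling_interval
    k = spike_peak_index
    end_limit = v.size if next_spike_peak_index is None else next_spike_peak_index
    while k < end_limit - 1 and v[k] > threshold_mV:
        k += 1
    if v[k] > threshold_mV:
        raise ShapeError("voltage never recrosses threshold after the spike")
    k_end = min(k + int(round(window_ms * 1e-3 / dt)), end_limit)
    if (k_end - k) * dt < 5e-3:
        return AfterPotentialProfile(
            shape_class="mono",
            ahp_slow_mono=float(np.min(v[k:k_end]) - threshold_mV) if k_end > k else 0.0,
            resolved=False, flags=["window_truncated"],
        )
    rel = v[k:k_end] - threshold_mV
    # locate extrema on a low-passed copy, measure amplitudes on the raw course
    rel_s = rel
    width = int(round(smooth_ms * 1e-3 / dt))
    if width > 1 and rel.size > 2 * width:
        pad = width // 2
        kernel = np.ones(width) / width
        rel_s = np.convolve(np.pad(rel, pad, mode="reflect"), kernel,
                            mode="same")[pad : pad + rel.size]

    def snap(idx, arr, mode):
        lo, hi = max(idx - width, 0), min(idx + width + 1, arr.size)
        off = np.argmin(arr[lo:hi]) if mode == "min" else np.argmax(arr[lo:hi])
        return lo + int(off)

    minima, _ = find_peaks(-rel_s, prominence=min_prominence_mV)
    if minima.size:
        m1 = snap(int(minima[0]), rel, "min")
        maxima, _ = find_peaks(rel_s, prominence=min_prominence_mV)
        maxima = maxima[maxima > m1]
        if maxima.size:
            m2 = snap(int(maxima[0]), rel, "max")
            ahp_slow = float(np.min(rel[m2:]))
            return AfterPotentialProfile(
                shape_class="tri",
                ahp_slow_mono=ahp_slow,
                ahp_fast=float(rel[m1]),
                adp=float(rel[m2]),
            )
    return AfterPotentialProfile(shape_class="mono", ahp_slow_mono=float(np.min(rel)))


def analyze_ap(
    trace: Trace,
    spike_peak_index: int,
    *,
    criterion_vps: float = 20.0,
    window_ms: tuple[float, float] = (5.0, 10.0),
) -> APFeatures:
    """Convenience: threshold, slope extrema, half-width and amplitude of one AP."""
    pp = phase_plot(trace, spike_peak_index, window_ms=window_ms)
    thr = ap_threshold(pp, criterion_vps)
    mx, mn = slope_extrema(pp)
    hw = ap_half_width(trace, thr, spike_peak_index)
    peak = float(trace.samples[spike_peak_index])
    return APFeatures(threshold=thr, peak=peak, max_dvdt=mx, min_dvdt=mn,
                      half_width=hw, amplitude=peak - thr)
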