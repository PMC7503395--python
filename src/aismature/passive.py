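"""Passive membrane properties from the voltage-clamp seal test.

The estimators follow standard membrane-test practice on a small (-5 mV)
hyperpolarizing step: the peak capacitive current I_max gives the series
resistance (Rs = |step| / |I_max|), the steady-state leak current I_mem
gives the input resistance (R_In = |step| / |I_mem|), and the cell
capacitance is the ratio of the transient time constant to the series
resistance (Cm = tau / Rs).

Note that these printed estimators are deliberately kept as-is even though
they carry a known bias for the underlying RC circuit: R_In as defined
includes the series resistance (R_In = Rs + Rm), and consequently
Cm = tau/Rs = Cm_true * Rm/(Rs + Rm). The bias is documented and asserted in
the test suite rather than hidden; ``corrected=True`` returns the unbiased
circuit values instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import (
    BaselineDriftWarning,
    ParameterError,
    ProtocolError,
    QualityError,
    ReliabilityWarning,
)
from .trace_io import Trace

__all__ = ["PassiveProperties", "IVCurve", "analyze_seal_test", "measure_erest", "extract_iv"]


@dataclass
class PassiveProperties:
    """Seal-test estimates in the units the protocol reports (MOhm, pF, ms, pA)."""

    Rs: float
    Rin: float
    Cm: float
    tau: float
    Imax: float
    Imem: float
    fit_r2: float
    Erest: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.Rs, self.Rin, self.Cm, self.tau) <= 0:
            raise ParameterError("Rs, Rin, Cm and tau must be > 0")
        if abs(self.Imax) < abs(self.Imem) * (1 - 1e-9):
            raise ParameterError("|Imax| must be >= |Imem|")


@dataclass
class IVCurve:
    """Peak-inward and steady-state currents per command voltage."""

    command_voltages: np.ndarray
    peak_inward: np.ndarray
    steady_state: np.ndarray

    def __post_init__(self) -> None:
        self.command_voltages = np.asarray(self.command_voltages, float)
        self.peak_inward = np.asarray(self.peak_inward, float)
        self.steady_state = np.asarray(self.steady_state, float)
        if not (
            self.command_voltages.size == self.peak_inward.size == self.steady_state.size
        ):
            raise ProtocolError("I-V arrays must have equal lengths")
        if self.command_voltages.size >= 2 and np.any(np.diff(self.command_voltages) <= 0):
            raise ProtocolError("command voltages must be strictly increasing")


def _exp_decay(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def analyze_seal_test(
    trace: Trace,
    step_mV: float | None = None,
    *,
    baseline_ms: float = 10.0,
    steady_frac: float = 0.2,
    imax_mode: str = "extrapolate",
    corrected: bool = False,
    min_r2: float = 0.9,
) -> PassiveProperties:
    """Estimate Rs, Rin, Cm and tau from one seal-test current trace.

    The capacitive transient is fitted with a single exponential
    (log-linear initialization, then least squares) between two samples
    after the raw extremum and the point where the transient has decayed to
    5% of its amplitude above the steady state. By default I_max is the fit
    back-extrapolated to the step onset, which removes the sampling-interval
    bias of the raw extremum (``imax_mode="raw"`` keeps the raw one).
    """
    if trace.signal_kind != "current":
        raise ParameterError("seal-test analysis needs a current trace")
    if imax_mode not in ("extrapolate", "raw"):
        raise ParameterError("imax_mode must be 'extrapolate' or 'raw'")
    dt = trace.sampling_interval
    t_on, t_off = trace.step_window
    k_on, k_off = trace.index_at(t_on), min(trace.index_at(t_off), trace.n_samples)
    if (k_off - k_on) * dt < 2e-3:
        raise ParameterError("need >= 2 ms of post-step data")
    i = trace.samples
    flags: list[str] = []

    k_base0 = max(0, k_on - int(round(baseline_ms * 1e-3 / dt)))
    baseline = float(np.mean(i[k_base0:k_on])) if k_on > k_base0 else 0.0
    noise_sd = float(np.std(i[k_base0:k_on])) if k_on - k_base0 > 2 else 0.0

    step = i[k_on:k_off] - baseline
    n_steady = max(int(round(steady_frac * step.size)), 1)
    imem = float(np.mean(step[-n_steady:]))

    # capacitive transient: extremum with the sign of the step, early in the step
    sign = np.sign(step_mV if step_mV is not None else trace.step_amplitude) or -1.0
    search = step[: max(step.size // 2, 8)]
    k_peak = int(np.argmax(sign * search))
    i_peak_raw = float(step[k_peak])

    # fit window: [peak + 2 samples, decay to 5% above Imem]
    resid = sign * (step - imem)
    amp0 = sign * (i_peak_raw - imem)
    k_fit0 = k_peak + 2
    below = np.flatnonzero(resid[k_fit0:] < 0.05 * amp0)
    k_fit1 = k_fit0 + (int(below[0]) if below.size else resid.size - k_fit0)
    if k_fit1 - k_fit0 < 4:
        k_fit1 = min(k_fit0 + 4, step.size)
    if k_fit1 - k_fit0 < 3:
        raise QualityError("transient too short to fit at this sampling rate")
    tt = (np.arange(k_fit0, k_fit1) - 0.0) * dt  # time from step onset
    yy = step[k_fit0:k_fit1] - imem

    # log-linear initialization on the same-signed portion
    pos = sign * yy > 0
    if pos.sum() < 3:
        raise QualityError("transient lost in noise: cannot fit tau")
    slope, intercept = np.polyfit(tt[pos], np.log(sign * yy[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else (tt[-1] - tt[0])
    a0 = sign * np.exp(intercept)
    try:
        popt, _ = curve_fit(
            _exp_decay, tt, yy, p0=(a0, max(tau0, dt), 0.0),
            maxfev=10000,
        )
        a_fit, tau_fit, c_fit = popt
    except RuntimeError as err:  # pragma: no cover - pathological traces
        raise QualityError(f"exponential fit failed: {err}") from None
    if tau_fit <= 0:
        raise QualityError("non-physical (non-positive) fitted tau")
    ss_res = float(np.sum((yy - _exp_decay(tt, *popt)) ** 2))
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if r2 < min_r2:
        raise QualityError(f"transient fit r^2 = {r2:.3f} < {min_r2}")

    if imax_mode == "extrapolate":
        imax = float(a_fit + c_fit + imem)
    else:
        imax = i_peak_raw

    if noise_sd > 0 and abs(imem) < 3 * noise_sd / np.sqrt(n_steady):
        flags.append("rin_unreliable")
        warnings.warn("steady-state current below noise floor; Rin unreliable",
                      ReliabilityWarning, stacklevel=2)

    v = abs(step_mV if step_mV is not None else trace.step_amplitude) * 1e-3  # V
    rs_ohm = v / abs(imax * 1e-12)
    rin_ohm = v / abs(imem * 1e-12)
    tau_s = tau_fit
    rs_M = rs_ohm * 1e-6
    rin_M = rin_ohm * 1e-6
    cm_pF = tau_s / rs_ohm * 1e12

    if corrected:
        # undo the series-resistance bias: tau = Cm*(Rs||Rm), Rm = Rin - Rs
        rm_M = rin_M - rs_M
        if rm_M <= 0:
            raise QualityError("corrected mode needs Rin > Rs")
        cm_pF = tau_s / (rs_ohm * rm_M / rin_M) * 1e12

    return PassiveProperties(
        Rs=rs_M, Rin=rin_M, Cm=cm_pF, tau=tau_fit * 1e3,
        Imax=imax, Imem=imem, fit_r2=r2, flags=flags,
    )


def measure_erest(
    trace: Trace, *, min_baseline_s: float = 0.05, drift_limit_mV: float = 2.0
) -> float:
    """Resting potential: mean voltage over the zero-current baseline window.

    A drift larger than ``drift_limit_mV`` between the first and last fifth
    of the window raises a :class:`BaselineDriftWarning`.
    """
    if trace.signal_kind != "voltage":
        raise ParameterError("Erest needs a current-clamp (voltage) trace")
    t0, t1 = trace.baseline_window
    if t1 - t0 < min_baseline_s:
        raise ParameterError(f"baseline window shorter than {min_baseline_s * 1e3:.0f} ms")
    k0, k1 = trace.index_at(t0), trace.index_at(t1)
    seg = trace.samples[k0:k1]
    fifth = max(seg.size // 5, 1)
    drift = float(np.mean(seg[-fifth:]) - np.mean(seg[:fifth]))
    if abs(drift) > drift_limit_mV:
        warnings.warn(
            f"baseline drifts {drift:+.2f} mV across the window",
            BaselineDriftWarning, stacklevel=2,
        )
    return float(np.mean(seg))


def extract_iv(
    traces: list[Trace],
    *,
    early_window_s: float = 0.05,
    steady_frac: float = 0.1,
    leak: str = "none",
) -> IVCurve:
    """Minimal I-V extraction from a family of voltage-clamp steps.

    Per step: peak inward = minimum of the baseline-subtracted current in the
    first ``early_window_s`` of the step; steady state = mean over the final
    ``steady_frac`` of the step. ``leak='linear'`` subtracts a linear leak
    estimated from the most hyperpolarized steps (those at or below the
    holding level); ``'none'`` reports raw currents.
    """
    if not traces:
        raise ProtocolError("empty voltage-clamp set")
    if leak not in ("none", "linear"):
        raise ParameterError("leak must be 'none' or 'linear'")
    volts = np.array([tr.holding_level + tr.step_amplitude for tr in traces])
    if np.any(np.diff(volts) <= 0):
        raise ProtocolError("command voltages must be strictly increasing")
    peaks, steadies = [], []
    for tr in traces:
        k_on, k_off = tr.index_at(tr.step_window[0]), tr.index_at(tr.step_window[1])
        k_off = min(k_off, tr.n_samples)
        base = float(np.mean(tr.samples[: k_on])) if k_on > 1 else 0.0
        step = tr.samples[k_on:k_off] - base
        k_early = max(int(round(early_window_s / tr.sampling_interval)), 1)
        peaks.append(float(np.min(step[:k_early])))
        n_st = max(int(round(steady_frac * step.size)), 1)
        steadies.append(float(np.mean(step[-n_st:])))
    peaks = np.asarray(peaks)
    steadies = np.asarray(steadies)
    if leak == "linear":
        sub = volts <= traces[0].holding_level
        if sub.sum() >= 2:
            coef = np.polyfit(volts[sub], steadies[sub], 1)
            leak_i = np.polyval(coef, volts)
            peaks = peaks - leak_i
            steadies = steadies - leak_i
    return IVCurve(command_voltages=volts, peak_inward=peaks, steady_state=steadies)
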