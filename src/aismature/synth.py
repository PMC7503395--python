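"""Ground-truth synthetic data: seal tests, step protocols, AIS profiles, cohorts.

Every generator embeds its exact ground truth in the object it returns
(``Trace.meta`` / ``IntensityProfile.meta`` / the cohort manifest), so that
recovery tests never have to re-derive truth from the signal. All randomness
flows from an explicit per-call seed; there is no global random state.

The cohort generator emulates the study design of the source recordings:
five postnatal age groups of rat motor-cortex layer-V neurons (~20 cells
from >= 3 animals per group for electrophysiology; hundreds of AIS per group
from 4-6 animals for morphometry), with passive properties, threshold
depolarization, AIS geometry and upstroke velocity drawn from per-group
distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .exceptions import AismatureWarning, GeometryError, ParameterError, StabilityError
from .morphometry import IntensityProfile
from .trace_io import StepProtocolSet, Trace

__all__ = [
    "RCCircuitParams",
    "TwoCompartmentParams",
    "AISGeometryTruth",
    "GroupSpec",
    "CohortSpec",
    "CellData",
    "Cohort",
    "simulate_seal_test",
    "simulate_lif_steps",
    "lif_rheobase",
    "simulate_two_compartment",
    "generate_ais_profile",
    "generate_ais_image",
    "generate_cohort",
    "save_cohort",
    "DEFAULT_AGE_GROUPS",
]


# --------------------------------------------------------------------------
# seal test (RC circuit)

@dataclass
class RCCircuitParams:
    """Series resistance, membrane resistance and capacitance of the seal-test circuit."""

    Rs: float  # MOhm
    Rm: float  # MOhm
    Cm_true: float  # pF

    def __post_init__(self) -> None:
        if min(self.Rs, self.Rm, self.Cm_true) <= 0:
            raise ParameterError("Rs, Rm and Cm_true must all be > 0")
        if self.Rm <= self.Rs:
            warnings.warn("Rm <= Rs: unusual circuit", AismatureWarning, stacklevel=2)

    @property
    def tau_s(self) -> float:
        """Transient time constant Cm * (Rs || Rm), in seconds."""
        rp = self.Rs * self.Rm / (self.Rs + self.Rm) * 1e6
        return self.Cm_true * 1e-12 * rp


def simulate_seal_test(
    params: RCCircuitParams,
    step_mV: float = -5.0,
    duration: float = 0.06,
    sampling_interval: float = 1e-4,
    noise_sd: float = 0.0,
    seed: int | None = None,
    *,
    step_on_s: float = 0.01,
    holding_mV: float = -70.0,
    baseline_offset_pA: float = 0.0,
) -> Trace:
    """Simulate the current response to a small voltage-clamp test step.

    The pipette (series) resistance Rs feeds the membrane RC; a step of
    ``step_mV`` produces a current jump to ``V/Rs`` that relaxes with
    ``tau = Cm * Rs*Rm/(Rs+Rm)`` toward the steady leak ``V/(Rs+Rm)``:

        I(t) = V/(Rs+Rm) + (V/Rs - V/(Rs+Rm)) * exp(-t/tau)

    Gaussian noise of ``noise_sd`` pA is added. Ground truth (parameters and
    the closed-form I0/Iss/tau) is stored in ``Trace.meta``.
    """
    if sampling_interval <= 0 or duration <= step_on_s:
        raise ParameterError("need sampling_interval > 0 and duration > step_on_s")
    tau = params.tau_s
    flags = []
    if duration - step_on_s < 5 * tau:
        flags.append("short_record")
        warnings.warn("record covers < 5 tau of decay", AismatureWarning, stacklevel=2)

    v = step_mV * 1e-3
    i_ss = v / ((params.Rs + params.Rm) * 1e6)  # A
    i_0 = v / (params.Rs * 1e6)

    n = int(round(duration / sampling_interval))
    # align the step onset to the sample grid
    k_on = int(round(step_on_s / sampling_interval))
    t = np.arange(n) * sampling_interval
    i = np.full(n, baseline_offset_pA * 1e-12)
    ts = t[k_on:] - t[k_on]
    i[k_on:] += i_ss + (i_0 - i_ss) * np.exp(-ts / tau)
    i_pA = i * 1e12
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i_pA = i_pA + rng.normal(0.0, noise_sd, size=n)

    return Trace(
        samples=i_pA,
        sampling_interval=sampling_interval,
        signal_kind="current",
        baseline_window=(0.0, k_on * sampling_interval),
        step_window=(k_on * sampling_interval, n * sampling_interval),
        step_amplitude=step_mV,
        holding_level=holding_mV,
        meta={
            "truth": {
                "Rs_Mohm": params.Rs,
                "Rm_Mohm": params.Rm,
                "Cm_pF": params.Cm_true,
                "tau_ms": tau * 1e3,
                "I0_pA": i_0 * 1e12,
                "Iss_pA": i_ss * 1e12,
            },
            "flags": flags,
        },
    )


# --------------------------------------------------------------------------
# leaky-integrate-and-fire step responses

def lif_rheobase(
    rin_Mohm: float, tau_m_ms: float, threshold_depol_mV: float, step_duration_s: float
) -> float:
    """Continuous (un-quantized) rheobase of the LIF cell, in pA.

    The subthreshold peak of a step I lasting T is I*Rin*(1 - exp(-T/tau)); the
    smallest current whose peak reaches the threshold depolarization is
    I* = depol / (Rin * (1 - exp(-T/tau))).
    """
    frac = 1.0 - math.exp(-step_duration_s * 1e3 / tau_m_ms)
    return threshold_depol_mV / (rin_Mohm * 1e-3 * frac)


def _lif_ap_shape(threshold_mV, reset_mV, peak_mV, rise_ms, fall_ms):
    def ap_voltage(dt_ms_from_onset):
        """Pasted stereotyped AP: half-cosine rise then half-cosine fall."""
        t = np.asarray(dt_ms_from_onset)
        v = np.empty_like(t, dtype=float)
        rising = t < rise_ms
        v[rising] = threshold_mV + (peak_mV - threshold_mV) * 0.5 * (
            1 - np.cos(np.pi * t[rising] / rise_ms)
        )
        tf = t[~rising] - rise_ms
        v[~rising] = reset_mV + (peak_mV - reset_mV) * 0.5 * (1 + np.cos(np.pi * tf / fall_ms))
        return v

    return ap_voltage


def simulate_lif_steps(
    rin_Mohm: float,
    tau_m_ms: float,
    erest_mV: float,
    threshold_depol_mV: float,
    amplitudes_pA,
    *,
    step_duration_s: float = 0.5,
    sampling_interval: float = 1e-4,
    baseline_s: float = 0.1,
    tail_s: float = 0.05,
    inter_step_hold: float = 0.5,
    noise_sd_mV: float = 0.0,
    seed: int | None = None,
    ap_peak_mV: float = 30.0,
    ap_rise_ms: float = 1.0,
    ap_fall_ms: float = 2.0,
    ap_max_dvdt_Vps: float | None = None,
) -> StepProtocolSet:
    """Current-clamp step family from a leaky integrate-and-fire cell.

    Subthreshold voltage follows the closed form
    ``V(t) = Erest + I*Rin*(1 - exp(-t/tau))``; at each threshold crossing a
    stereotyped AP is pasted (half-cosine rise to ``ap_peak_mV``, half-cosine
    fall back to the reset = Erest), after which integration restarts. If
    ``ap_max_dvdt_Vps`` is given, the rise duration is set so the pasted
    upstroke has exactly that peak dV/dt. The continuous rheobase is recorded
    in the protocol metadata.
    """
    if tau_m_ms <= 0 or threshold_depol_mV <= 0 or rin_Mohm <= 0:
        raise ParameterError("rin, tau_m and threshold_depol must be > 0")
    amplitudes = np.asarray(amplitudes_pA, dtype=float)
    tau_s = tau_m_ms * 1e-3
    vth = erest_mV + threshold_depol_mV
    rise_ms = ap_rise_ms
    if ap_max_dvdt_Vps is not None:
        # half-cosine rise: peak dV/dt = pi*(peak - threshold)/(2*rise)
        rise_ms = math.pi * (ap_peak_mV - vth) / (2.0 * ap_max_dvdt_Vps)
    ap_dur_s = (rise_ms + ap_fall_ms) * 1e-3
    ap_v = _lif_ap_shape(vth, erest_mV, ap_peak_mV, rise_ms, ap_fall_ms)

    rng = np.random.default_rng(seed) if noise_sd_mV > 0 else None
    n = int(round((baseline_s + step_duration_s + tail_s) / sampling_interval))
    k_on = int(round(baseline_s / sampling_interval))
    k_off = int(round((baseline_s + step_duration_s) / sampling_interval))
    t = np.arange(n) * sampling_interval
    t_on, t_off = t[k_on], k_off * sampling_interval

    traces = []
    for amp in amplitudes:
        drive = amp * rin_Mohm * 1e-3  # mV at infinity
        v = np.full(n, float(erest_mV), dtype=float)
        spike_times = []
        cursor = t_on
        while cursor < t_off:
            if drive > threshold_depol_mV:
                t_cross = cursor - tau_s * math.log(1.0 - threshold_depol_mV / drive)
            else:
                t_cross = math.inf
            seg_end = min(t_cross, t_off)
            sel = (t >= cursor) & (t < seg_end)
            v[sel] = erest_mV + drive * (1.0 - np.exp(-(t[sel] - cursor) / tau_s))
            if t_cross >= t_off:
                # relax back to rest after the step from the voltage reached at t_off
                v_off = erest_mV + drive * (1.0 - math.exp(-(t_off - cursor) / tau_s))
                sel = t >= t_off
                v[sel] = erest_mV + (v_off - erest_mV) * np.exp(-(t[sel] - t_off) / tau_s)
                break
            spike_times.append(t_cross)
            sel = (t >= t_cross) & (t < t_cross + ap_dur_s)
            v[sel] = ap_v((t[sel] - t_cross) * 1e3)
            cursor = t_cross + ap_dur_s
        if rng is not None:
            v = v + rng.normal(0.0, noise_sd_mV, size=n)
        traces.append(
            Trace(
                samples=v,
                sampling_interval=sampling_interval,
                signal_kind="voltage",
                baseline_window=(0.0, t_on),
                step_window=(t_on, t_off),
                step_amplitude=float(amp),
                holding_level=0.0,
                meta={"true_spike_times_s": spike_times},
            )
        )

    return StepProtocolSet(
        traces=traces,
        injected_amplitudes=amplitudes,
        step_duration=step_duration_s,
        inter_step_hold=inter_step_hold,
        meta={
            "truth": {
                "rin_Mohm": rin_Mohm,
                "tau_m_ms": tau_m_ms,
                "erest_mV": erest_mV,
                "threshold_depol_mV": threshold_depol_mV,
                "threshold_mV": vth,
                "rheobase_pA": lif_rheobase(
                    rin_Mohm, tau_m_ms, threshold_depol_mV, step_duration_s
                ),
                "ap_max_dvdt_Vps": math.pi * (ap_peak_mV - vth) / (2.0 * rise_ms),
            }
        },
    )


# --------------------------------------------------------------------------
# two-compartment conductance-based model (AIS + soma)

@dataclass
class TwoCompartmentParams:
    """Soma + AIS compartments coupled by an axial conductance.

    Units: capacitance pF, conductance nS, voltage mV, time ms (then
    dV/dt = I/C comes out in mV/ms = V/s directly). Sodium activation is
    instantaneous (m_inf^3), inactivation h and potassium activation n are
    first order. The AIS compartment is small and sodium-dense, so its local
    spike precedes and precharges the somatic one -- the source of the
    biphasic somatic phase plot.
    """

    C_soma: float = 40.0
    C_ais: float = 2.0
    g_leak_soma: float = 4.0
    g_leak_ais: float = 0.2
    E_leak: float = -75.0
    g_axial: float = 60.0
    gNa_ais: float = 600.0
    gNa_soma: float = 150.0
    gK_ais: float = 120.0
    gK_soma: float = 150.0
    E_Na: float = 60.0
    E_K: float = -90.0
    vm_half: float = -28.0
    km: float = 6.0
    vm_half_shift_ais: float = -11.0  # AIS Nav activate at lower voltage
    vh_half: float = -45.0
    kh: float = 6.0
    tau_h_ms: float = 1.5
    vn_half: float = -25.0
    kn: float = 9.0
    tau_n_ms: float = 3.0
    v_init: float = -75.0

    def __post_init__(self) -> None:
        if min(self.C_soma, self.C_ais) <= 0:
            raise ParameterError("capacitances must be > 0")
        if min(self.gNa_ais, self.gNa_soma, self.gK_ais, self.gK_soma,
               self.g_leak_soma, self.g_leak_ais) < 0:
            raise ParameterError("conductances must be >= 0")
        if self.g_axial <= 0:
            raise ParameterError("g_axial must be > 0")
        if 0 in (self.km, self.kh, self.kn):
            raise ParameterError("kinetic slopes must be nonzero")


def _sigmoid(v, half, slope):
    return 1.0 / (1.0 + np.exp(-(v - half) / slope))


def simulate_two_compartment(
    params: TwoCompartmentParams,
    amplitudes_pA,
    *,
    dt_ms: float = 0.005,
    step_duration_s: float = 0.05,
    baseline_s: float = 0.01,
    tail_s: float = 0.01,
    seed: int | None = None,
    record_states: bool = False,
) -> StepProtocolSet:
    """Deterministic RK4 integration of the soma+AIS model; somatic V returned.

    Current steps are injected into the soma. With the default sodium
    distribution (gNa_ais >> gNa_soma) the somatic phase plot shows two
    rising-phase dV/dt maxima: the initial-segment (IS) hump followed by the
    somatodendritic (SD) peak. Divergence (|V| > 200 mV) raises
    :class:`StabilityError` naming the time step.
    """
    if dt_ms > 0.01:
        raise ParameterError("dt_ms must be <= 0.01 ms for this stiff system")
    p = params
    amplitudes = np.asarray(amplitudes_pA, dtype=float)
    n = int(round((baseline_s + step_duration_s + tail_s) * 1e3 / dt_ms))
    k_on = int(round(baseline_s * 1e3 / dt_ms))
    k_off = int(round((baseline_s + step_duration_s) * 1e3 / dt_ms))

    def deriv(y, i_inj):
        vs, va, hs, ha, ns_, na_ = y
        ms = _sigmoid(vs, p.vm_half, p.km)
        ma = _sigmoid(va, p.vm_half + p.vm_half_shift_ais, p.km)
        i_s = (
            -p.g_leak_soma * (vs - p.E_leak)
            - p.gNa_soma * ms**3 * hs * (vs - p.E_Na)
            - p.gK_soma * ns_**4 * (vs - p.E_K)
            + p.g_axial * (va - vs)
            + i_inj
        )
        i_a = (
            -p.g_leak_ais * (va - p.E_leak)
            - p.gNa_ais * ma**3 * ha * (va - p.E_Na)
            - p.gK_ais * na_**4 * (va - p.E_K)
            + p.g_axial * (vs - va)
        )
        return np.array([
            i_s / p.C_soma,
            i_a / p.C_ais,
            (_sigmoid(-vs, -p.vh_half, p.kh) - hs) / p.tau_h_ms,
            (_sigmoid(-va, -p.vh_half, p.kh) - ha) / p.tau_h_ms,
            (_sigmoid(vs, p.vn_half, p.kn) - ns_) / p.tau_n_ms,
            (_sigmoid(va, p.vn_half, p.kn) - na_) / p.tau_n_ms,
        ])

    traces = []
    for amp in amplitudes:
        y = np.array([
            p.v_init, p.v_init,
            _sigmoid(-p.v_init, -p.vh_half, p.kh),
            _sigmoid(-p.v_init, -p.vh_half, p.kh),
            _sigmoid(p.v_init, p.vn_half, p.kn),
            _sigmoid(p.v_init, p.vn_half, p.kn),
        ])
        vs_rec = np.empty(n)
        states = np.empty((n, 6)) if record_states else None
        for k in range(n):
            i_inj = amp if k_on <= k < k_off else 0.0
            vs_rec[k] = y[0]
            if states is not None:
                states[k] = y
            k1 = deriv(y, i_inj)
            k2 = deriv(y + 0.5 * dt_ms * k1, i_inj)
            k3 = deriv(y + 0.5 * dt_ms * k2, i_inj)
            k4 = deriv(y + dt_ms * k3, i_inj)
            y = y + (dt_ms / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if abs(y[0]) > 200 or abs(y[1]) > 200:
                raise StabilityError(
                    f"integration diverged at step {amp} pA with dt={dt_ms} ms"
                )
        meta = {"amp_pA": float(amp)}
        if record_states:
            meta["states"] = states
            meta["state_names"] = ["v_soma", "v_ais", "h_soma", "h_ais", "n_soma", "n_ais"]
        traces.append(
            Trace(
                samples=vs_rec,
                sampling_interval=dt_ms * 1e-3,
                signal_kind="voltage",
                baseline_window=(0.0, baseline_s),
                step_window=(baseline_s, baseline_s + step_duration_s),
                step_amplitude=float(amp),
                meta=meta,
            )
        )
    return StepProtocolSet(
        traces=traces,
        injected_amplitudes=amplitudes,
        step_duration=step_duration_s,
        inter_step_hold=0.0,
        meta={"params": asdict(params), "dt_ms": dt_ms},
    )


# --------------------------------------------------------------------------
# AIS intensity profiles and images

@dataclass
class AISGeometryTruth:
    """Ground-truth geometry for one synthetic AIS fluorescence profile."""

    start_um: float
    end_um: float
    diameter_um: float = 1.2
    plateau_intensity: float = 1.0
    background_intensity: float = 0.05
    psf_sigma_um: float = 0.4
    pixel_size_um: float = 0.1
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.end_um > self.start_um >= 0):
            raise ParameterError("need end > start >= 0")
        if not (self.plateau_intensity > self.background_intensity >= 0):
            raise ParameterError("need plateau > background >= 0")
        if self.pixel_size_um <= 0 or self.psf_sigma_um < 0:
            raise ParameterError("pixel size must be > 0 and PSF sigma >= 0")

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um


def _edge_model(x, truth: AISGeometryTruth):
    """Ideal plateau convolved with a Gaussian PSF, evaluated at x (um)."""
    a = truth.plateau_intensity - truth.background_intensity
    if truth.psf_sigma_um == 0:
        core = ((x >= truth.start_um) & (x < truth.end_um)).astype(float)
    else:
        s = truth.psf_sigma_um
        core = ndtr((x - truth.start_um) / s) - ndtr((x - truth.end_um) / s)
    return truth.background_intensity + a * core


def generate_ais_profile(
    truth: AISGeometryTruth,
    n_pixels: int | None = None,
    seed: int | None = None,
    *,
    margin_um: float = 2.0,
) -> IntensityProfile:
    """Plateau-plus-blur line profile with additive Gaussian noise (clipped at 0).

    The profile spans from 0 (soma-proximal origin) past the distal edge by
    ``max(3 sigma, margin_um)``; it must also cover ``start - 3 sigma``.
    """
    span_needed = truth.end_um + max(3 * truth.psf_sigma_um, margin_um)
    if n_pixels is None:
        n_pixels = int(math.ceil(span_needed / truth.pixel_size_um)) + 1
    x = np.arange(n_pixels) * truth.pixel_size_um
    if x[-1] < truth.end_um + 3 * truth.psf_sigma_um:
        raise GeometryError("profile span does not cover end + 3 sigma")
    y = _edge_model(x, truth)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=y.size)
        y = np.clip(y, 0.0, None)
    return IntensityProfile(
        positions=x,
        intensities=y,
        pixel_size=truth.pixel_size_um,
        meta={"truth": asdict(truth)},
    )


def generate_ais_image(
    truth: AISGeometryTruth,
    shape: tuple[int, int] = (64, 256),
    row: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """2-D image with one straight horizontal AIS (same edge model in x and y)."""
    h, w = shape
    if row is None:
        row = h // 2
    x = np.arange(w) * truth.pixel_size_um
    y = (np.arange(h) - row) * truth.pixel_size_um
    along = _edge_model(x, truth) - truth.background_intensity
    r = truth.diameter_um / 2.0
    if truth.psf_sigma_um == 0:
        across = ((y >= -r) & (y < r)).astype(float)
    else:
        s = truth.psf_sigma_um
        across = ndtr((y + r) / s) - ndtr((y - r) / s)
    img = truth.background_intensity + np.outer(across, along)
    if truth.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = np.clip(img + rng.normal(0.0, truth.noise_sd, size=img.shape), 0.0, None)
    return img


# --------------------------------------------------------------------------
# age cohorts

@dataclass
class GroupSpec:
    """Parameter distributions for one age group; (mean, sd) tuples, physical units."""

    label: str
    n_animals: int = 4
    n_cells_per_animal: int = 6
    n_ais_per_animal: int = 100
    cm_pF: tuple = (120.0, 25.0)
    rm_Mohm: tuple = (300.0, 60.0)
    rs_Mohm: tuple = (8.0, 1.5)
    erest_mV: tuple = (-65.0, 3.0)
    threshold_depol_mV: tuple = (16.0, 2.0)
    ais_length_um: tuple = (20.0, 2.0)
    ais_length_within_sd_um: float = 3.0
    ais_diameter_um: tuple = (1.2, 0.12)
    is_dvdt_Vps: tuple = (200.0, 30.0)

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.n_cells_per_animal < 1:
            raise ParameterError("need >= 1 animal and >= 1 cell per animal")


#: Five age groups emulating postnatal maturation of motor-cortex layer-V
#: neurons: capacitance rises and input resistance falls steeply over the
#: first three postnatal weeks then plateaus; resting potential and (because
#: depolarization-at-rheobase stays ~16 mV) AP threshold hyperpolarize by
#: ~12 mV; the AIS elongates from ~13-14 um to ~28 um with > 80% of the
#: elongation complete by week three, widening as it grows; the IS-component
#: upstroke velocity triples.
DEFAULT_AGE_GROUPS = [
    GroupSpec("P2-5", n_animals=4, n_cells_per_animal=6,
              cm_pF=(60.0, 15.0), rm_Mohm=(600.0, 120.0), rs_Mohm=(8.0, 1.5),
              erest_mV=(-58.0, 3.0), threshold_depol_mV=(16.0, 2.0),
              ais_length_um=(14.0, 1.5), ais_diameter_um=(1.0, 0.10),
              is_dvdt_Vps=(90.0, 15.0)),
    GroupSpec("P10-15", n_animals=5, n_cells_per_animal=5,
              cm_pF=(120.0, 25.0), rm_Mohm=(400.0, 80.0), rs_Mohm=(8.0, 1.5),
              erest_mV=(-66.0, 3.0), threshold_depol_mV=(16.0, 2.0),
              ais_length_um=(22.0, 2.0), ais_diameter_um=(1.2, 0.12),
              is_dvdt_Vps=(150.0, 25.0)),
    GroupSpec("P20-25", n_animals=4, n_cells_per_animal=6,
              cm_pF=(160.0, 30.0), rm_Mohm=(180.0, 40.0), rs_Mohm=(8.0, 1.5),
              erest_mV=(-69.0, 3.0), threshold_depol_mV=(16.0, 2.0),
              ais_length_um=(25.5, 2.0), ais_diameter_um=(1.35, 0.13),
              is_dvdt_Vps=(250.0, 40.0)),
    GroupSpec("P50-56", n_animals=5, n_cells_per_animal=4,
              cm_pF=(180.0, 30.0), rm_Mohm=(150.0, 35.0), rs_Mohm=(8.0, 1.5),
              erest_mV=(-70.0, 3.0), threshold_depol_mV=(16.0, 2.0),
              ais_length_um=(27.0, 2.0), ais_diameter_um=(1.45, 0.14),
              is_dvdt_Vps=(290.0, 45.0)),
    GroupSpec("P>150", n_animals=5, n_cells_per_animal=4,
              cm_pF=(190.0, 35.0), rm_Mohm=(140.0, 35.0), rs_Mohm=(8.0, 1.5),
              erest_mV=(-70.0, 3.0), threshold_depol_mV=(16.0, 2.0),
              ais_length_um=(28.0, 2.0), ais_diameter_um=(1.5, 0.15),
              is_dvdt_Vps=(300.0, 50.0)),
]


@dataclass
class CohortSpec:
    """Study design: which groups to generate and the shared protocol settings."""

    groups: list = field(default_factory=lambda: list(DEFAULT_AGE_GROUPS))
    seed: int = 0
    step_duration_s: float = 0.5
    sampling_interval: float = 1e-4
    rheobase_step_pA: float = 5.0
    fi_step_pA: float = 20.0
    fi_max_pA: float = 300.0
    sealtest_noise_pA: float = 5.0
    voltage_noise_mV: float = 0.15
    ais_psf_sigma_um: float = 0.4
    ais_pixel_size_um: float = 0.1
    ais_noise_sd: float = 0.03


@dataclass
class CellData:
    """One synthetic cell: its truth and the raw data the pipeline analyzes."""

    group: str
    animal_id: str
    cell_id: str
    truth: dict
    sealtest: Trace
    rheo_protocol: StepProtocolSet
    fi_protocol: StepProtocolSet
    ais_profile: IntensityProfile
    ais_cross_profile: IntensityProfile


@dataclass
class Cohort:
    spec: CohortSpec
    cells: list
    ais_profiles: list  # (group, animal_id, ais_id, IntensityProfile)
    manifest: pd.DataFrame
    ais_manifest: pd.DataFrame


def _draw_pos(rng, mean_sd, floor=1e-6):
    m, s = mean_sd
    return max(float(rng.normal(m, s)), floor if floor is not None else -np.inf)


def _cross_profile(diameter_um, truth_like: AISGeometryTruth, rng) -> IntensityProfile:
    """Perpendicular profile through the AIS: blurred boxcar of width = diameter."""
    px = truth_like.pixel_size_um
    half = diameter_um / 2.0
    span = half + max(3 * truth_like.psf_sigma_um, 1.5)
    x = np.arange(-math.ceil(span / px), math.ceil(span / px) + 1) * px
    a = truth_like.plateau_intensity - truth_like.background_intensity
    if truth_like.psf_sigma_um == 0:
        core = ((x >= -half) & (x < half)).astype(float)
    else:
        s = truth_like.psf_sigma_um
        core = ndtr((x + half) / s) - ndtr((x - half) / s)
    y = truth_like.background_intensity + a * core
    if truth_like.noise_sd > 0:
        y = np.clip(y + rng.normal(0, truth_like.noise_sd, x.size), 0, None)
    return IntensityProfile(positions=x - x[0], intensities=y, pixel_size=px,
                            meta={"truth": {"diameter_um": diameter_um}})


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full multi-animal cohort with its ground-truth manifests.

    Per cell: a seal test, a fine (5 pA) rheobase protocol that stops a few
    steps above the cell's continuous rheobase, a coarse (20 pA) f-I protocol,
    and one AIS line profile + perpendicular cross profile. Per animal:
    ``n_ais_per_animal`` additional AIS profiles for the morphometry arm.
    Fully reproducible from (spec, spec.seed).
    """
    root = np.random.default_rng(spec.seed)
    cells: list[CellData] = []
    ais_profiles = []
    man_rows = []
    ais_rows = []
    for gi, g in enumerate(spec.groups):
        for a in range(g.n_animals):
            animal = f"{g.label}_rat{a + 1}"
            a_rng = np.random.default_rng(root.integers(0, 2**31 - 1))
            # morphometry arm: AIS lengths vary around an animal-level mean
            animal_len = _draw_pos(a_rng, g.ais_length_um)
            for j in range(g.n_ais_per_animal):
                L = max(float(a_rng.normal(animal_len, g.ais_length_within_sd_um)), 3.0)
                d = _draw_pos(a_rng, g.ais_diameter_um, floor=0.3)
                start = float(a_rng.uniform(1.0, 6.0))
                truth = AISGeometryTruth(
                    start_um=start, end_um=start + L, diameter_um=d,
                    psf_sigma_um=spec.ais_psf_sigma_um,
                    pixel_size_um=spec.ais_pixel_size_um,
                    noise_sd=spec.ais_noise_sd,
                )
                prof = generate_ais_profile(truth, seed=int(a_rng.integers(0, 2**31 - 1)))
                ais_id = f"ais{j + 1:03d}"
                ais_profiles.append((g.label, animal, ais_id, prof))
                ais_rows.append({
                    "group": g.label, "animal_id": animal, "ais_id": ais_id,
                    "true_length_um": L, "true_diameter_um": d, "true_start_um": start,
                })
            # electrophysiology arm
            for c in range(g.n_cells_per_animal):
                cell_id = f"cell{c + 1:02d}"
                cm = _draw_pos(a_rng, g.cm_pF, floor=5.0)
                rm = _draw_pos(a_rng, g.rm_Mohm, floor=20.0)
                rs = _draw_pos(a_rng, g.rs_Mohm, floor=2.0)
                erest = float(a_rng.normal(*g.erest_mV))
                depol = _draw_pos(a_rng, g.threshold_depol_mV, floor=5.0)
                isd = _draw_pos(a_rng, g.is_dvdt_Vps, floor=30.0)
                L = max(float(a_rng.normal(animal_len, g.ais_length_within_sd_um)), 3.0)
                d = _draw_pos(a_rng, g.ais_diameter_um, floor=0.3)
                rin = rs + rm
                tau_m = cm * rm * 1e-3  # ms

                seal = simulate_seal_test(
                    RCCircuitParams(Rs=rs, Rm=rm, Cm_true=cm),
                    noise_sd=spec.sealtest_noise_pA,
                    seed=int(a_rng.integers(0, 2**31 - 1)),
                )
                i_star = lif_rheobase(rin, tau_m, depol, spec.step_duration_s)
                top = (math.ceil(i_star / spec.rheobase_step_pA) + 3) * spec.rheobase_step_pA
                rheo_amps = np.arange(-20.0, top + 0.5 * spec.rheobase_step_pA,
                                      spec.rheobase_step_pA)
                rheo = simulate_lif_steps(
                    rin, tau_m, erest, depol, rheo_amps,
                    step_duration_s=spec.step_duration_s,
                    sampling_interval=spec.sampling_interval,
                    noise_sd_mV=spec.voltage_noise_mV,
                    seed=int(a_rng.integers(0, 2**31 - 1)),
                    ap_max_dvdt_Vps=isd,
                )
                fi_amps = np.arange(-20.0, spec.fi_max_pA + 1.0, spec.fi_step_pA)
                fi = simulate_lif_steps(
                    rin, tau_m, erest, depol, fi_amps,
                    step_duration_s=spec.step_duration_s,
                    sampling_interval=spec.sampling_interval,
                    noise_sd_mV=spec.voltage_noise_mV,
                    seed=int(a_rng.integers(0, 2**31 - 1)),
                    ap_max_dvdt_Vps=isd,
                )
                start = float(a_rng.uniform(1.0, 6.0))
                geo = AISGeometryTruth(
                    start_um=start, end_um=start + L, diameter_um=d,
                    psf_sigma_um=spec.ais_psf_sigma_um,
                    pixel_size_um=spec.ais_pixel_size_um,
                    noise_sd=spec.ais_noise_sd,
                )
                prof = generate_ais_profile(geo, seed=int(a_rng.integers(0, 2**31 - 1)))
                cross = _cross_profile(d, geo, a_rng)
                truth = {
                    "cm_pF": cm, "rm_Mohm": rm, "rs_Mohm": rs, "rin_Mohm": rin,
                    "erest_mV": erest, "threshold_depol_mV": depol,
                    "threshold_mV": erest + depol, "rheobase_pA": i_star,
                    "is_dvdt_Vps": isd, "ais_length_um": L, "ais_diameter_um": d,
                    "tau_m_ms": tau_m,
                }
                cells.append(CellData(g.label, animal, cell_id, truth,
                                      seal, rheo, fi, prof, cross))
                man_rows.append({"group": g.label, "animal_id": animal,
                                 "cell_id": cell_id, **truth})
    return Cohort(
        spec=spec,
        cells=cells,
        ais_profiles=ais_profiles,
        manifest=pd.DataFrame(man_rows),
        ais_manifest=pd.DataFrame(ais_rows),
    )


def save_cohort(cohort: Cohort, out_dir) -> None:
    """Persist a cohort as ``group/animal/cell/{...}.csv`` + manifests."""
    from pathlib import Path

    from .trace_io import write_trace

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cell in cohort.cells:
        cdir = out / cell.group / cell.animal_id / cell.cell_id
        write_trace(cell.sealtest, cdir / "sealtest.csv")
        for i, (amp, tr) in enumerate(cell.rheo_protocol):
            write_trace(tr, cdir / "steps_rheo" / f"step{i:03d}_{amp:+.0f}pA.csv")
        for i, (amp, tr) in enumerate(cell.fi_protocol):
            write_trace(tr, cdir / "steps_fi" / f"step{i:03d}_{amp:+.0f}pA.csv")
        _save_profile(cell.ais_profile, cdir / "ais_profile.csv")
        _save_profile(cell.ais_cross_profile, cdir / "ais_cross_profile.csv")
    for group, animal, ais_id, prof in cohort.ais_profiles:
        _save_profile(prof, out / group / animal / "ais" / f"{ais_id}.csv")
    cohort.manifest.to_csv(out / "manifest.csv", index=False)
    cohort.ais_manifest.to_csv(out / "ais_manifest.csv", index=False)


def _save_profile(profile: IntensityProfile, path) -> None:
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"position_um": profile.positions, "intensity": profile.intensities}
    ).to_csv(path, index=False, float_format="%.9g")


def load_profile(path) -> IntensityProfile:
    df = pd.read_csv(path, comment="#")
    pos = df["position_um"].to_numpy(float)
    return IntensityProfile(
        positions=pos,
        intensities=df["intensity"].to_numpy(float),
        pixel_size=float(pos[1] - pos[0]),
    )
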