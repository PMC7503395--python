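"""Phase-plane metrics against closed-form waveform oracles."""

import numpy as np
import pytest

from aismature.exceptions import NoAPError, ParameterError, ShapeError
from aismature.trace_io import Trace
from aismature.waveform import (
    AfterPotentialProfile,
    ISSDComponents,
    PhasePlot,
    ahp_adp_profile,
    ap_half_width,
    ap_threshold,
    is_sd_components,
    phase_plot,
    slope_extrema,
)


def voltage_trace(v, dt=1e-5):
    return Trace(samples=v, sampling_interval=dt, signal_kind="voltage",
                 baseline_window=(0.0, 0.001), step_window=(0.0, len(v) * dt),
                 step_amplitude=0.0)


class TestPhasePlot:
    def test_sine_wave_gives_elliptic_orbit_with_amplitude_omega_extrema(self):
        # V = A sin(wt): dV/dt extrema = +/- A*w; A=50 mV, f=100 Hz -> 31.42 V/s
        dt = 1e-5
        t = np.arange(0, 0.02, dt)
        v = 50.0 * np.sin(2 * np.pi * 100 * t)
        tr = voltage_trace(v, dt)
        pp = phase_plot(tr, int(np.argmax(v)), window_ms=(2.5, 2.5))
        mx, mn = slope_extrema(pp)
        expect = 2 * np.pi * 100 * 0.05
        assert mx == pytest.approx(expect, rel=5e-3)
        assert mn == pytest.approx(-expect, rel=5e-3)

    def test_constant_trace_gives_zero_dvdt(self):
        tr = voltage_trace(np.full(4000, -70.0))
        pp = phase_plot(tr, 2000, window_ms=(5, 5))
        np.testing.assert_allclose(pp.dvdt, 0.0)

    def test_window_fully_outside_trace_rejected(self):
        tr = voltage_trace(np.full(400, -70.0))
        with pytest.raises(ParameterError):
            phase_plot(tr, 3, window_ms=(5, 5))


class TestAPThreshold:
    def test_exponential_takeoff_closed_form(self):
        # dV/dt = a (V - Vb) with a = 1/ms, Vb = -70: criterion 20 V/s crossed
        # exactly at V = Vb + 20/a = -50 mV
        dt = 1e-6
        t = np.arange(0, 12e-3, dt)
        v = -70.0 + 0.05 * np.exp(t / 1e-3)
        v = v[v <= 20.0]
        tr = voltage_trace(v, dt)
        pp = phase_plot(tr, len(v) - 2, window_ms=(len(v) * dt * 1e3 - 0.01, 0.0))
        assert ap_threshold(pp, 20.0) == pytest.approx(-50.0, abs=0.1)

    def test_subthreshold_trace_raises(self):
        tr = voltage_trace(np.linspace(-70, -69, 2000))
        pp = phase_plot(tr, 1500, window_ms=(5, 2))
        with pytest.raises(NoAPError):
            ap_threshold(pp, 20.0)

    def test_zero_criterion_returns_first_rising_sample(self):
        dt = 1e-5
        t = np.arange(0, 0.01, dt)
        v = -70.0 + 40 * np.sin(2 * np.pi * 100 * t) ** 2
        tr = voltage_trace(v, dt)
        pk = int(np.argmax(v[:500]))
        pp = phase_plot(tr, pk, window_ms=(2, 1))
        thr = ap_threshold(pp, 0.0)
        assert thr == pytest.approx(pp.voltage[0], abs=0.5)


class TestHalfWidth:
    def test_gaussian_spike_closed_form(self, gaussian_spike_trace):
        tr, sigma, t0 = gaussian_spike_trace
        pk = int(np.argmax(tr.samples))
        hw = ap_half_width(tr, -70.0, pk)
        assert hw == pytest.approx(2 * sigma * 1e3 * np.sqrt(2 * np.log(2)), abs=0.02)

    def test_triangular_spike_geometry(self):
        dt = 1e-5
        rise = np.linspace(-70, 30, 101)
        fall = np.linspace(30, -70, 101)[1:]
        v = np.concatenate([np.full(100, -70.0), rise, fall, np.full(100, -70.0)])
        tr = voltage_trace(v, dt)
        # 1 ms rise, 1 ms fall: at half amplitude the chord is exactly 1 ms
        assert ap_half_width(tr, -70.0, 100 + 100) == pytest.approx(1.0, rel=1e-3)

    def test_width_monotone_in_sigma(self):
        dt = 1e-5
        t = np.arange(0, 0.04, dt)
        widths = []
        for sig in (0.2e-3, 0.3e-3, 0.5e-3):
            v = -70 + 100 * np.exp(-((t - 0.02) ** 2) / (2 * sig**2))
            widths.append(ap_half_width(voltage_trace(v, dt), -70.0, int(np.argmax(v))))
        assert widths[0] < widths[1] < widths[2]

    def test_no_repolarization_raises(self):
        v = np.concatenate([np.full(100, -70.0), np.linspace(-70, 30, 200)])
        with pytest.raises(ShapeError):
            ap_half_width(voltage_trace(v), -70.0, 299)


class TestISSD:
    @staticmethod
    def _pp(v, dvdt):
        return PhasePlot(voltage=np.asarray(v, float), dvdt=np.asarray(dvdt, float),
                         sampling_interval=1e-5, window=(0.0, 1.0),
                         peak_index=len(v) - 1)

    def _two_bump(self, is_amp=80.0, sd_amp=300.0):
        v = np.linspace(-55.0, 0.0, 111)
        bump1 = is_amp * np.exp(-((v + 45.0) ** 2) / (2 * 2.0**2))
        bump2 = sd_amp * np.exp(-((v + 20.0) ** 2) / (2 * 4.0**2))
        return self._pp(v, bump1 + bump2)

    def test_constructed_two_bump_rising_phase(self):
        # bumps of 80 V/s (at -45 mV) and 300 V/s (at -20 mV):
        # IS = 80, SD = 300, ratio 0.267
        out = is_sd_components(self._two_bump(), smooth=False)
        assert out.biphasic
        assert out.is_peak == pytest.approx(80.0, rel=0.02)
        assert out.sd_peak == pytest.approx(300.0, rel=0.02)
        assert out.ratio == pytest.approx(0.267, abs=0.01)
        assert out.is_voltage < out.sd_voltage

    def test_single_bump_is_monophasic_with_is_attribution(self):
        v = np.linspace(-55.0, 0.0, 111)
        d = 120.0 * np.exp(-((v + 30.0) ** 2) / (2 * 4.0**2))
        out = is_sd_components(self._pp(v, d), smooth=False)
        assert not out.biphasic
        assert out.sd_peak is None and out.ratio is None
        assert out.is_peak == pytest.approx(120.0, rel=0.02)

    def test_raising_prominence_can_only_flip_biphasic_to_monophasic(self):
        pp = self._two_bump(is_amp=40.0)
        lo = is_sd_components(pp, min_prominence_vps=10.0, smooth=False)
        hi = is_sd_components(pp, min_prominence_vps=60.0, smooth=False)
        assert lo.biphasic
        assert not hi.biphasic

    def test_invariants_enforced_on_type(self):
        with pytest.raises(ParameterError):
            ISSDComponents(is_peak=300.0, sd_peak=200.0, ratio=1.5, biphasic=True)
        with pytest.raises(ParameterError):
            ISSDComponents(is_peak=100.0, sd_peak=200.0, ratio=0.5, biphasic=False)


class TestAfterPotentials:
    @staticmethod
    def _post_spike_trace(after_rel, threshold=-45.0, dt=1e-4):
        """Baseline, fast triangular spike, then a prescribed after-course."""
        spike = np.concatenate([np.linspace(threshold, 30, 10),
                                np.linspace(30, threshold, 10)[1:]])
        v = np.concatenate([np.full(200, -60.0), spike, threshold + np.asarray(after_rel)])
        tr = Trace(samples=v, sampling_interval=dt, signal_kind="voltage",
                   baseline_window=(0.0, 0.02), step_window=(0.0, len(v) * dt),
                   step_amplitude=0.0)
        return tr, 200 + 9

    def test_monotonic_dip_classified_mono(self):
        t = np.linspace(0, 1, 900)
        after = -8.0 * np.sin(np.pi * np.clip(t, 0, 1)) - 0.0
        tr, pk = self._post_spike_trace(after)
        prof = ahp_adp_profile(tr, pk, -45.0)
        assert prof.shape_class == "mono"
        assert prof.ahp_slow_mono == pytest.approx(-8.0, abs=0.05)
        assert prof.ahp_fast is None and prof.adp is None

    def test_dip_rebound_dip_classified_tri(self):
        seg1 = np.linspace(0, -6, 60)           # fast AHP
        seg2 = np.linspace(-6, -2, 60)[1:]      # rebound to ADP
        seg3 = np.linspace(-2, -9, 200)[1:]     # slow AHP
        seg4 = np.linspace(-9, -1, 300)[1:]
        tr, pk = self._post_spike_trace(np.concatenate([seg1, seg2, seg3, seg4]))
        prof = ahp_adp_profile(tr, pk, -45.0)
        assert prof.shape_class == "tri"
        assert prof.ahp_fast == pytest.approx(-6.0, abs=0.1)
        assert prof.adp == pytest.approx(-2.0, abs=0.1)
        assert prof.ahp_slow_mono == pytest.approx(-9.0, abs=0.1)

    def test_small_rebound_below_prominence_stays_mono(self):
        seg1 = np.linspace(0, -6, 60)
        seg2 = np.linspace(-6, -5.7, 60)[1:]    # 0.3 mV rebound < 0.5 mV cutoff
        seg3 = np.linspace(-5.7, -9, 200)[1:]
        seg4 = np.linspace(-9, -1, 300)[1:]
        tr, pk = self._post_spike_trace(np.concatenate([seg1, seg2, seg3, seg4]))
        prof = ahp_adp_profile(tr, pk, -45.0, min_prominence_mV=0.5)
        assert prof.shape_class == "mono"

    def test_truncated_window_flags_unresolved(self):
        after = np.linspace(0, -4, 30)
        tr, pk = self._post_spike_trace(after)
        prof = ahp_adp_profile(tr, pk, -45.0, next_spike_peak_index=pk + 25)
        assert not prof.resolved

    def test_profile_type_invariants(self):
        with pytest.raises(ParameterError):
            AfterPotentialProfile(shape_class="mono", ahp_slow_mono=-5.0, adp=-1.0)
        with pytest.raises(ParameterError):
            AfterPotentialProfile(shape_class="tri", ahp_slow_mono=-5.0)


class TestInvariances:
    def test_metrics_invariant_to_time_shift_and_voltage_offset(self, gaussian_spike_trace):
        tr, sigma, t0 = gaussian_spike_trace
        pk = int(np.argmax(tr.samples))
        pp = phase_plot(tr, pk, window_ms=(3, 3))
        base = (ap_threshold(pp, 20.0), *slope_extrema(pp),
                ap_half_width(tr, ap_threshold(pp, 20.0), pk))

        shifted = Trace(samples=np.roll(tr.samples, 300), sampling_interval=tr.sampling_interval,
                        signal_kind="voltage", baseline_window=tr.baseline_window,
                        step_window=tr.step_window, step_amplitude=0.0)
        pk2 = int(np.argmax(shifted.samples))
        pp2 = phase_plot(shifted, pk2, window_ms=(3, 3))
        thr2 = ap_threshold(pp2, 20.0)
        assert thr2 == pytest.approx(base[0], abs=1e-6)
        assert slope_extrema(pp2)[0] == pytest.approx(base[1], rel=1e-9)

        offset = tr.with_samples(tr.samples + 12.0)
        pp3 = phase_plot(offset, pk, window_ms=(3, 3))
        assert ap_threshold(pp3, 20.0) == pytest.approx(base[0] + 12.0, abs=1e-6)
        assert ap_half_width(offset, ap_threshold(pp3, 20.0), pk) == pytest.approx(base[3], rel=1e-6)

    def test_sampling_rate_robustness_on_analytic_waveform(self):
        # same Gaussian AP at 10 and 50 kHz: metrics differ by <= one coarse sample
        def metrics(dt):
            t = np.arange(0, 0.04, dt)
            v = -70 + 100 * np.exp(-((t - 0.02) ** 2) / (2 * 0.4e-3**2))
            tr = Trace(samples=v, sampling_interval=dt, signal_kind="voltage",
                       baseline_window=(0, 0.01), step_window=(0, 0.04),
                       step_amplitude=0.0)
            pk = int(np.argmax(v))
            pp = phase_plot(tr, pk, window_ms=(3, 3))
            thr = ap_threshold(pp, 20.0)
            return thr, ap_half_width(tr, thr, pk)

        thr10, hw10 = metrics(1e-4)
        thr50, hw50 = metrics(2e-5)
        assert hw10 == pytest.approx(hw50, abs=0.1)  # 1 coarse sample = 0.1 ms
        assert thr10 == pytest.approx(thr50, abs=1.0)


def test_ais_strengthening_hyperpolarizes_threshold_and_speeds_upstroke():
    """Stronger AIS sodium: threshold falls, max dV/dt rises (maturation direction)."""
    from aismature.firing import detect_spikes
    from aismature.synth import TwoCompartmentParams, simulate_two_compartment

    out = []
    for g in (450.0, 900.0):
        ps = simulate_two_compartment(TwoCompartmentParams(gNa_ais=g), [200.0])
        tr = ps.traces[0]
        pk = int(detect_spikes(tr).spike_peak_indices[0])
        pp = phase_plot(tr, pk, window_ms=(3, 5))
        out.append((ap_threshold(pp, 20.0), slope_extrema(pp)[0]))
    (thr_lo, mx_lo), (thr_hi, mx_hi) = out
    assert thr_hi < thr_lo
    assert mx_hi > mx_lo
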