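"""Generators against their closed-form oracles and determinism contracts."""

import numpy as np
import pytest

from aismature.exceptions import AismatureWarning, GeometryError, ParameterError
from aismature.firing import detect_spikes
from aismature.synth import (
    AISGeometryTruth,
    CohortSpec,
    GroupSpec,
    RCCircuitParams,
    TwoCompartmentParams,
    generate_ais_profile,
    generate_cohort,
    lif_rheobase,
    simulate_lif_steps,
    simulate_seal_test,
    simulate_two_compartment,
)
from aismature.waveform import phase_plot


class TestSealTest:
    def test_matches_rc_closed_form(self):
        # Rs=10, Rm=190, Cm=100: I(0+) = -5mV/10MOhm = -500 pA,
        # steady state -5/200 = -25 pA, tau = 100 pF * 9.5 MOhm = 0.95 ms
        tr = simulate_seal_test(RCCircuitParams(10, 190, 100), sampling_interval=1e-5)
        truth = tr.meta["truth"]
        assert truth["I0_pA"] == pytest.approx(-500.0)
        assert truth["Iss_pA"] == pytest.approx(-25.0)
        assert truth["tau_ms"] == pytest.approx(0.95)
        k_on = tr.index_at(tr.step_window[0])
        assert tr.samples[k_on] == pytest.approx(-500.0)
        assert tr.samples[-1] == pytest.approx(-25.0, abs=1e-3)
        # decay follows the closed form at every sample
        t = (np.arange(tr.n_samples) - k_on) * tr.sampling_interval
        expect = -25.0 + (-500.0 + 25.0) * np.exp(-t[k_on:] / 0.95e-3)
        np.testing.assert_allclose(tr.samples[k_on:], expect, rtol=1e-9)

    def test_tiny_capacitance_removes_transient(self):
        tr = simulate_seal_test(RCCircuitParams(10, 190, 0.01), sampling_interval=1e-4)
        k_on = tr.index_at(tr.step_window[0])
        # tau ~ 0.1 us << one sample: every in-step sample sits at steady state
        np.testing.assert_allclose(tr.samples[k_on + 1 :], -25.0, atol=1e-6)

    def test_same_seed_identical_traces(self):
        p = RCCircuitParams(8, 300, 150)
        a = simulate_seal_test(p, noise_sd=5.0, seed=123)
        b = simulate_seal_test(p, noise_sd=5.0, seed=123)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_short_record_flags_warning(self):
        with pytest.warns(AismatureWarning, match="5 tau"):
            tr = simulate_seal_test(
                RCCircuitParams(10, 1000, 400), duration=0.012, step_on_s=0.01
            )
        assert "short_record" in tr.meta["flags"]

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ParameterError):
            RCCircuitParams(0, 100, 100)


class TestLIF:
    def test_continuous_rheobase_closed_form(self):
        # Rin=200, tau=20 ms, depol=16 mV, T=500 ms: I* = 16/(0.2*(1-e^-25)) = 80 pA
        assert lif_rheobase(200, 20, 16, 0.5) == pytest.approx(80.0, rel=1e-6)
        # Ohm scaling: doubling Rin halves, doubling depol doubles
        assert lif_rheobase(400, 20, 16, 0.5) == pytest.approx(40.0, rel=1e-6)
        assert lif_rheobase(200, 20, 32, 0.5) == pytest.approx(160.0, rel=1e-6)

    def test_zero_current_stays_at_rest(self):
        ps = simulate_lif_steps(200, 20, -70, 16, [0.0])
        tr = ps.traces[0]
        np.testing.assert_allclose(tr.samples, -70.0, atol=1e-9)
        assert detect_spikes(tr).n_spikes == 0

    def test_subthreshold_matches_closed_form(self):
        ps = simulate_lif_steps(200, 20, -70, 16, [40.0], sampling_interval=1e-5)
        tr = ps.traces[0]
        t_on = tr.step_window[0]
        t = tr.times
        sel = (t >= t_on) & (t < tr.step_window[1])
        expect = -70.0 + 40 * 200 * 1e-3 * (1 - np.exp(-(t[sel] - t_on) / 20e-3))
        np.testing.assert_allclose(tr.samples[sel], expect, rtol=1e-6)

    def test_spikes_pasted_at_threshold_crossings(self):
        ps = simulate_lif_steps(200, 20, -70, 16, [120.0])
        tr = ps.traces[0]
        truth_times = np.asarray(tr.meta["true_spike_times_s"])
        train = detect_spikes(tr)
        assert train.n_spikes == truth_times.size > 1
        # detected 0 mV crossings fall inside each pasted upstroke (1 ms rise)
        assert np.all((train.spike_times > truth_times) & (train.spike_times < truth_times + 1.5e-3))

    def test_requested_upstroke_velocity_is_honored(self):
        ps = simulate_lif_steps(200, 20, -70, 16, [120.0], sampling_interval=1e-5,
                                ap_max_dvdt_Vps=250.0)
        tr = ps.traces[0]
        pk = int(detect_spikes(tr).spike_peak_indices[0])
        pp = phase_plot(tr, pk, window_ms=(3, 4))
        assert np.max(pp.dvdt) == pytest.approx(250.0, rel=0.01)


class TestTwoCompartment:
    def test_biphasic_upstroke_with_default_sodium_distribution(self, two_comp_default_ap):
        pp = two_comp_default_ap
        d = pp.dvdt[: pp.peak_index + 1]
        rising = d[d >= 20.0]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(rising, prominence=10.0)
        assert peaks.size >= 2

    def test_somatic_sodium_removal_gives_monophasic_upstroke(self):
        ps = simulate_two_compartment(TwoCompartmentParams(gNa_soma=0.0), [200.0])
        tr = ps.traces[0]
        pk = int(detect_spikes(tr).spike_peak_indices[0])
        pp = phase_plot(tr, pk, window_ms=(3, 5))
        d = pp.dvdt[: pp.peak_index + 1]
        rising = d[d >= 20.0]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(rising, prominence=10.0)
        assert peaks.size <= 1

    def test_halving_dt_changes_peak_dvdt_under_one_percent(self):
        def peak_dvdt(dt):
            ps = simulate_two_compartment(TwoCompartmentParams(), [200.0], dt_ms=dt)
            tr = ps.traces[0]
            pk = int(detect_spikes(tr).spike_peak_indices[0])
            return float(np.max(phase_plot(tr, pk, window_ms=(3, 5)).dvdt))

        a, b = peak_dvdt(0.005), peak_dvdt(0.0025)
        assert abs(a - b) / b < 0.01

    def test_charge_conservation_per_compartment(self):
        p = TwoCompartmentParams()
        ps = simulate_two_compartment(p, [200.0], dt_ms=0.002, step_duration_s=0.03,
                                      record_states=True)
        tr = ps.traces[0]
        st = tr.meta["states"]
        vs, va, hs, ha, ns_, na_ = (st[:, i] for i in range(6))
        dt_s = tr.sampling_interval
        t = tr.times
        inj = np.where((t >= tr.step_window[0]) & (t < tr.step_window[1]), 200.0, 0.0)

        def sig(v, half, slope):
            return 1.0 / (1.0 + np.exp(-(v - half) / slope))

        ms = sig(vs, p.vm_half, p.km)
        i_s = (-p.g_leak_soma * (vs - p.E_leak)
               - p.gNa_soma * ms**3 * hs * (vs - p.E_Na)
               - p.gK_soma * ns_**4 * (vs - p.E_K)
               + p.g_axial * (va - vs) + inj)  # pA
        q_true = p.C_soma * (vs - vs[0])  # pF*mV = fC... consistent charge units
        q_int = np.concatenate([[0.0], np.cumsum((i_s[1:] + i_s[:-1]) / 2) * dt_s * 1e3])
        scale = np.max(np.abs(q_true))
        assert np.max(np.abs(q_true - q_int)) < 1e-3 * scale

    def test_coarse_dt_rejected(self):
        with pytest.raises(ParameterError):
            simulate_two_compartment(TwoCompartmentParams(), [100.0], dt_ms=0.05)


class TestAISProfile:
    def test_boxcar_truth_by_construction(self):
        t = AISGeometryTruth(start_um=4.0, end_um=12.0, psf_sigma_um=0.0,
                             pixel_size_um=0.2, plateau_intensity=1.0,
                             background_intensity=0.05)
        prof = generate_ais_profile(t)
        inside = (prof.positions >= 4.0) & (prof.positions < 12.0)
        np.testing.assert_allclose(prof.intensities[inside], 1.0)
        np.testing.assert_allclose(prof.intensities[~inside], 0.05)

    def test_blurred_edge_follows_error_function(self):
        from scipy.special import ndtr

        t = AISGeometryTruth(start_um=4.0, end_um=12.0, psf_sigma_um=0.4,
                             pixel_size_um=0.1)
        prof = generate_ais_profile(t)
        x = prof.positions
        expect = 0.05 + 0.95 * (ndtr((x - 4.0) / 0.4) - ndtr((x - 12.0) / 0.4))
        np.testing.assert_allclose(prof.intensities, expect, rtol=1e-9, atol=1e-12)

    def test_noiseless_and_seeded_profiles_are_deterministic(self):
        t = AISGeometryTruth(start_um=4.0, end_um=12.0, noise_sd=0.05)
        a = generate_ais_profile(t, seed=5)
        b = generate_ais_profile(t, seed=5)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_span_too_small_raises_geometry_error(self):
        t = AISGeometryTruth(start_um=4.0, end_um=12.0, psf_sigma_um=0.4)
        with pytest.raises(GeometryError):
            generate_ais_profile(t, n_pixels=50)  # 5 um < end + 3 sigma


@pytest.fixture(scope="module")
def small_spec():
    groups = [
        GroupSpec("young", n_animals=2, n_cells_per_animal=3, n_ais_per_animal=4,
                  cm_pF=(60.0, 10.0), rm_Mohm=(600.0, 80.0),
                  ais_length_um=(14.0, 1.0)),
        GroupSpec("adult", n_animals=2, n_cells_per_animal=3, n_ais_per_animal=4,
                  cm_pF=(180.0, 20.0), rm_Mohm=(150.0, 25.0),
                  ais_length_um=(27.0, 1.5)),
    ]
    return CohortSpec(groups=groups, seed=11)


class TestCohort:
    def test_counts_match_design(self, small_spec):
        cohort = generate_cohort(small_spec)
        assert len(cohort.cells) == 12
        assert len(cohort.manifest) == 12
        assert len(cohort.ais_profiles) == 2 * 2 * 4
        assert set(cohort.manifest["group"]) == {"young", "adult"}

    def test_group_means_differ_in_the_specified_direction(self, small_spec):
        m = generate_cohort(small_spec).manifest.groupby("group")
        assert m["cm_pF"].mean()["adult"] > m["cm_pF"].mean()["young"]
        assert m["rin_Mohm"].mean()["adult"] < m["rin_Mohm"].mean()["young"]
        assert m["ais_length_um"].mean()["adult"] > m["ais_length_um"].mean()["young"]

    def test_same_spec_and_seed_reproduce_manifest(self, small_spec):
        import pandas as pd

        a = generate_cohort(small_spec)
        b = generate_cohort(small_spec)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        np.testing.assert_array_equal(a.cells[0].sealtest.samples,
                                      b.cells[0].sealtest.samples)
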