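"""Shared fixtures: expensive simulations reused across test modules."""

import numpy as np
import pytest

from aismature.firing import detect_spikes
from aismature.synth import TwoCompartmentParams, simulate_two_compartment
from aismature.waveform import phase_plot


@pytest.fixture(scope="session")
def two_comp_default_ap():
    """Phase plot of the first somatic AP of the default two-compartment cell."""
    ps = simulate_two_compartment(TwoCompartmentParams(), [200.0])
    tr = ps.traces[0]
    pk = int(detect_spikes(tr).spike_peak_indices[0])
    return phase_plot(tr, pk, window_ms=(3.0, 5.0))


@pytest.fixture
def gaussian_spike_trace():
    """Analytic Gaussian AP on a flat baseline: half-width = 2*sigma*sqrt(2 ln 2)."""
    from aismature.trace_io import Trace

    dt = 1e-5
    t = np.arange(0, 0.04, dt)
    sigma = 0.3e-3
    t0 = 0.02
    v = -70.0 + 100.0 * np.exp(-((t - t0) ** 2) / (2 * sigma**2))
    return Trace(samples=v, sampling_interval=dt, signal_kind="voltage",
                 baseline_window=(0.0, 0.01), step_window=(0.01, 0.04),
                 step_amplitude=100.0), sigma, t0
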