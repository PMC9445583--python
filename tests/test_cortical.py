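"""Adaptive exponential integrate-and-fire dynamics for PY/FS cells."""

import numpy as np
import pytest

from tcosim.cortical import (CortexNeuronParams, CortexNeuronState,
                             CortexSynapseParams, adaptation_derivative,
                             conductance_update, cortical_membrane_derivative,
                             on_spike)


@pytest.fixture
def params():
    return CortexNeuronParams()


@pytest.fixture
def syn():
    return CortexSynapseParams()


def test_only_exponential_term_at_leak_reversal(params, syn):
    st = CortexNeuronState(voltage=params.leak_reversal)
    dv = cortical_membrane_derivative(params, syn, st)
    expected = (params.leak_conductance * params.slope_factor
                * np.exp((params.leak_reversal - params.threshold) / params.slope_factor)
                / params.membrane_capacitance)
    assert dv == pytest.approx(expected)
    assert dv > 0.0


def test_zero_driving_force_for_excitation(params, syn):
    st0 = CortexNeuronState(voltage=syn.excitatory_reversal, g_exc=0.0)
    st1 = CortexNeuronState(voltage=syn.excitatory_reversal, g_exc=10.0)
    assert cortical_membrane_derivative(params, syn, st1) == pytest.approx(
        cortical_membrane_derivative(params, syn, st0))


def test_subthreshold_fixed_point_reached(params, syn):
    """Euler-integrate to the root of the subthreshold current balance."""
    from scipy.optimize import brentq
    g_e = 2.0  # nS constant excitation

    def balance(v):
        return (-params.leak_conductance * (v - params.leak_reversal)
                + params.leak_conductance * params.slope_factor
                * np.exp((v - params.threshold) / params.slope_factor)
                - params.adaptation_coupling * (v - params.leak_reversal)
                - g_e * (v - syn.excitatory_reversal))

    v_star = brentq(balance, -80.0, params.threshold - 1.0)
    st = CortexNeuronState(voltage=params.leak_reversal)
    dt = 0.02
    for _ in range(int(2000.0 / dt)):
        st.g_exc = g_e
        dv = cortical_membrane_derivative(params, syn, st)
        dw = adaptation_derivative(params, st)
        st.voltage += dt * dv
        st.adaptation_current += dt * dw
    # at the fixed point w = a (v - E_L), matching the root equation
    assert st.voltage == pytest.approx(v_star, abs=0.05)


def test_adaptation_at_rest_is_zero(params):
    st = CortexNeuronState(voltage=params.leak_reversal, adaptation_current=0.0)
    assert adaptation_derivative(params, st) == 0.0


def test_adaptation_decays_exponentially(params):
    st = CortexNeuronState(voltage=params.leak_reversal, adaptation_current=50.0)
    dt, t = 0.01, 0.0
    while t < params.adaptation_time_constant:
        st.adaptation_current += dt * adaptation_derivative(params, st)
        t += dt
    assert st.adaptation_current == pytest.approx(50.0 * np.exp(-1.0), rel=1e-3)


def test_on_spike_reset_and_increment(params):
    st = CortexNeuronState(voltage=5.0, adaptation_current=10.0)
    out = on_spike(params, st)
    assert out.voltage == params.reset_potential
    assert out.adaptation_current == pytest.approx(10.0 + params.spike_adaptation_increment)
    assert out.refractory_remaining == params.refractory_period
    out2 = on_spike(params, out)
    assert out2.adaptation_current == pytest.approx(10.0 + 2 * params.spike_adaptation_increment)


def test_spike_frequency_adaptation(params, syn):
    """Constant suprathreshold drive: inter-spike intervals lengthen."""
    st = CortexNeuronState(voltage=params.leak_reversal)
    g_e = 6.0
    dt, t = 0.02, 0.0
    spikes = []
    while t < 1000.0 and len(spikes) < 6:
        if st.refractory_remaining > 0:
            st.refractory_remaining = max(0.0, st.refractory_remaining - dt)
            st.voltage = params.reset_potential
        else:
            st.g_exc = g_e
            dv = cortical_membrane_derivative(params, syn, st)
            st.voltage += dt * dv
        st.adaptation_current += dt * adaptation_derivative(params, st)
        if st.voltage >= params.spike_cutoff_voltage:
            st = on_spike(params, st)
            spikes.append(t)
        t += dt
    isis = np.diff(spikes)
    assert len(isis) >= 3
    assert np.all(np.diff(isis) > 0)


class TestConductanceUpdate:
    def test_exponential_decay(self, syn):
        st = CortexNeuronState(g_exc=1.0)
        for _ in range(5):
            st = conductance_update(syn, st, dt=1.0)
        assert st.g_exc == pytest.approx(np.exp(-5.0 / syn.excitatory_decay))

    def test_quantal_jump(self, syn):
        st = conductance_update(syn, CortexNeuronState(), dt=1e-9, exc_spikes=1)
        assert st.g_exc == pytest.approx(syn.excitatory_quantum)

    def test_negative_counts_rejected(self, syn):
        with pytest.raises(ValueError):
            conductance_update(syn, CortexNeuronState(), dt=0.1, exc_spikes=-1)

    def test_poisson_mean_conductance(self, syn):
        """Shot-noise mean r * Q * tau, within 5%."""
        rng = np.random.default_rng(7)
        rate, dt, t_end = 0.2, 0.1, 20000.0  # spikes per ms
        st = CortexNeuronState()
        acc, n = 0.0, 0
        for _ in range(int(t_end / dt)):
            k = rng.poisson(rate * dt)
            st = conductance_update(syn, st, dt, exc_spikes=k)
            acc += st.g_exc
            n += 1
        expected = rate * syn.excitatory_quantum * syn.excitatory_decay
        assert acc / n == pytest.approx(expected, rel=0.05)


def test_parameter_validation():
    with pytest.raises(ValueError):
        CortexNeuronParams(slope_factor=0.0)
    with pytest.raises(ValueError):
        CortexSynapseParams(excitatory_decay=0.0)
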