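"""Chemical synapse kinetics, short-term depression and gap junctions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcosim.synapses import (ChemicalSynapseParams, ChemicalSynapseState,
                             GapJunctionSpec, chemical_synaptic_current,
                             depression_factor, depression_fixed_point,
                             gap_junction_current, gating_fraction_derivative,
                             mg_block, register_spike)


class TestGapJunction:
    def test_defaults_by_pair_class(self):
        assert GapJunctionSpec("HTC-HTC").resistance == 100.0
        assert GapJunctionSpec("HTC-RTC").resistance == 300.0
        assert GapJunctionSpec("RE-RE").resistance == 300.0

    def test_equal_potentials_no_current(self):
        assert gap_junction_current(GapJunctionSpec(), -60.0, -60.0) == 0.0

    def test_ohms_law(self):
        spec = GapJunctionSpec("HTC-HTC")
        assert gap_junction_current(spec, 40.0, -60.0) == pytest.approx(1.0)  # nA

    @given(st.floats(-90, 40), st.floats(-90, 40))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, v1, v2):
        spec = GapJunctionSpec("RE-RE")
        assert gap_junction_current(spec, v1, v2) == pytest.approx(
            -gap_junction_current(spec, v2, v1))

    def test_invalid_resistance(self):
        with pytest.raises(ValueError):
            GapJunctionSpec(resistance=-5.0)


class TestReceptorGating:
    def test_decay_without_transmitter(self):
        p = ChemicalSynapseParams(backward_rate=0.2)
        s, dt = 0.6, 0.001
        for _ in range(int(10.0 / dt)):
            s += dt * gating_fraction_derivative(p, s, transmitter_on=False)
        assert s == pytest.approx(0.6 * np.exp(-0.2 * 10.0), rel=1e-3)

    def test_fixed_point_with_transmitter(self):
        p = ChemicalSynapseParams(forward_rate=1.1, backward_rate=0.19)
        a_t = p.forward_rate * p.transmitter_amplitude
        s_inf = a_t / (a_t + p.backward_rate)
        assert gating_fraction_derivative(p, s_inf, True) == pytest.approx(0.0, abs=1e-14)

    def test_rest_is_absorbing(self):
        p = ChemicalSynapseParams()
        assert gating_fraction_derivative(p, 0.0, False) == 0.0


class TestDepression:
    def test_full_recovery(self):
        p = ChemicalSynapseParams()
        st0 = register_spike(p, ChemicalSynapseState(), t=0.0)
        assert depression_factor(p, st0, t=1e7) == pytest.approx(1.0)

    def test_value_at_spike_time(self):
        p = ChemicalSynapseParams(depression_use_fraction=0.3)
        st0 = register_spike(p, ChemicalSynapseState(), t=0.0)
        assert depression_factor(p, st0, 0.0) == pytest.approx(
            st0.depression_at_last_spike * 0.7)

    def test_ordering_error(self):
        p = ChemicalSynapseParams()
        st0 = register_spike(p, ChemicalSynapseState(), t=10.0)
        with pytest.raises(ValueError):
            depression_factor(p, st0, 5.0)

    def test_drop_factor_per_spike_and_recovery_monotone(self):
        p = ChemicalSynapseParams(depression_use_fraction=0.2,
                                  recovery_time_constant=100.0)
        state = ChemicalSynapseState()
        t = 0.0
        for _ in range(4):
            before = depression_factor(p, state, t)
            state = register_spike(p, state, t)
            assert state.depression == pytest.approx(before * 0.8)
            # non-decreasing between spikes
            ds = [depression_factor(p, state, t + x) for x in (1.0, 5.0, 20.0)]
            assert ds == sorted(ds)
            t += 25.0

    def test_periodic_train_fixed_point_matches_closed_form(self):
        """Iterated per-spike map converges to the analytic D*."""
        p = ChemicalSynapseParams(depression_use_fraction=0.15,
                                  recovery_time_constant=300.0)
        interval = 25.0
        state = ChemicalSynapseState()
        t = 0.0
        for _ in range(300):
            state = register_spike(p, state, t)
            t += interval
        d_before = depression_factor(p, state, t)
        assert d_before == pytest.approx(depression_fixed_point(p, interval), rel=1e-9)

    def test_paired_pulse_ratio_equals_depression_ratio(self):
        """With identical s dynamics per pulse, amplitude ratio = D2/D1."""
        p = ChemicalSynapseParams(depression_use_fraction=0.25)
        state = ChemicalSynapseState()
        d1 = depression_factor(p, state, 0.0)
        state = register_spike(p, state, 0.0)
        d2 = depression_factor(p, state, 20.0)
        s_fixed = 0.4
        v = -60.0
        i1 = s_fixed * d1 * p.max_conductance * (v - p.reversal)
        i2 = s_fixed * d2 * p.max_conductance * (v - p.reversal)
        assert i2 / i1 == pytest.approx(d2 / d1)


class TestSynapticCurrent:
    def test_closed_channels_no_current(self):
        p = ChemicalSynapseParams()
        st0 = ChemicalSynapseState(open_fraction=0.0)
        assert chemical_synaptic_current(p, st0, -60.0) == 0.0

    def test_zero_driving_force(self):
        p = ChemicalSynapseParams(reversal=-60.0)
        st0 = ChemicalSynapseState(open_fraction=0.5)
        assert chemical_synaptic_current(p, st0, -60.0) == 0.0

    def test_nmda_block_removed_at_depolarization(self):
        p = ChemicalSynapseParams(receptor="NMDA", max_conductance=2.0, reversal=0.0)
        st0 = ChemicalSynapseState(open_fraction=0.5, depression=0.8)
        i_strong = chemical_synaptic_current(p, st0, 60.0)
        unblocked = 0.5 * 0.8 * 2.0 * 60.0
        assert i_strong == pytest.approx(unblocked, rel=0.04)
        assert mg_block(60.0) > 0.96
        assert mg_block(-80.0) < 0.05

    def test_invalid_use_fraction(self):
        with pytest.raises(ValueError):
            ChemicalSynapseParams(depression_use_fraction=1.5)
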