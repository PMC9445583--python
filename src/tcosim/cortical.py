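"""Adaptive exponential integrate-and-fire dynamics for cortical PY and FS cells.

    Cm dv/dt = -g_L (v - E_L) + g_L * Delta * exp((v - v_th)/Delta) - w - I_syn
    tau_w dw/dt = a (v - E_L) - w            (+ b at each spike)
    I_syn = g_E (v - E_E) + g_I (v - E_I)
    tau_{E,I} dg_{E,I}/dt = -g_{E,I}         (+ Q_{E,I} per presynaptic spike)

Units: pF, nS, mV, pA, ms.  A spike is declared when v crosses the cutoff
voltage (the exponential term diverges past threshold); v is then reset to
v_rest and held there for the refractory period while w is incremented by b.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CortexNeuronParams",
    "CortexSynapseParams",
    "CortexNeuronState",
    "cortical_membrane_derivative",
    "adaptation_derivative",
    "on_spike",
    "conductance_update",
]


@dataclass
class CortexNeuronParams:
    cell_type: str = "PY"
    membrane_capacitance: float = 200.0   # pF
    leak_conductance: float = 10.0        # nS
    leak_reversal: float = -65.0          # mV
    threshold: float = -50.0              # mV (soft threshold v_th)
    slope_factor: float = 2.0             # mV (Delta)
    adaptation_coupling: float = 4.0      # nS (a)
    spike_adaptation_increment: float = 30.0  # pA (b)
    adaptation_time_constant: float = 150.0   # ms (tau_w)
    reset_potential: float = -65.0        # mV (v_rest)
    refractory_period: float = 2.0        # ms
    spike_cutoff_voltage: float = 0.0     # mV

    def __post_init__(self):
        if self.slope_factor <= 0:
            raise ValueError("slope factor must be > 0")
        if self.adaptation_time_constant <= 0:
            raise ValueError("adaptation time constant must be > 0")
        if self.refractory_period < 0:
            raise ValueError("refractory period must be >= 0")


@dataclass
class CortexSynapseParams:
    excitatory_reversal: float = 0.0      # mV
    inhibitory_reversal: float = -80.0    # mV
    excitatory_decay: float = 5.0         # ms
    inhibitory_decay: float = 10.0        # ms
    excitatory_quantum: float = 1.0       # nS
    inhibitory_quantum: float = 5.0       # nS

    def __post_init__(self):
        if self.excitatory_decay <= 0 or self.inhibitory_decay <= 0:
            raise ValueError("synaptic decay time constants must be > 0")
        if self.excitatory_quantum < 0 or self.inhibitory_quantum < 0:
            raise ValueError("quantal increments must be >= 0")


@dataclass
class CortexNeuronState:
    voltage: float = -65.0            # mV
    adaptation_current: float = 0.0   # pA
    g_exc: float = 0.0                # nS
    g_inh: float = 0.0                # nS
    refractory_remaining: float = 0.0  # ms


def synaptic_current(syn: CortexSynapseParams, state: CortexNeuronState) -> float:
    """I_syn in pA."""
    return state.g_exc * (state.voltage - syn.excitatory_reversal) + state.g_inh * (
        state.voltage - syn.inhibitory_reversal
    )


def cortical_membrane_derivative(
    params: CortexNeuronParams,
    syn: CortexSynapseParams,
    state: CortexNeuronState,
) -> float:
    """dv/dt in mV/ms; exponential argument clamped at the spike cutoff."""
    v = state.voltage
    arg = (v - params.threshold) / params.slope_factor
    # past the cutoff the event handler takes over; clamp to avoid overflow
    arg = min(arg, 8.0)
    i_exp = params.leak_conductance * params.slope_factor * np.exp(arg)
    dv = (
        -params.leak_conductance * (v - params.leak_reversal)
        + i_exp
        - state.adaptation_current
        - synaptic_current(syn, state)
    ) / params.membrane_capacitance
    return dv


def adaptation_derivative(params: CortexNeuronParams, state: CortexNeuronState) -> float:
    """Continuous part of dw/dt in pA/ms (the spike-triggered jump is in on_spike)."""
    return (
        params.adaptation_coupling * (state.voltage - params.leak_reversal)
        - state.adaptation_current
    ) / params.adaptation_time_constant


def on_spike(params: CortexNeuronParams, state: CortexNeuronState) -> CortexNeuronState:
    """Reset rule: v -> v_rest, w -> w + b, refractory clock armed."""
    return replace(
        state,
        voltage=params.reset_potential,
        adaptation_current=state.adaptation_current + params.spike_adaptation_increment,
        refractory_remaining=params.refractory_period,
    )


def conductance_update(
    syn: CortexSynapseParams,
    state: CortexNeuronState,
    dt: float,
    exc_spikes: int = 0,
    inh_spikes: int = 0,
) -> CortexNeuronState:
    """Exponential decay over ``dt`` plus Q-sized jumps per presynaptic spike."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if exc_spikes < 0 or inh_spikes < 0:
        raise ValueError("spike counts must be >= 0")
    g_e = state.g_exc * np.exp(-dt / syn.excitatory_decay) + exc_spikes * syn.excitatory_quantum
    g_i = state.g_inh * np.exp(-dt / syn.inhibitory_decay) + inh_spikes * syn.inhibitory_quantum
    return replace(state, g_exc=g_e, g_inh=g_i)
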