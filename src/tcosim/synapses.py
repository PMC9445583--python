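"""Thalamic chemical synapses and electrical gap junctions.

Chemical synaptic currents follow a first-order kinetic receptor model with
short-term depression:

    I_syn = s * D * g_syn * B(V) * (V - E_syn)
    ds/dt = alpha [T] (1 - s) - beta s
    D     = 1 - (1 - D_i (1 - U)) exp(-(t - t_i)/tau)

where [T] is a 0.5 mM transmitter pulse lasting 0.3 ms after each
presynaptic spike, U the fraction of synaptic resources consumed per spike
and tau the recovery time constant.  B(V) is unity for AMPA/GABA-A and the
sigmoidal magnesium-block factor for NMDA.  Gap junctions are ohmic:
I_gap = (V_pre - V_post) / R_g.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np

__all__ = [
    "GapJunctionSpec",
    "ChemicalSynapseParams",
    "ChemicalSynapseState",
    "gap_junction_current",
    "gating_fraction_derivative",
    "depression_factor",
    "depression_fixed_point",
    "chemical_synaptic_current",
    "mg_block",
]

TRANSMITTER_AMPLITUDE = 0.5  # mM
TRANSMITTER_DURATION = 0.3   # ms

#: Default gap-junction resistances (MOhm) by connected pair class.
DEFAULT_GAP_RESISTANCE = {"HTC-HTC": 100.0, "HTC-RTC": 300.0, "RE-RE": 300.0}


@dataclass
class GapJunctionSpec:
    pair_class: str = "HTC-HTC"
    resistance: float | None = None  # MOhm

    def __post_init__(self):
        if self.resistance is None:
            self.resistance = DEFAULT_GAP_RESISTANCE.get(self.pair_class, 300.0)
        if self.resistance <= 0:
            raise ValueError("gap junction resistance must be > 0")


@dataclass
class ChemicalSynapseParams:
    receptor: str = "AMPA"            # AMPA | NMDA | GABAA
    max_conductance: float = 1.0      # conductance unit chosen by the caller
    reversal: float = 0.0             # mV
    forward_rate: float = 1.1         # alpha, /mM/ms
    backward_rate: float = 0.19       # beta, /ms
    transmitter_amplitude: float = TRANSMITTER_AMPLITUDE  # mM
    transmitter_duration: float = TRANSMITTER_DURATION    # ms
    depression_use_fraction: float = 0.07   # U
    recovery_time_constant: float = 700.0   # tau, ms
    mg_concentration: float = 1.0     # mM, NMDA block

    def __post_init__(self):
        if not 0.0 <= self.depression_use_fraction <= 1.0:
            raise ValueError("U must lie in [0,1]")
        if self.forward_rate <= 0 or self.backward_rate <= 0:
            raise ValueError("binding rates must be > 0")
        if self.recovery_time_constant <= 0:
            raise ValueError("recovery time constant must be > 0")


@dataclass
class ChemicalSynapseState:
    open_fraction: float = 0.0           # s
    depression: float = 1.0              # D
    last_pre_spike_time: float = -np.inf  # t_i, ms
    depression_at_last_spike: float = 1.0  # D_i
    transmitter_off_time: float = -np.inf  # ms


def gap_junction_current(spec: GapJunctionSpec, v_pre: float, v_post: float) -> float:
    """Ohmic gap current in nA (mV / MOhm); positive flows into the post cell."""
    return (v_pre - v_post) / spec.resistance


def gating_fraction_derivative(
    params: ChemicalSynapseParams, s: float, transmitter_on: bool
) -> float:
    """ds/dt = alpha [T] (1-s) - beta s, with [T] the pulse amplitude or zero."""
    t_conc = params.transmitter_amplitude if transmitter_on else 0.0
    return params.forward_rate * t_conc * (1.0 - s) - params.backward_rate * s


def depression_factor(
    params: ChemicalSynapseParams, state: ChemicalSynapseState, t: float
) -> float:
    """D(t) = 1 - (1 - D_i (1-U)) exp(-(t - t_i)/tau) since the last spike."""
    t_i = state.last_pre_spike_time
    if t < t_i:
        raise ValueError("query time precedes the last presynaptic spike")
    if not np.isfinite(t_i):
        return 1.0
    u = params.depression_use_fraction
    tau = params.recovery_time_constant
    return 1.0 - (1.0 - state.depression_at_last_spike * (1.0 - u)) * exp(-(t - t_i) / tau)


def register_spike(
    params: ChemicalSynapseParams, state: ChemicalSynapseState, t: float
) -> ChemicalSynapseState:
    """Refresh (D_i, t_i) at a presynaptic spike and start a transmitter pulse.

    D_i is the depression value immediately before the spike; the running D
    drops by the factor (1 - U).
    """
    d_before = depression_factor(params, state, t)
    return ChemicalSynapseState(
        open_fraction=state.open_fraction,
        depression=d_before * (1.0 - params.depression_use_fraction),
        last_pre_spike_time=t,
        depression_at_last_spike=d_before,
        transmitter_off_time=t + params.transmitter_duration,
    )


def depression_fixed_point(params: ChemicalSynapseParams, interval: float) -> float:
    """Steady-state D* just before each spike of a periodic train.

    D* = (1 - e^(-dt/tau)) / (1 - (1-U) e^(-dt/tau)).
    """
    e = exp(-interval / params.recovery_time_constant)
    return (1.0 - e) / (1.0 - (1.0 - params.depression_use_fraction) * e)


def mg_block(v: float, mg: float = 1.0) -> float:
    """Sigmoidal magnesium-block factor for NMDA receptors."""
    return 1.0 / (1.0 + np.exp(-0.062 * v) * mg / 3.57)


def chemical_synaptic_current(
    params: ChemicalSynapseParams, state: ChemicalSynapseState, v_post: float
) -> float:
    """I_syn = s D g_syn B(V) (V - E_syn); units follow ``max_conductance``."""
    b = mg_block(v_post, params.mg_concentration) if params.receptor == "NMDA" else 1.0
    return (
        state.open_fraction
        * state.depression
        * params.max_conductance
        * b
        * (v_post - params.reversal)
    )
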