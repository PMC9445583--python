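"""Hodgkin-Huxley point-neuron dynamics for the four thalamic cell types.

The current balance for a thalamic neuron (HTC, RTC, IN or RE) is

    Cm dV/dt = -g_L (V - E_L) - g_KL (V - E_KL) - sum I_int - sum I_syn

with intrinsic currents I_i = g_i m^p h^q (V - E_i) (positive = outward) and
intracellular calcium regulated by

    d[Ca]/dt = -I_Ca / (z F w) + ([Ca]_rest - [Ca]) / tau_Ca.

These reference implementations operate on one neuron and are the ground
truth the compiled network core is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .channels import GatingSpec, IonChannelSpec

__all__ = [
    "CalciumDynamicsParams",
    "ThalamicNeuronParams",
    "ThalamicNeuronState",
    "channel_current",
    "gating_derivative",
    "calcium_derivative",
    "thalamic_membrane_derivative",
]

FARADAY = 96485.332  # C/mol


@dataclass
class CalciumDynamicsParams:
    """First-order intracellular calcium pool.

    ``shell_thickness`` w is the perimembranous shell depth in um; with the
    2+ valence and Faraday constant the influx term for a current density in
    uA/cm^2 is -10 * I_Ca / (z F w) in mM/ms.
    """

    shell_thickness: float = 1.0        # um
    valence: int = 2
    faraday_constant: float = FARADAY   # C/mol
    removal_time_constant: float = 5.0  # ms
    resting_concentration: float = 2.4e-4  # mM

    def __post_init__(self):
        if self.removal_time_constant <= 0:
            raise ValueError("calcium removal time constant must be > 0")
        if self.resting_concentration <= 0:
            raise ValueError("resting calcium must be > 0")
        if self.valence != 2:
            raise ValueError("calcium valence must be 2")

    @property
    def influx_factor(self) -> float:
        """mM/ms per uA/cm^2 of inward calcium current (the 10 converts units)."""
        return 10.0 / (self.valence * self.faraday_constant * self.shell_thickness)


@dataclass
class ThalamicNeuronParams:
    cell_type: str = "RTC"
    membrane_capacitance: float = 1.0   # uF/cm^2
    leak_conductance: float = 0.01      # mS/cm^2
    leak_reversal: float = -70.0        # mV
    k_leak_conductance: float = 0.0     # mS/cm^2
    k_leak_reversal: float = -90.0      # mV
    channels: List[IonChannelSpec] = field(default_factory=list)
    calcium: CalciumDynamicsParams = field(default_factory=CalciumDynamicsParams)
    area: float = 2.9e-4                # cm^2, converts point conductances to densities


@dataclass
class ThalamicNeuronState:
    voltage: float = -70.0              # mV
    gating_values: Dict[str, float] = field(default_factory=dict)
    calcium: float = 2.4e-4             # mM

    def validate(self):
        for name, x in self.gating_values.items():
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating value {name}={x} outside [0,1]")
        if self.calcium <= 0:
            raise ValueError("calcium must stay positive")


def _gate_value(state: ThalamicNeuronState, channel: IonChannelSpec, which: str) -> float:
    key = f"{channel.name}_{which}"
    if key not in state.gating_values:
        raise KeyError(
            f"channel {channel.name} declares an exponent for '{which}' but the "
            f"state holds no gating value '{key}'"
        )
    return state.gating_values[key]


def channel_current(channel: IonChannelSpec, state: ThalamicNeuronState) -> float:
    """I_i = g_i m^p h^q (V - E_i) in uA/cm^2 (positive = outward)."""
    g = channel.max_conductance_density
    if g == 0.0:
        return 0.0
    factor = 1.0
    if channel.activation_exponent > 0:
        m = _gate_value(state, channel, "m")
        factor *= m ** channel.activation_exponent
    if channel.inactivation_exponent > 0:
        h = _gate_value(state, channel, "h")
        factor *= h ** channel.inactivation_exponent
    return g * factor * (state.voltage - channel.reversal_potential)


def gating_derivative(gating: GatingSpec, x: float, v: float, ca: float = 0.0) -> float:
    """dx/dt = phi (x_inf(V,Ca) - x) / tau(V,Ca) in 1/ms."""
    return gating.derivative(x, v, ca)


def calcium_derivative(params: CalciumDynamicsParams, i_ca_total: float, ca: float) -> float:
    """d[Ca]/dt in mM/ms; ``i_ca_total`` is the summed calcium current (uA/cm^2)."""
    if ca <= 0:
        raise ValueError("calcium must be > 0")
    influx = -params.influx_factor * i_ca_total
    relax = (params.resting_concentration - ca) / params.removal_time_constant
    return influx + relax


def thalamic_membrane_derivative(
    params: ThalamicNeuronParams,
    state: ThalamicNeuronState,
    i_syn_total: float = 0.0,
) -> float:
    """dV/dt in mV/ms for the full current balance (synaptic current in uA/cm^2)."""
    v = state.voltage
    i_leak = params.leak_conductance * (v - params.leak_reversal)
    i_kleak = params.k_leak_conductance * (v - params.k_leak_reversal)
    i_int = sum(channel_current(ch, state) for ch in params.channels)
    return (-i_leak - i_kleak - i_int - i_syn_total) / params.membrane_capacitance


def leak_steady_state(params: ThalamicNeuronParams) -> float:
    """Resting voltage with all intrinsic channels and synapses silent."""
    g = params.leak_conductance + params.k_leak_conductance
    return (
        params.leak_conductance * params.leak_reversal
        + params.k_leak_conductance * params.k_leak_reversal
    ) / g


def initial_state(params: ThalamicNeuronParams, v0: float | None = None) -> ThalamicNeuronState:
    """State with gates at steady state for ``v0`` and calcium at rest."""
    if v0 is None:
        v0 = leak_steady_state(params)
    ca0 = params.calcium.resting_concentration
    gating = {}
    for ch in params.channels:
        if ch.activation_exponent > 0:
            gating[f"{ch.name}_m"] = float(ch.activation.steady_state(v0, ca0))
        if ch.inactivation_exponent > 0:
            gating[f"{ch.name}_h"] = float(ch.inactivation.steady_state(v0, ca0))
    return ThalamicNeuronState(voltage=v0, gating_values=gating, calcium=ca0)
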