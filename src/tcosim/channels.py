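"""Voltage- and calcium-gated ion channel kinetics for thalamic neurons.

Each intrinsic current follows the Hodgkin-Huxley template

    I_i = g_i * m^p * h^q * (V - E_i)          [uA/cm^2]

with first-order gating kinetics

    dx/dt = phi_x * (x_inf(V, Ca) - x) / tau_x(V, Ca)   [1/ms]

The kinetic functions collected here are the standard forms used by the
Destexhe/Huguenard family of thalamic models (transient sodium and delayed
rectifier built on Traub-style rate functions, low-threshold T-type calcium
for relay and reticular cells, a high-threshold calcium current supporting
high-threshold bursting, the hyperpolarization-activated cation current, and
a calcium-activated potassium afterhyperpolarization current).  All voltages
are in mV, times in ms, calcium in mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "GatingSpec",
    "IonChannelSpec",
    "vtrap",
    "STANDARD_GATES",
    "gate_tables",
]


def vtrap(x, y):
    """x / (1 - exp(-x/y)), numerically safe at x -> 0."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(x / y) < 1e-6,
                       y * (1.0 + x / (2.0 * y)),
                       x / (1.0 - np.exp(-np.clip(x / y, -500, 500))))
    return out if out.ndim else float(out)


@dataclass
class GatingSpec:
    """One gating variable: steady state, time constant and temperature factor.

    ``steady_state_fn`` and ``time_constant_fn`` map ``(V [mV], Ca [mM])`` to a
    dimensionless value in [0, 1] and a strictly positive time in ms.
    ``temperature_factor`` is the dimensionless phi multiplying the relaxation
    rate.  ``ca_dependent`` marks gates whose kinetics read the calcium
    concentration (the AHP activation gate).
    """

    name: str
    steady_state_fn: Callable[[float, float], float]
    time_constant_fn: Callable[[float, float], float]
    temperature_factor: float = 1.0
    ca_dependent: bool = False

    def steady_state(self, v, ca=0.0):
        x = self.steady_state_fn(v, ca)
        return np.clip(x, 0.0, 1.0)

    def time_constant(self, v, ca=0.0):
        tau = self.time_constant_fn(v, ca)
        if np.any(np.asarray(tau) <= 0):
            raise ValueError(f"gate {self.name}: time constant must be > 0")
        return tau

    def derivative(self, x, v, ca=0.0):
        """phi * (x_inf - x) / tau for gating value ``x``."""
        if np.any((np.asarray(x) < 0) | (np.asarray(x) > 1)):
            raise ValueError(f"gate {self.name}: gating value outside [0,1]")
        return self.temperature_factor * (self.steady_state(v, ca) - x) / self.time_constant(v, ca)


@dataclass
class IonChannelSpec:
    """One HH-style intrinsic current.

    ``max_conductance_density`` g_i in mS/cm^2, ``reversal_potential`` E_i in
    mV.  ``activation``/``inactivation`` name gates from :data:`STANDARD_GATES`
    (or carry explicit :class:`GatingSpec` objects); exponents p, q >= 0.
    ``is_calcium_current`` flags currents whose flux feeds the intracellular
    calcium pool.
    """

    name: str
    max_conductance_density: float
    reversal_potential: float
    activation: Optional[GatingSpec] = None
    activation_exponent: int = 0
    inactivation: Optional[GatingSpec] = None
    inactivation_exponent: int = 0
    is_calcium_current: bool = False

    def __post_init__(self):
        if self.max_conductance_density < 0:
            raise ValueError(f"channel {self.name}: conductance must be >= 0")
        if self.activation_exponent < 0 or self.inactivation_exponent < 0:
            raise ValueError(f"channel {self.name}: exponents must be >= 0")
        if self.activation_exponent > 0 and self.activation is None:
            raise ValueError(f"channel {self.name}: activation gate missing")
        if self.inactivation_exponent > 0 and self.inactivation is None:
            raise ValueError(f"channel {self.name}: inactivation gate missing")


# ---------------------------------------------------------------------------
# Standard gate kinetics (V in mV, tau in ms).
# ---------------------------------------------------------------------------

def _na_m_rates(v, vt):
    a = 0.32 * vtrap(v - vt - 13.0, 4.0)
    b = 0.28 * vtrap(-(v - vt - 40.0), 5.0)
    return a, b


def _na_h_rates(v, vt):
    a = 0.128 * np.exp(-(v - vt - 17.0) / 18.0)
    b = 4.0 / (1.0 + np.exp(-(v - vt - 40.0) / 5.0))
    return a, b


def _k_n_rates(v, vt):
    a = 0.032 * vtrap(v - vt - 15.0, 5.0)
    b = 0.5 * np.exp(-(v - vt - 10.0) / 40.0)
    return a, b


def _rates_to_inf_tau(rate_fn, vt, tau_min=0.05):
    def inf(v, ca=0.0):
        a, b = rate_fn(v, vt)
        return a / (a + b)

    def tau(v, ca=0.0):
        a, b = rate_fn(v, vt)
        return np.maximum(1.0 / (a + b), tau_min)

    return inf, tau


def make_na_gates(vt=-52.0, phi=1.0):
    m_inf, m_tau = _rates_to_inf_tau(_na_m_rates, vt)
    h_inf, h_tau = _rates_to_inf_tau(_na_h_rates, vt)
    return (
        GatingSpec("na_m", m_inf, m_tau, phi),
        GatingSpec("na_h", h_inf, h_tau, phi),
    )


def make_k_gate(vt=-52.0, phi=1.0):
    n_inf, n_tau = _rates_to_inf_tau(_k_n_rates, vt)
    return GatingSpec("k_n", n_inf, n_tau, phi)


# Low-threshold T-type calcium, relay-cell variant (Huguenard-McCormick form).
def _tlt_m_inf(v, ca=0.0):
    return 1.0 / (1.0 + np.exp(-(v + 57.0) / 6.2))


def _tlt_m_tau(v, ca=0.0):
    return 0.612 + 1.0 / (np.exp(-(v + 131.6) / 16.7) + np.exp((v + 16.8) / 18.2))


def _tlt_h_inf(v, ca=0.0):
    return 1.0 / (1.0 + np.exp((v + 81.0) / 4.0))


def _tlt_h_tau(v, ca=0.0):
    return 30.8 + (211.4 + np.exp((v + 113.2) / 5.0)) / (1.0 + np.exp((v + 84.0) / 3.2))


# Low-threshold T-type calcium, reticular-cell variant (Huguenard-Prince form).
def _tre_m_inf(v, ca=0.0):
    return 1.0 / (1.0 + np.exp(-(v + 52.0) / 7.4))


def _tre_m_tau(v, ca=0.0):
    return 3.0 + 1.0 / (np.exp((v + 27.0) / 10.0) + np.exp(-(v + 102.0) / 15.0))


def _tre_h_inf(v, ca=0.0):
    return 1.0 / (1.0 + np.exp((v + 80.0) / 5.0))


def _tre_h_tau(v, ca=0.0):
    return 85.0 + 1.0 / (np.exp((v + 48.0) / 4.0) + np.exp(-(v + 407.0) / 50.0))


# High-threshold calcium current supporting high-threshold bursting: fast
# activation near -30 mV, slow voltage-dependent inactivation whose recovery
# rate controls the inter-burst interval.
def _tht_m_inf(v, ca=0.0):
    return 1.0 / (1.0 + np.exp(-(v + 35.0) / 4.0))


def _tht_m_tau(v, ca=0.0):
    return np.full_like(np.asarray(v, dtype=float), 2.0) if np.ndim(v) else 2.0


def _tht_h_inf(v, ca=0.0):
    return 1.0 / (1.0 + np.exp((v + 64.0) / 2.5))


def _tht_h_tau(v, ca=0.0):
    return 12.0 + 320.0 / (1.0 + np.exp((v + 64.0) / 4.0))


# Non-inactivating high-threshold (L-type) calcium current: activates during
# each action potential and feeds the calcium pool that drives the AHP,
# providing spike-frequency adaptation in tonic mode.
def _cal_m_inf(v, ca=0.0):
    return 1.0 / (1.0 + np.exp(-(v + 25.0) / 5.0))


def _cal_m_tau(v, ca=0.0):
    return np.full_like(np.asarray(v, dtype=float), 1.0) if np.ndim(v) else 1.0


# Slow non-inactivating (M-type) potassium current: graded depolarization-
# activated adaptation that limits tonic firing rates.
def _km_m_inf(v, ca=0.0):
    return 1.0 / (1.0 + np.exp(-(v + 30.0) / 10.0))


def _km_m_tau(v, ca=0.0):
    return 8.0 + 40.0 / (np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))


# High-threshold M-current variant: engages mainly at depolarized
# inter-spike voltages, flattening the frequency-input curve at strong drive.
def _kms_m_inf(v, ca=0.0):
    return 1.0 / (1.0 + np.exp(-(v + 18.0) / 6.0))


def _kms_m_tau(v, ca=0.0):
    return 8.0 + 40.0 / (np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))


# Hyperpolarization-activated cation current (McCormick-Pape kinetics).
def _h_r_inf(v, ca=0.0):
    return 1.0 / (1.0 + np.exp((v + 75.0) / 5.5))


def _h_r_tau(v, ca=0.0):
    return 20.0 + 1000.0 / (np.exp((v + 71.5) / 14.2) + np.exp(-(v + 89.0) / 11.6))


# Calcium-activated potassium (AHP): alpha = kf * Ca^2, beta constant.
AHP_KF = 48.0      # /mM^2/ms
AHP_BETA = 0.03    # /ms


def _ahp_m_inf(v, ca):
    a = AHP_KF * ca * ca
    return a / (a + AHP_BETA)


def _ahp_m_tau(v, ca):
    a = AHP_KF * ca * ca
    return np.maximum(1.0 / (a + AHP_BETA), 0.1)


AHP_LIN_KF = 2.0     # /mM/ms
AHP_LIN_BETA = 0.01  # /ms


def _ahp_lin_m_inf(v, ca):
    a = AHP_LIN_KF * ca
    return a / (a + AHP_LIN_BETA)


def _ahp_lin_m_tau(v, ca):
    a = AHP_LIN_KF * ca
    return np.maximum(1.0 / (a + AHP_LIN_BETA), 0.1)


#: Registry of the standard gates, keyed by the names channel configs use.
STANDARD_GATES = {
    "na_m": make_na_gates()[0],
    "na_h": make_na_gates()[1],
    "k_n": make_k_gate(),
    "tlt_m": GatingSpec("tlt_m", _tlt_m_inf, _tlt_m_tau, 4.6),
    "tlt_h": GatingSpec("tlt_h", _tlt_h_inf, _tlt_h_tau, 3.7),
    "tre_m": GatingSpec("tre_m", _tre_m_inf, _tre_m_tau, 5.0),
    "tre_h": GatingSpec("tre_h", _tre_h_inf, _tre_h_tau, 3.0),
    "tht_m": GatingSpec("tht_m", _tht_m_inf, _tht_m_tau, 1.0),
    "tht_h": GatingSpec("tht_h", _tht_h_inf, _tht_h_tau, 1.0),
    "cal_m": GatingSpec("cal_m", _cal_m_inf, _cal_m_tau, 1.0),
    "km_m": GatingSpec("km_m", _km_m_inf, _km_m_tau, 1.0),
    "kms_m": GatingSpec("kms_m", _kms_m_inf, _kms_m_tau, 1.0),
    "h_r": GatingSpec("h_r", _h_r_inf, _h_r_tau, 1.0),
    "ahp_m": GatingSpec("ahp_m", _ahp_m_inf, _ahp_m_tau, 1.0, ca_dependent=True),
    "ahp_lin_m": GatingSpec("ahp_lin_m", _ahp_lin_m_inf, _ahp_lin_m_tau, 1.0, ca_dependent=True),
}


def gate_tables(gate: GatingSpec, v_min=-120.0, v_max=60.0, dv=0.05):
    """Tabulate x_inf(V) and tau(V)/phi on a uniform voltage grid.

    Used by the compiled integration core; calcium-dependent gates are
    evaluated analytically there and are not tabulated.
    """
    if gate.ca_dependent:
        raise ValueError("calcium-dependent gates are not tabulated")
    v = np.arange(v_min, v_max + dv / 2, dv)
    inf = np.asarray(gate.steady_state_fn(v, 0.0), dtype=np.float64)
    tau = np.asarray(gate.time_constant_fn(v, 0.0), dtype=np.float64)
    if tau.ndim == 0:
        tau = np.full_like(v, float(tau))
    return v, np.clip(inf, 0.0, 1.0), tau / gate.temperature_factor
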