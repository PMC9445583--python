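"""Default configuration of the thalamocortical oscillation network.

Everything a simulation needs is in one nested mapping: population sizes and
grids, per-cell-type membrane and channel parameters, synapse parameters per
projection, gap-junction topology, background drives and integration
settings.  The channel rosters and kinetic constants follow the unified
thalamic network model family this model adopts (Destexhe/Huguenard-style
kinetics); conductance densities and synaptic strengths are prior-model
defaults calibrated once so the three background-drive levels (2.5, 15 and
25 nS) produce the alpha/beta/gamma oscillatory states at their nominal
frequencies.  Every value can be overridden via the YAML config file.

Units: thalamic membrane quantities are densities (uF/cm^2, mS/cm^2) with
point conductances in uS converted through the membrane area; cortical AdEx
quantities are pF / nS / pA; voltages mV, times ms, calcium mM.
"""

from __future__ import annotations

import copy
import hashlib
import json

import yaml

__all__ = ["default_config", "load_config", "save_config", "merge_config", "config_digest"]


def default_config() -> dict:
    return copy.deepcopy(_DEFAULT)


def load_config(path) -> dict:
    """Load a YAML config file, filling unspecified fields from the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(default_config(), user)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def merge_config(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def config_digest(cfg: dict) -> str:
    """Stable short hash of a config for provenance stamping."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Channel parameter blocks.  g in mS/cm^2, E in mV; gates reference the
# kinetics registry in channels.py.
# ---------------------------------------------------------------------------

def _chan(g, e, m=None, p=0, h=None, q=0, is_ca=False):
    return {"g": g, "e": e, "m_gate": m, "p": p, "h_gate": h, "q": q, "is_ca": is_ca}


_TC_COMMON = {
    "cm": 1.0,            # uF/cm^2
    "g_l": 0.01,          # mS/cm^2 (heterogeneity applied by the builder)
    "e_l": -70.0,
    "g_kl": 0.006,
    "e_kl": -90.0,
    "calcium": {"shell_um": 1.0, "tau_ms": 50.0, "rest_mM": 2.4e-4},
}

_DEFAULT = {
    "area_cm2": 2.9e-4,
    "populations": {
        "HTC": {"size": 49, "grid": [7, 7]},
        "RTC": {"size": 144, "grid": [12, 12]},
        "IN": {"size": 64, "grid": [8, 8]},
        "RE": {"size": 100, "grid": [10, 10]},
        "PY": {"size": 80},
        "FS": {"size": 20},
    },
    "thalamic_cells": {
        "HTC": {
            **_TC_COMMON,
            "g_kl": 0.0,
            "e_l": -68.0,
            "calcium": {"shell_um": 2.0, "tau_ms": 60.0, "rest_mM": 2.4e-4},
            "channels": {
                "na": _chan(90.0, 50.0, "na_m", 3, "na_h", 1),
                "kdr": _chan(10.0, -90.0, "k_n", 4),
                "t_lt": _chan(2.0, 120.0, "tlt_m", 2, "tlt_h", 1, is_ca=True),
                "t_ht": _chan(10.0, 120.0, "tht_m", 2, "tht_h", 1, is_ca=True),
                "km": _chan(0.24, -90.0, "km_m", 1),
                "kms": _chan(0.5, -90.0, "kms_m", 1),
                "h": _chan(0.05, -43.0, "h_r", 1),
                "ahp": _chan(0.1, -90.0, "ahp_m", 2),
            },
        },
        "RTC": {
            **_TC_COMMON,
            "g_kl": 0.0,
            "channels": {
                "na": _chan(90.0, 50.0, "na_m", 3, "na_h", 1),
                "kdr": _chan(10.0, -90.0, "k_n", 4),
                "t_lt": _chan(1.0, 120.0, "tlt_m", 2, "tlt_h", 1, is_ca=True),
                "km": _chan(0.24, -90.0, "km_m", 1),
                "kms": _chan(0.5, -90.0, "kms_m", 1),
                "h": _chan(0.015, -43.0, "h_r", 1),
                "ahp": _chan(0.05, -90.0, "ahp_m", 2),
            },
        },
        "IN": {
            **_TC_COMMON,
            "g_kl": 0.002,
            "channels": {
                "na": _chan(90.0, 50.0, "na_m", 3, "na_h", 1),
                "kdr": _chan(10.0, -90.0, "k_n", 4),
                "t_lt": _chan(1.0, 120.0, "tlt_m", 2, "tlt_h", 1, is_ca=True),
                "km": _chan(0.25, -90.0, "km_m", 1),
                "kms": _chan(0.5, -90.0, "kms_m", 1),
                "h": _chan(0.01, -43.0, "h_r", 1),
                "ahp": _chan(0.05, -90.0, "ahp_m", 2),
            },
        },
        "RE": {
            **_TC_COMMON,
            "e_l": -77.0,
            "g_kl": 0.002,
            "channels": {
                "na": _chan(100.0, 50.0, "na_m", 3, "na_h", 1),
                "kdr": _chan(10.0, -90.0, "k_n", 4),
                "t_re": _chan(1.5, 120.0, "tre_m", 2, "tre_h", 1, is_ca=True),
                "km": _chan(0.25, -90.0, "km_m", 1),
                "kms": _chan(0.3, -90.0, "kms_m", 1),
                "ahp": _chan(0.05, -90.0, "ahp_m", 2),
            },
        },
    },
    "heterogeneity": {
        # leakage conductance drawn uniformly within +-25% of the default
        "g_l_range": [0.0075, 0.0125],
        "populations": ["HTC", "RTC", "IN", "RE"],
    },
    "cortical_cells": {
        "PY": {
            "cm": 200.0, "g_l": 10.0, "e_l": -65.0, "v_th": -50.0, "delta": 2.0,
            "a": 4.0, "b": 30.0, "tau_w": 150.0, "v_reset": -65.0,
            "refractory": 2.0, "v_cut": 0.0,
        },
        "FS": {
            "cm": 100.0, "g_l": 10.0, "e_l": -65.0, "v_th": -48.0, "delta": 1.0,
            "a": 0.0, "b": 30.0, "tau_w": 60.0, "v_reset": -65.0,
            "refractory": 1.0, "v_cut": 0.0,
        },
    },
    "cortex_synapse": {
        "e_exc": 0.0, "e_inh": -80.0, "tau_exc": 5.0, "tau_inh": 15.0,
    },
    # Receptor kinetic constants (first-order transmitter binding).
    "receptors": {
        "AMPA": {"alpha": 1.1, "beta": 0.19},
        "NMDA": {"alpha": 0.072, "beta": 0.0066, "mg_mM": 1.0},
        "GABAA": {"alpha": 5.0, "beta": 0.18},
    },
    # Short-term depression applied to all chemical synapses.
    "depression": {"U": 0.07, "tau_ms": 700.0},
    # Chemical projections: conductance per synapse in uS; probability of an
    # edge per ordered (source, target) pair.  Connection statistics are not
    # in the main text of the source model description; these are exposed
    # prior-model defaults.
    "projections": [
        {"source": "HTC", "target": "IN", "receptor": "AMPA", "p": 0.3, "g_uS": 0.008, "e_mV": 0.0},
        {"source": "HTC", "target": "RE", "receptor": "AMPA", "p": 0.2, "g_uS": 0.008, "e_mV": 0.0},
        {"source": "RTC", "target": "RE", "receptor": "AMPA", "p": 0.2, "g_uS": 0.008, "e_mV": 0.0},
        {"source": "RE", "target": "HTC", "receptor": "GABAA", "p": 0.1, "g_uS": 0.0005, "e_mV": -85.0},
        {"source": "RE", "target": "RTC", "receptor": "GABAA", "p": 0.2, "g_uS": 0.003, "e_mV": -85.0},
        {"source": "RE", "target": "IN", "receptor": "GABAA", "p": 0.2, "g_uS": 0.002, "e_mV": -85.0},
        {"source": "RE", "target": "RE", "receptor": "GABAA", "p": 0.2, "g_uS": 0.002, "e_mV": -85.0},
        {"source": "IN", "target": "RTC", "receptor": "GABAA", "p": 0.3, "g_uS": 0.003, "e_mV": -85.0},
        # corticothalamic feedback
        {"source": "PY", "target": "RTC", "receptor": "AMPA", "p": 0.1, "g_uS": 0.001, "e_mV": 0.0},
        {"source": "PY", "target": "RE", "receptor": "AMPA", "p": 0.1, "g_uS": 0.001, "e_mV": 0.0},
    ],
    # Cortical quantal projections (Q jumps on g_E / g_I, in nS).
    "cortical_projections": [
        {"source": "PY", "target": "PY", "p": 0.5, "q_nS": 0.2, "kind": "exc"},
        {"source": "PY", "target": "FS", "p": 0.8, "q_nS": 0.15, "kind": "exc"},
        {"source": "FS", "target": "PY", "p": 0.8, "q_nS": 1.0, "kind": "inh"},
        {"source": "FS", "target": "FS", "p": 0.8, "q_nS": 0.3, "kind": "inh"},
        # thalamocortical drive carried by relay cells
        {"source": "RTC", "target": "PY", "p": 0.2, "q_nS": 2.0, "kind": "exc"},
        {"source": "RTC", "target": "FS", "p": 0.2, "q_nS": 0.6, "kind": "exc"},
    ],
    "gap_junctions": {
        # spatial-neighborhood coupling on the population grids; radius in
        # source-grid units, resistance in MOhm
        "HTC-HTC": {"radius": 3.0, "r_mohm": 100.0},
        "HTC-RTC": {"radius": 0.2, "r_mohm": 300.0},
        "RE-RE": {"radius": 1.5, "r_mohm": 300.0},
    },
    "drives": {
        "thalamic": {
            # independent Poisson spikes onto every thalamic neuron; the
            # conductance (nS) selects the oscillatory state:
            # 2.5 -> alpha, 15 -> beta, 25 -> gamma
            "rate_hz": 100.0,
            "g_nS": {"alpha": 2.5, "beta": 15.0, "gamma": 25.0},
            "tau_ms": 5.0,
            "e_mV": 0.0,
        },
        "cortical": {
            # 80 i.i.d. 2-Hz excitatory Poisson trains per neuron
            "train_count": 80,
            "rate_hz": 2.0,
            "q_nS": 1.2,
        },
    },
    "flicker": {
        "frequency_hz": 40.0,
        "intensity": 1,          # spikes per flash, 1..3
        "duty_cycle": None,      # fraction (multiple of 1/6); None -> intensity/6
        "onset_ms": 0.0,
        "gc_synapse": {
            "ampa_uS": 0.15,
            "nmda_uS": 0.05,
            "e_mV": 10.0,
            # GC->IN strengths are scaled so that ~3 near-simultaneous
            # inputs are needed to fire an IN cell
            "in_scale": 0.075,
            "tc_nmda": False,    # TC response is monosynaptic AMPA
        },
    },
    "simulation": {
        "dt_ms": 0.02,
        "duration_ms": 10000.0,
        "warmup_ms": 1000.0,
        "v_init_jitter_mV": 5.0,
        "record_decimation": 5,   # record every Nth step (0.1 ms at default dt)
        "spike_threshold_mV": 0.0,
        "spike_lockout_ms": 1.0,
    },
}
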