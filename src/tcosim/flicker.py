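"""Retinal ganglion-cell input for rhythmic light-flicker stimulation.

Periodic global flicker entrains the resonant ON response of the ganglion
cell population, which is reduced to a single GC spike source firing at the
flicker frequency.  Intensity is the number of spikes per flash (1-3) and
the duty cycle is the ON fraction of each period in sixths; by default a
flash of intensity k occupies a k/6 duty cycle, with the two knobs
independently overridable.  The GC connects to every HTC, RTC and IN cell:
TC cells receive monosynaptic AMPA excitation with a +10 mV reversal, IN
cells receive AMPA+NMDA scaled so that about three near-simultaneous inputs
are needed to evoke a spike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .network import Network, Projection

__all__ = ["FlickerProtocol", "GCSynapseParams", "generate_gc_spike_train",
           "attach_gc_input", "calibrate_gc_in_scale"]

#: minimum spacing between two GC spikes inside one ON window
MIN_SPIKE_SPACING_MS = 1.0


@dataclass
class FlickerProtocol:
    frequency_hz: float = 40.0
    intensity: int = 1                  # spikes per flash
    duty_cycle: Optional[float] = None  # fraction of the period; None -> intensity/6
    onset_ms: float = 0.0
    duration_ms: float = 10000.0

    def __post_init__(self):
        if not 1 <= int(self.intensity) <= 3:
            raise ValueError("intensity must be 1, 2 or 3 spikes per flash")
        if self.duty_cycle is None:
            self.duty_cycle = self.intensity / 6.0
        k = round(self.duty_cycle * 6.0)
        if not (1 <= k <= 5 and abs(self.duty_cycle * 6.0 - k) < 1e-9):
            raise ValueError("duty cycle must be a multiple of 1/6 between 1/6 and 5/6")
        if self.frequency_hz <= 0:
            raise ValueError("flicker frequency must be > 0")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.frequency_hz

    @property
    def on_window_ms(self) -> float:
        return self.duty_cycle * self.period_ms


@dataclass
class GCSynapseParams:
    ampa_uS: float = 0.15
    nmda_uS: float = 0.05
    e_mV: float = 10.0
    in_scale: float = 1.0     # GC->IN strength relative to GC->TC
    tc_nmda: bool = False     # include the NMDA component at TC synapses


def generate_gc_spike_train(protocol: FlickerProtocol) -> np.ndarray:
    """Deterministic GC spike times (ms) for one flicker protocol.

    Each period contributes ``intensity`` spikes spanning the ON window:
    a single spike sits at the window onset; multiple spikes are equally
    spaced from the onset to the end of the window (inclusive), so a longer
    duty cycle spreads the same number of spikes over a wider fraction of
    the period.
    """
    if protocol.duration_ms <= 0:
        return np.empty(0)
    period = protocol.period_ms
    window = protocol.on_window_ms
    k = int(protocol.intensity)
    if k == 1:
        offsets = np.array([0.0])
    else:
        offsets = np.arange(k) * (window / (k - 1))
        if window / (k - 1) < MIN_SPIKE_SPACING_MS:
            raise ValueError(
                f"ON window of {window:.2f} ms cannot hold {k} spikes at "
                f">= {MIN_SPIKE_SPACING_MS} ms spacing"
            )
    n_cycles = int(np.ceil(protocol.duration_ms / period)) + 1
    starts = protocol.onset_ms + np.arange(n_cycles) * period
    times = (starts[:, None] + offsets[None, :]).ravel()
    end = protocol.onset_ms + protocol.duration_ms
    return times[(times >= protocol.onset_ms) & (times < end)]


def attach_gc_input(net: Network, params: GCSynapseParams | None = None) -> Network:
    """Wire the single GC onto every HTC, RTC and IN cell (in place).

    Fan-out is the full TC+IN complement (257 in the default network).
    """
    if params is None:
        gc_cfg = net.config["flicker"]["gc_synapse"]
        params = GCSynapseParams(
            ampa_uS=gc_cfg["ampa_uS"], nmda_uS=gc_cfg["nmda_uS"],
            e_mV=gc_cfg["e_mV"], in_scale=gc_cfg["in_scale"],
            tc_nmda=gc_cfg.get("tc_nmda", False),
        )
    receptors = net.config["receptors"]
    dep = net.config["depression"]
    gc_u = float(net.config["flicker"]["gc_synapse"].get("depression_U", dep["U"]))
    net.gc_in_scale = params.in_scale

    def _proj(target, receptor, g_uS):
        n_tgt = net.pop_sizes[target]
        kin = receptors[receptor]
        return Projection(
            source="GC", target=target, receptor=receptor, g_uS=g_uS,
            e_mV=params.e_mV, alpha=float(kin["alpha"]), beta=float(kin["beta"]),
            U=gc_u, tau_rec=float(dep["tau_ms"]),
            indptr=np.arange(n_tgt + 1, dtype=np.int64),
            src=np.zeros(n_tgt, dtype=np.int64),
            mg_mM=float(kin.get("mg_mM", 1.0)),
        )

    if params.in_scale is None:
        params.in_scale = calibrate_gc_in_scale(net.config)
    if all(net.pop_sizes.get(p, 0) == 0 for p in ("HTC", "RTC", "IN")):
        raise ValueError("network lacks the TC and IN populations for GC input")
    net.projections = [p for p in net.projections if p.source != "GC"]
    for pop in ("HTC", "RTC"):
        if net.pop_sizes.get(pop, 0):
            net.projections.append(_proj(pop, "AMPA", params.ampa_uS))
            if params.tc_nmda:
                net.projections.append(_proj(pop, "NMDA", params.nmda_uS))
    if net.pop_sizes.get("IN", 0):
        net.projections.append(_proj("IN", "AMPA", params.ampa_uS * params.in_scale))
        net.projections.append(_proj("IN", "NMDA", params.nmda_uS * params.in_scale))
    return net


def _in_fires(cfg, scale: float, n_spikes: int) -> bool:
    """Does an isolated, quiescent IN cell spike to ``n_spikes`` GC inputs?"""
    from .engine import SimulationSettings, integrate, single_cell_config
    from .network import build_network

    cell_cfg = single_cell_config("IN", cfg)
    cell_cfg["drives"]["thalamic"]["g_nS"] = {"calibration": 0.0}
    cell_cfg["drives"]["cortical"] = {"train_count": 0, "rate_hz": 0.0, "q_nS": 0.0}
    net = build_network(cell_cfg, seed=0)
    gc = cell_cfg["flicker"]["gc_synapse"]
    attach_gc_input(net, GCSynapseParams(
        ampa_uS=gc["ampa_uS"], nmda_uS=gc["nmda_uS"], e_mV=gc["e_mV"], in_scale=scale))
    # one 40-Hz flash of the requested intensity: spikes 25/intensity*duty ms apart
    proto = FlickerProtocol(frequency_hz=40.0, intensity=n_spikes,
                            onset_ms=50.0, duration_ms=25.0)
    res = integrate(net, SimulationSettings(duration=150.0, warmup_discard=0.0, seed=0),
                    state="calibration", protocol=proto)
    return len(res.spike_times("IN")) > 0


def calibrate_gc_in_scale(config: dict, tolerance: float = 0.01,
                          lo: float = 0.01, hi: float = 0.5) -> float:
    """GC->IN strength scale such that three near-simultaneous GC inputs fire
    an interneuron while one or two do not.

    Bisects the firing threshold for the three-spike and two-spike protocols
    and returns the midpoint, so the requirement sits centrally between the
    two thresholds (relative bisection tolerance ``tolerance``).
    """
    def threshold(n_spikes: int) -> float:
        a, b = lo, hi
        if _in_fires(config, a, n_spikes):
            return a
        if not _in_fires(config, b, n_spikes):
            raise RuntimeError("IN cell never fires inside the calibration bracket")
        while (b - a) / b > tolerance:
            mid = 0.5 * (a + b)
            if _in_fires(config, mid, n_spikes):
                b = mid
            else:
                a = mid
        return b

    t3 = threshold(3)
    t2 = threshold(2)
    return 0.5 * (t3 + t2)
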