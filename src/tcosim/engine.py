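"""Simulation engine: fixed-step RK4 integration of the built network.

Packs a :class:`~tcosim.network.Network` into flat arrays, drives the
compiled core, and returns spike rasters and population mean-voltage traces.
The classical fourth-order Runge-Kutta scheme advances all continuous state
at a fixed 0.02 ms step; discrete events are handled at step boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .channels import AHP_BETA, AHP_KF, STANDARD_GATES, gate_tables
from .config import config_digest, default_config, merge_config
from .flicker import FlickerProtocol, attach_gc_input, generate_gc_spike_train
from .network import (CORTICAL_POPS, THALAMIC_POPS, Network, build_network,
                      generate_poisson_drive)

__all__ = [
    "SimulationSettings",
    "SimulationResult",
    "integrate",
    "run_state",
    "run_protocol",
    "detect_spikes",
    "single_cell_config",
]

_TAB_VMIN, _TAB_VMAX, _TAB_DV = -150.0, 80.0, 0.05


@dataclass
class SimulationSettings:
    time_step: float = 0.02        # ms
    duration: float = 10000.0      # ms
    warmup_discard: float = 1000.0  # ms
    seed: int = 0                  # run seed for the stochastic drives
    record_decimation: int = 5     # record every Nth step
    record_neurons: Tuple[Tuple[str, int], ...] = ()  # (pop, local idx) full-V records
    spike_threshold: float = 0.0   # mV
    spike_lockout: float = 1.0     # ms

    def __post_init__(self):
        if self.time_step <= 0:
            raise ValueError("time step must be > 0")
        if self.duration < self.warmup_discard:
            raise ValueError("duration must cover the warmup discard")


@dataclass
class SimulationResult:
    times: np.ndarray                       # recorded time axis, ms
    mean_voltage: Dict[str, np.ndarray]     # per-population mean V, mV
    spikes: Dict[str, pd.DataFrame]         # per-population (neuron, t_ms)
    recorded_voltage: Dict[Tuple[str, int], np.ndarray]
    seed: int
    config_digest: str
    state: str
    protocol: Optional[FlickerProtocol]
    warmup_discard: float
    duration: float

    def spike_times(self, pop: str, neuron: Optional[int] = None) -> np.ndarray:
        df = self.spikes[pop]
        if neuron is not None:
            df = df[df["neuron"] == neuron]
        return df["t_ms"].to_numpy()

    def firing_rate(self, pop: str, discard_warmup: bool = True) -> float:
        """Mean firing rate in Hz over the (post-warmup) interval."""
        t0 = self.warmup_discard if discard_warmup else 0.0
        n = len(self.spikes[pop][self.spikes[pop]["t_ms"] >= t0])
        window_s = (self.duration - t0) / 1000.0
        n_cells = self._pop_sizes[pop]
        return n / (window_s * n_cells) if n_cells and window_s > 0 else np.nan

    _pop_sizes: Dict[str, int] = field(default_factory=dict)


def detect_spikes(voltage: np.ndarray, times: np.ndarray,
                  threshold: float = 0.0, lockout: float = 1.0) -> np.ndarray:
    """Upward threshold crossings with a refractory lockout (times in ms)."""
    v = np.asarray(voltage, float)
    t = np.asarray(times, float)
    crossings = np.nonzero((v[:-1] < threshold) & (v[1:] >= threshold))[0] + 1
    out = []
    last = -np.inf
    for k in crossings:
        if t[k] - last >= lockout:
            out.append(t[k])
            last = t[k]
    return np.asarray(out)


def single_cell_config(cell_type: str, base: Optional[dict] = None) -> dict:
    """Config for one isolated thalamic cell (no connections, no cortex)."""
    cfg = merge_config(base or default_config(), {})
    for pop in list(cfg["populations"]):
        spec = cfg["populations"][pop]
        spec.pop("grid", None)
        spec["size"] = 1 if pop == cell_type else 0
    cfg["projections"] = []
    cfg["cortical_projections"] = []
    cfg["gap_junctions"] = {}
    cfg["heterogeneity"] = {"g_l_range": [0.01, 0.01], "populations": []}
    cfg["simulation"]["v_init_jitter_mV"] = 0.0
    return cfg


# ---------------------------------------------------------------------------
# Packing
# ---------------------------------------------------------------------------

_SRC_KIND = {"GC": _kernels.SRC_GC, "PY": _kernels.SRC_PY, "FS": _kernels.SRC_PY}


class _Packed:
    """Flat-array view of one network + drive realization."""

    def __init__(self, net: Network, state: str, protocol: Optional[FlickerProtocol],
                 settings: SimulationSettings):
        cfg = net.config
        dt = settings.time_step
        self.net, self.cfg, self.settings = net, cfg, settings
        area = float(cfg["area_cm2"])

        sizes = net.pop_sizes
        self.th_pops = [p for p in THALAMIC_POPS]
        self.cx_pops = [p for p in CORTICAL_POPS]
        th_off = np.zeros(len(self.th_pops) + 1, dtype=np.int64)
        for k, p in enumerate(self.th_pops):
            th_off[k + 1] = th_off[k] + sizes[p]
        cx_off = np.zeros(len(self.cx_pops) + 1, dtype=np.int64)
        for k, p in enumerate(self.cx_pops):
            cx_off[k + 1] = cx_off[k] + sizes[p]
        self.th_off, self.cx_off = th_off, cx_off
        n_th, n_cx = int(th_off[-1]), int(cx_off[-1])
        self.n_th, self.n_cx = n_th, n_cx
        self.th_pop_start = {p: int(th_off[k]) for k, p in enumerate(self.th_pops)}
        self.cx_pop_start = {p: int(cx_off[k]) for k, p in enumerate(self.cx_pops)}

        # --- thalamic membrane parameters ---
        self.gL = np.zeros(n_th); self.gKL = np.zeros(n_th)
        self.EL = np.zeros(n_th); self.EKL = np.zeros(n_th)
        self.Cm = np.ones(n_th); self.kCa = np.zeros(n_th)
        self.tauCa = np.ones(n_th); self.caRest = np.full(n_th, 2.4e-4)
        gate_names: List[str] = []
        tab_rows: Dict[str, int] = {}

        ch_rows = []
        for k, pop in enumerate(self.th_pops):
            n = sizes[pop]
            if n == 0:
                continue
            cell = cfg["thalamic_cells"][pop]
            i0, i1 = int(th_off[k]), int(th_off[k + 1])
            self.gL[i0:i1] = net.g_l[pop]
            self.gKL[i0:i1] = cell["g_kl"]
            self.EL[i0:i1] = cell["e_l"]
            self.EKL[i0:i1] = cell["e_kl"]
            self.Cm[i0:i1] = cell["cm"]
            ca = cell["calcium"]
            self.kCa[i0:i1] = 10.0 / (2.0 * 96485.332 * ca["shell_um"])
            self.tauCa[i0:i1] = ca["tau_ms"]
            self.caRest[i0:i1] = ca["rest_mM"]
            for name, ch in cell["channels"].items():
                if ch["g"] <= 0:
                    continue
                ch_rows.append((pop, name, ch, i0, i1))

        n_entries = len(ch_rows)
        self.ch_i0 = np.zeros(n_entries, dtype=np.int64)
        self.ch_i1 = np.zeros(n_entries, dtype=np.int64)
        self.ch_g = np.zeros(n_entries)
        self.ch_E = np.zeros(n_entries)
        self.ch_p = np.zeros(n_entries, dtype=np.int64)
        self.ch_q = np.zeros(n_entries, dtype=np.int64)
        self.ch_m_tab = np.full(n_entries, -1, dtype=np.int64)
        self.ch_h_tab = np.full(n_entries, -1, dtype=np.int64)
        self.ch_m_slot = np.full(n_entries, -1, dtype=np.int64)
        self.ch_h_slot = np.full(n_entries, -1, dtype=np.int64)
        self.ch_is_ca = np.zeros(n_entries, dtype=np.int64)
        self.ch_ca_lin = np.zeros(n_entries, dtype=np.int64)
        self._entry_meta = []
        slot = 0

        def table_row(gname: str) -> int:
            if gname not in tab_rows:
                tab_rows[gname] = len(gate_names)
                gate_names.append(gname)
            return tab_rows[gname]

        for c, (pop, name, ch, i0, i1) in enumerate(ch_rows):
            self.ch_i0[c], self.ch_i1[c] = i0, i1
            self.ch_g[c] = ch["g"]
            self.ch_E[c] = ch["e"]
            self.ch_p[c] = ch["p"]
            self.ch_q[c] = ch["q"]
            self.ch_is_ca[c] = 1 if ch.get("is_ca") else 0
            m_gate, h_gate = ch.get("m_gate"), ch.get("h_gate")
            if m_gate == "ahp_lin_m":
                self.ch_ca_lin[c] = 1
            if ch["p"] > 0 and m_gate:
                spec = STANDARD_GATES[m_gate]
                self.ch_m_tab[c] = -1 if spec.ca_dependent else table_row(m_gate)
                self.ch_m_slot[c] = slot; slot += 1
            if ch["q"] > 0 and h_gate:
                spec = STANDARD_GATES[h_gate]
                if spec.ca_dependent:
                    raise ValueError("calcium-dependent inactivation not supported")
                self.ch_h_tab[c] = table_row(h_gate)
                self.ch_h_slot[c] = slot; slot += 1
            self._entry_meta.append((pop, name, m_gate, h_gate))
        self.n_slots = max(slot, 1)

        n_v = int(round((_TAB_VMAX - _TAB_VMIN) / _TAB_DV)) + 1
        self.tab_inf = np.zeros((max(len(gate_names), 1), n_v))
        self.tab_tau = np.ones((max(len(gate_names), 1), n_v))
        for gname, row in tab_rows.items():
            _, inf, tau = gate_tables(STANDARD_GATES[gname], _TAB_VMIN, _TAB_VMAX, _TAB_DV)
            self.tab_inf[row], self.tab_tau[row] = inf, tau

        # --- gap junctions (directed adjacency) ---
        heads = [[] for _ in range(n_th)]
        weights = [[] for _ in range(n_th)]
        for gj in net.gap_junctions:
            w = 1e-3 / (gj.r_mohm * area)  # mS/cm^2 per mV -> uA/cm^2
            oa, ob = self.th_pop_start[gj.pop_a], self.th_pop_start[gj.pop_b]
            for ia, ib in zip(gj.a, gj.b):
                ga, gb = oa + int(ia), ob + int(ib)
                heads[ga].append(gb); weights[ga].append(w)
                heads[gb].append(ga); weights[gb].append(w)
        self.gap_indptr = np.zeros(n_th + 1, dtype=np.int64)
        for i in range(n_th):
            self.gap_indptr[i + 1] = self.gap_indptr[i] + len(heads[i])
        flat_idx = [j for h in heads for j in h]
        flat_w = [w for ws in weights for w in ws]
        self.gap_idx = np.asarray(flat_idx, dtype=np.int64)
        self.gap_w = np.asarray(flat_w, dtype=np.float64)

        # --- chemical projections ---
        projections = net.projections
        n_pr = len(projections)
        self.pr_src_kind = np.zeros(n_pr, dtype=np.int64)
        self.pr_src_g0 = np.zeros(n_pr, dtype=np.int64)
        self.pr_tgt_g0 = np.zeros(n_pr, dtype=np.int64)
        self.pr_nsrc = np.zeros(n_pr, dtype=np.int64)
        self.pr_ntgt = np.zeros(n_pr, dtype=np.int64)
        self.pr_gden = np.zeros(n_pr)
        self.pr_E = np.zeros(n_pr)
        self.pr_is_nmda = np.zeros(n_pr, dtype=np.int64)
        self.pr_exp_off = np.zeros(n_pr)
        self.pr_exp_on = np.zeros(n_pr)
        self.pr_sinf_on = np.zeros(n_pr)
        self.pr_one_minus_U = np.zeros(n_pr)
        self.pr_exp_rec = np.zeros(n_pr)
        self.pr_st_off = np.zeros(n_pr, dtype=np.int64)
        ipt, edg = [], []
        self.pr_ip_off = np.zeros(n_pr, dtype=np.int64)
        self.pr_edge_off = np.zeros(n_pr, dtype=np.int64)
        st = 0
        for p, pr in enumerate(projections):
            if pr.source == "GC":
                self.pr_src_kind[p] = _kernels.SRC_GC
                self.pr_src_g0[p] = 0
                self.pr_nsrc[p] = 1
            elif pr.source in self.cx_pop_start:
                self.pr_src_kind[p] = _kernels.SRC_PY
                self.pr_src_g0[p] = self.cx_pop_start[pr.source]
                self.pr_nsrc[p] = sizes[pr.source]
            else:
                self.pr_src_kind[p] = _kernels.SRC_THALAMIC
                self.pr_src_g0[p] = self.th_pop_start[pr.source]
                self.pr_nsrc[p] = sizes[pr.source]
            if pr.target not in self.th_pop_start:
                raise ValueError("chemical projections must target thalamic populations")
            self.pr_tgt_g0[p] = self.th_pop_start[pr.target]
            self.pr_ntgt[p] = sizes[pr.target]
            self.pr_gden[p] = pr.g_uS * 1e-3 / area
            self.pr_E[p] = pr.e_mV
            self.pr_is_nmda[p] = 1 if pr.receptor == "NMDA" else 0
            a_t = pr.alpha * 0.5  # alpha * [T]
            self.pr_exp_off[p] = np.exp(-pr.beta * dt)
            self.pr_exp_on[p] = np.exp(-(a_t + pr.beta) * dt)
            self.pr_sinf_on[p] = a_t / (a_t + pr.beta)
            self.pr_one_minus_U[p] = 1.0 - pr.U
            self.pr_exp_rec[p] = np.exp(-dt / pr.tau_rec)
            self.pr_st_off[p] = st
            st += int(self.pr_nsrc[p])
            self.pr_ip_off[p] = len(ipt)
            ipt.extend(pr.indptr.tolist())
            self.pr_edge_off[p] = len(edg)
            edg.extend(pr.src.tolist())
        self.pr_indptr = np.array(ipt or [0], dtype=np.int64)
        self.pr_edge_src = np.array(edg or [0], dtype=np.int64)
        self.pr_s = np.zeros(max(st, 1))
        self.pr_D = np.ones(max(st, 1))
        self.n_syn_state = st

        # --- cortex parameters ---
        self.cx = {}
        for nm, default in (("cm", 1.0), ("g_l", 1.0), ("e_l", -65.0), ("v_th", -50.0),
                            ("delta", 1.0), ("a", 0.0), ("b", 0.0), ("tau_w", 1.0),
                            ("v_reset", -65.0), ("refractory", 0.0), ("v_cut", 0.0)):
            arr = np.full(n_cx, default)
            for k, pop in enumerate(self.cx_pops):
                if sizes[pop]:
                    arr[cx_off[k]:cx_off[k + 1]] = cfg["cortical_cells"][pop][nm]
            self.cx[nm] = arr
        syn = cfg["cortex_synapse"]
        self.eE, self.eI = float(syn["e_exc"]), float(syn["e_inh"])
        self.tauE, self.tauI = float(syn["tau_exc"]), float(syn["tau_inh"])

        # --- cortical quantal projections, CSR over sources ---
        cqs = net.cortical_projections
        n_cq = len(cqs)
        self.cq_src_kind = np.zeros(n_cq, dtype=np.int64)
        self.cq_src_g0 = np.zeros(n_cq, dtype=np.int64)
        self.cq_tgt_g0 = np.zeros(n_cq, dtype=np.int64)
        self.cq_nsrc = np.zeros(n_cq, dtype=np.int64)
        self.cq_q = np.zeros(n_cq)
        self.cq_is_inh = np.zeros(n_cq, dtype=np.int64)
        self.cq_ip_off = np.zeros(n_cq, dtype=np.int64)
        self.cq_edge_off = np.zeros(n_cq, dtype=np.int64)
        ipt, edg = [], []
        for p, pr in enumerate(cqs):
            n_src, n_tgt = sizes[pr.source], sizes[pr.target]
            if pr.source in self.th_pop_start:
                self.cq_src_kind[p] = _kernels.CQ_SRC_THALAMIC
                self.cq_src_g0[p] = self.th_pop_start[pr.source]
            else:
                self.cq_src_kind[p] = _kernels.CQ_SRC_CORTICAL
                self.cq_src_g0[p] = self.cx_pop_start[pr.source]
            self.cq_tgt_g0[p] = self.cx_pop_start[pr.target]
            self.cq_nsrc[p] = n_src
            self.cq_q[p] = pr.q_nS
            self.cq_is_inh[p] = 1 if pr.kind == "inh" else 0
            # transpose target-CSR -> source-CSR
            out = [[] for _ in range(n_src)]
            for tgt in range(n_tgt):
                for k in range(pr.indptr[tgt], pr.indptr[tgt + 1]):
                    out[int(pr.src[k])].append(tgt)
            self.cq_ip_off[p] = len(ipt)
            indptr = [0]
            flat = []
            for s_ in range(n_src):
                flat.extend(out[s_])
                indptr.append(len(flat))
            self.cq_edge_off[p] = len(edg)
            ipt.extend(indptr)
            edg.extend(flat)
        self.cq_indptr = np.array(ipt or [0], dtype=np.int64)
        self.cq_edge_tgt = np.array(edg or [0], dtype=np.int64)

        # --- drives ---
        run_ss = np.random.SeedSequence([net.seed & 0x7FFFFFFF, settings.seed & 0x7FFFFFFF])
        ss_th, ss_cx = run_ss.spawn(2)
        drv_cfg = cfg["drives"]["thalamic"]
        g_state = drv_cfg["g_nS"][state] if isinstance(drv_cfg["g_nS"], dict) else drv_cfg["g_nS"]
        q_den = float(g_state) * 1e-6 / area
        rng_th = np.random.default_rng(ss_th)
        if settings.duration > 0:
            trains = generate_poisson_drive(n_th, float(drv_cfg["rate_hz"]),
                                            settings.duration, rng_th)
        else:
            trains = [np.empty(0) for _ in range(n_th)]
        t_all = np.concatenate(trains) if n_th else np.empty(0)
        i_all = np.concatenate([np.full(len(tr), i, dtype=np.int64)
                                for i, tr in enumerate(trains)]) if n_th else np.empty(0, np.int64)
        order = np.argsort(t_all, kind="stable")
        self.drv_t = t_all[order]
        self.drv_i = i_all[order]
        self.drv_q = np.full(len(order), q_den)
        self.tau_drive = float(drv_cfg["tau_ms"])
        self.e_drive = float(drv_cfg["e_mV"])

        cx_cfg = cfg["drives"]["cortical"]
        eff_rate = float(cx_cfg["train_count"]) * float(cx_cfg["rate_hz"])
        rng_cx = np.random.default_rng(ss_cx)
        if settings.duration > 0:
            trains = generate_poisson_drive(n_cx, eff_rate, settings.duration, rng_cx)
        else:
            trains = [np.empty(0) for _ in range(n_cx)]
        t_all = np.concatenate(trains) if n_cx else np.empty(0)
        i_all = np.concatenate([np.full(len(tr), i, dtype=np.int64)
                                for i, tr in enumerate(trains)]) if n_cx else np.empty(0, np.int64)
        order = np.argsort(t_all, kind="stable")
        self.cxn_t = t_all[order]
        self.cxn_i = i_all[order]
        self.cxn_q = np.full(len(order), float(cx_cfg["q_nS"]))

        # --- GC spike train ---
        if protocol is not None:
            self.gc_times = generate_gc_spike_train(protocol)
        else:
            self.gc_times = np.empty(0)

        # --- initial state ---
        from .network import init_rng
        rng0 = init_rng(net.seed)
        jit = float(cfg["simulation"].get("v_init_jitter_mV", 5.0))
        gsum = self.gL + self.gKL
        v0 = np.where(gsum > 0,
                      (self.gL * self.EL + self.gKL * self.EKL) / np.maximum(gsum, 1e-12),
                      self.EL)
        self.V = v0 + rng0.uniform(-jit, jit, n_th)
        self.Ca = self.caRest.copy()
        self.gdrive = np.zeros(n_th)
        self.X = np.zeros((self.n_slots, n_th))
        for c in range(n_entries):
            pop, name, m_gate, h_gate = self._entry_meta[c]
            i0, i1 = int(self.ch_i0[c]), int(self.ch_i1[c])
            if self.ch_m_slot[c] >= 0:
                spec = STANDARD_GATES[m_gate]
                self.X[self.ch_m_slot[c], i0:i1] = spec.steady_state(self.V[i0:i1], self.Ca[i0:i1])
            if self.ch_h_slot[c] >= 0:
                spec = STANDARD_GATES[h_gate]
                self.X[self.ch_h_slot[c], i0:i1] = spec.steady_state(self.V[i0:i1], self.Ca[i0:i1])
        self.v_cx = self.cx["e_l"] + (rng0.uniform(-jit, jit, n_cx) if n_cx else 0.0)
        self.w_cx = np.zeros(n_cx)
        self.gEcx = np.zeros(n_cx)
        self.gIcx = np.zeros(n_cx)
        self.refr = np.zeros(n_cx)
        self.toff_th = np.full(n_th, -1e30)
        self.toff_py = np.full(max(n_cx, 1), -1e30)
        self.last_spike_th = np.full(n_th, -1e30)


def integrate(net: Network, settings: SimulationSettings, state: str = "gamma",
              protocol: Optional[FlickerProtocol] = None) -> SimulationResult:
    """Integrate the network; identical seed + config give identical results."""
    pk = _Packed(net, state, protocol, settings)
    dt = settings.time_step
    n_steps = int(round(settings.duration / dt))
    decim = int(settings.record_decimation)
    n_rec = (n_steps + decim - 1) // decim
    n_pops = len(pk.th_pops) + len(pk.cx_pops)
    traces = np.zeros((n_pops, n_rec))

    sel = []
    for pop, idx in settings.record_neurons:
        if pop in pk.th_pop_start:
            sel.append(pk.th_pop_start[pop] + idx)
        else:
            raise ValueError("full-voltage recording is available for thalamic cells")
    sel_idx = np.asarray(sel, dtype=np.int64)
    v_sel = np.zeros((len(sel), n_rec))

    cap_th = int(min(4_000_000, max(100_000, pk.n_th * settings.duration * 0.6)))
    cap_cx = int(min(2_000_000, max(50_000, max(pk.n_cx, 1) * settings.duration * 0.6)))
    sp_i_th = np.zeros(cap_th, dtype=np.int64)
    sp_t_th = np.zeros(cap_th)
    sp_i_cx = np.zeros(cap_cx, dtype=np.int64)
    sp_t_cx = np.zeros(cap_cx)

    n_th_sp, n_cx_sp, status, steps_done = _kernels.simulate(
        dt, n_steps,
        pk.V, pk.X, pk.Ca, pk.gdrive,
        pk.gL, pk.gKL, pk.EL, pk.EKL, pk.Cm, pk.kCa, pk.tauCa, pk.caRest,
        pk.tau_drive, pk.e_drive,
        pk.ch_i0, pk.ch_i1, pk.ch_g, pk.ch_E, pk.ch_p, pk.ch_q,
        pk.ch_m_tab, pk.ch_h_tab, pk.ch_m_slot, pk.ch_h_slot, pk.ch_is_ca, pk.ch_ca_lin,
        AHP_KF, AHP_BETA, 0.1,
        pk.tab_inf, pk.tab_tau, _TAB_VMIN, 1.0 / _TAB_DV,
        pk.gap_indptr, pk.gap_idx, pk.gap_w,
        pk.pr_src_kind, pk.pr_src_g0, pk.pr_tgt_g0, pk.pr_nsrc, pk.pr_ntgt,
        pk.pr_gden, pk.pr_E, pk.pr_is_nmda,
        pk.pr_exp_off, pk.pr_exp_on, pk.pr_sinf_on, pk.pr_one_minus_U, pk.pr_exp_rec,
        pk.pr_indptr, pk.pr_ip_off, pk.pr_edge_src, pk.pr_edge_off,
        pk.pr_s, pk.pr_D, pk.pr_st_off,
        pk.toff_th, pk.toff_py,
        pk.gc_times,
        settings.spike_threshold, settings.spike_lockout, pk.last_spike_th,
        pk.drv_t, pk.drv_i, pk.drv_q,
        pk.v_cx, pk.w_cx, pk.gEcx, pk.gIcx, pk.refr,
        pk.cx["cm"], pk.cx["g_l"], pk.cx["e_l"], pk.cx["v_th"], pk.cx["delta"],
        pk.cx["a"], pk.cx["b"], pk.cx["tau_w"], pk.cx["v_reset"],
        pk.cx["refractory"], pk.cx["v_cut"],
        pk.eE, pk.eI, pk.tauE, pk.tauI,
        pk.cq_src_kind, pk.cq_src_g0, pk.cq_tgt_g0, pk.cq_nsrc, pk.cq_q, pk.cq_is_inh,
        pk.cq_indptr, pk.cq_ip_off, pk.cq_edge_tgt, pk.cq_edge_off,
        pk.cxn_t, pk.cxn_i, pk.cxn_q,
        decim, pk.th_off, pk.cx_off, traces,
        sel_idx, v_sel,
        sp_i_th, sp_t_th, sp_i_cx, sp_t_cx,
    )
    if status == _kernels.STATUS_NONFINITE:
        t_bad = steps_done * dt
        raise FloatingPointError(
            f"non-finite membrane state detected near t={t_bad:.2f} ms")
    if status == _kernels.STATUS_SPIKE_OVERFLOW:
        raise RuntimeError("spike record capacity exceeded; raise the cap or shorten the run")

    times = np.arange(n_rec) * dt * decim
    mean_v = {}
    for k, pop in enumerate(pk.th_pops):
        mean_v[pop] = traces[k]
    for k, pop in enumerate(pk.cx_pops):
        mean_v[pop] = traces[len(pk.th_pops) + k]

    spikes = {}
    idx_th, t_th = sp_i_th[:n_th_sp], sp_t_th[:n_th_sp]
    for k, pop in enumerate(pk.th_pops):
        mask = (idx_th >= pk.th_off[k]) & (idx_th < pk.th_off[k + 1])
        spikes[pop] = pd.DataFrame({
            "neuron": idx_th[mask] - pk.th_off[k], "t_ms": t_th[mask]})
    idx_cx, t_cx = sp_i_cx[:n_cx_sp], sp_t_cx[:n_cx_sp]
    for k, pop in enumerate(pk.cx_pops):
        mask = (idx_cx >= pk.cx_off[k]) & (idx_cx < pk.cx_off[k + 1])
        spikes[pop] = pd.DataFrame({
            "neuron": idx_cx[mask] - pk.cx_off[k], "t_ms": t_cx[mask]})

    recorded = {}
    for j, (pop, idx) in enumerate(settings.record_neurons):
        recorded[(pop, idx)] = v_sel[j]

    res = SimulationResult(
        times=times, mean_voltage=mean_v, spikes=spikes, recorded_voltage=recorded,
        seed=settings.seed, config_digest=config_digest(net.config),
        state=state, protocol=protocol,
        warmup_discard=settings.warmup_discard, duration=settings.duration,
    )
    res._pop_sizes = dict(net.pop_sizes)
    return res


def run_state(config: Optional[dict] = None, state: str = "gamma",
              protocol: Optional[FlickerProtocol] = None,
              settings: Optional[SimulationSettings] = None,
              seed: int = 0, net: Optional[Network] = None) -> SimulationResult:
    """Build (or reuse) a network and run one state/protocol combination."""
    if net is None:
        net = build_network(config, seed=seed)
        if protocol is not None:
            attach_gc_input(net)
    settings = settings or SimulationSettings(seed=seed)
    return integrate(net, settings, state=state, protocol=protocol)


def run_protocol(config: Optional[dict], state: str,
                 protocol_grid: Sequence[FlickerProtocol],
                 settings: SimulationSettings, seed: int = 0):
    """Apply each protocol of the grid to the same frozen network realization.

    The network structure and heterogeneity are sampled once from ``seed``;
    each grid point runs with its own drive substream (indexed by position).
    """
    net = build_network(config, seed=seed)
    attach_gc_input(net)
    results = []
    for k, proto in enumerate(protocol_grid):
        s = SimulationSettings(**{**settings.__dict__, "seed": settings.seed + k + 1})
        results.append(integrate(net, s, state=state, protocol=proto))
    return results
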