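"""Construction of the thalamocortical network from a configuration and a seed.

The thalamic sheet holds 49 HTC, 144 RTC, 64 IN and 100 RE Hodgkin-Huxley
neurons; the cortical patch holds 80 PY and 20 FS adaptive-exponential
neurons.  Cortical cells are connected all-to-all with probability 0.8
(0.5 within PY); thalamic chemical projections, gap-junction neighborhoods
on the population grids, leak-conductance heterogeneity and the background
Poisson drives are sampled from independent substreams of a single root
seed, so rebuilding with the same seed reproduces the identical network and
stimulation protocols can be swept over "the same network".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import config_digest, default_config

__all__ = [
    "Projection",
    "CorticalProjection",
    "GapJunction",
    "Network",
    "build_network",
    "sample_heterogeneity",
    "generate_poisson_drive",
]

THALAMIC_POPS = ("HTC", "RTC", "IN", "RE")
CORTICAL_POPS = ("PY", "FS")


@dataclass
class Projection:
    """Chemical projection using the kinetic receptor model with depression.

    ``indptr``/``src`` form a CSR over target-local indices; source indices
    are local to the source population ("GC" is the single ganglion cell).
    ``g_uS`` is the per-synapse maximal conductance.
    """

    source: str
    target: str
    receptor: str
    g_uS: float
    e_mV: float
    alpha: float
    beta: float
    U: float
    tau_rec: float
    indptr: np.ndarray
    src: np.ndarray
    mg_mM: float = 1.0
    weight: Optional[np.ndarray] = None  # per-edge scale, default 1

    @property
    def n_edges(self) -> int:
        return int(len(self.src))


@dataclass
class CorticalProjection:
    """Quantal projection onto cortical g_E/g_I (Q-jump conductances)."""

    source: str
    target: str
    kind: str  # "exc" | "inh"
    q_nS: float
    indptr: np.ndarray
    src: np.ndarray

    @property
    def n_edges(self) -> int:
        return int(len(self.src))


@dataclass
class GapJunction:
    pair_class: str
    pop_a: str
    pop_b: str
    a: np.ndarray       # local indices in pop_a
    b: np.ndarray       # local indices in pop_b
    r_mohm: float


@dataclass
class Network:
    config: dict
    seed: int
    pop_sizes: Dict[str, int]
    g_l: Dict[str, np.ndarray]            # heterogeneous leak per thalamic pop
    grid_xy: Dict[str, np.ndarray]        # grid coordinates per gridded pop
    projections: List[Projection] = field(default_factory=list)
    cortical_projections: List[CorticalProjection] = field(default_factory=list)
    gap_junctions: List[GapJunction] = field(default_factory=list)
    gc_in_scale: float = 1.0

    @property
    def digest(self) -> str:
        return config_digest(self.config)

    def node_table(self) -> pd.DataFrame:
        rows = []
        for pop in THALAMIC_POPS:
            for i in range(self.pop_sizes[pop]):
                rows.append((pop, i, self.g_l[pop][i]))
        for pop in CORTICAL_POPS:
            for i in range(self.pop_sizes[pop]):
                rows.append((pop, i, np.nan))
        return pd.DataFrame(rows, columns=["population", "neuron", "g_l_mS_cm2"])

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for pr in self.projections:
            for tgt in range(len(pr.indptr) - 1):
                for k in range(pr.indptr[tgt], pr.indptr[tgt + 1]):
                    rows.append((pr.source, int(pr.src[k]), pr.target, tgt,
                                 "chemical", pr.receptor, pr.g_uS))
        for pr in self.cortical_projections:
            for tgt in range(len(pr.indptr) - 1):
                for k in range(pr.indptr[tgt], pr.indptr[tgt + 1]):
                    rows.append((pr.source, int(pr.src[k]), pr.target, tgt,
                                 "quantal", pr.kind, pr.q_nS))
        for gj in self.gap_junctions:
            for ia, ib in zip(gj.a, gj.b):
                rows.append((gj.pop_a, int(ia), gj.pop_b, int(ib),
                             "gap", gj.pair_class, 1.0 / gj.r_mohm))
        return pd.DataFrame(rows, columns=[
            "source_pop", "source", "target_pop", "target", "kind", "receptor", "weight"])


def _substreams(seed: int):
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(4)
    return {
        "connectivity": np.random.default_rng(kids[0]),
        "heterogeneity": np.random.default_rng(kids[1]),
        "drives": kids[2],      # spawned further per run
        "init": np.random.default_rng(kids[3]),
    }


def sample_heterogeneity(n: int, g_range, rng) -> np.ndarray:
    """Per-neuron leak conductances drawn uniformly on ``g_range``."""
    lo, hi = float(g_range[0]), float(g_range[1])
    if lo <= 0 or hi < lo:
        raise ValueError("heterogeneity range must be positive and ordered")
    return rng.uniform(lo, hi, size=n)


def _random_edges(n_src: int, n_tgt: int, p: float, rng, self_connections: bool):
    """CSR over targets; each ordered pair sampled independently."""
    indptr = np.zeros(n_tgt + 1, dtype=np.int64)
    srcs = []
    for tgt in range(n_tgt):
        if p <= 0:
            chosen = np.empty(0, dtype=np.int64)
        else:
            mask = rng.random(n_src) < p
            if not self_connections and n_src == n_tgt:
                mask[tgt] = False
            chosen = np.nonzero(mask)[0]
        srcs.append(chosen)
        indptr[tgt + 1] = indptr[tgt] + len(chosen)
    src = np.concatenate(srcs) if srcs else np.empty(0, dtype=np.int64)
    return indptr, src.astype(np.int64)


def _grid_coords(shape) -> np.ndarray:
    ny, nx = int(shape[0]), int(shape[1])
    ys, xs = np.mgrid[0:ny, 0:nx]
    return np.column_stack([ys.ravel(), xs.ravel()]).astype(float)


def _gap_pairs(xy_a, xy_b, radius, same_pop, scale_b=1.0):
    """Index pairs within ``radius`` (grid units of pop a); each unordered pair once."""
    pairs_a, pairs_b = [], []
    for i, pa in enumerate(xy_a):
        d = np.hypot(*(xy_b * scale_b - pa).T) if scale_b != 1.0 else np.hypot(
            xy_b[:, 0] - pa[0], xy_b[:, 1] - pa[1])
        close = np.nonzero(d <= radius + 1e-9)[0]
        for j in close:
            if same_pop and j <= i:
                continue
            pairs_a.append(i)
            pairs_b.append(int(j))
    return np.asarray(pairs_a, dtype=np.int64), np.asarray(pairs_b, dtype=np.int64)


def build_network(config: Optional[dict] = None, seed: int = 0) -> Network:
    """Sample a concrete network realization; deterministic given seed+config."""
    cfg = config if config is not None else default_config()
    streams = _substreams(seed)
    rng_conn = streams["connectivity"]
    rng_het = streams["heterogeneity"]

    pop_sizes = {name: int(spec["size"]) for name, spec in cfg["populations"].items()}
    for name in THALAMIC_POPS + CORTICAL_POPS:
        if name not in pop_sizes:
            pop_sizes[name] = 0

    het = cfg["heterogeneity"]
    g_l = {}
    for pop in THALAMIC_POPS:
        n = pop_sizes[pop]
        if pop in het["populations"] and n > 0:
            g_l[pop] = sample_heterogeneity(n, het["g_l_range"], rng_het)
        else:
            g_l[pop] = np.full(n, cfg["thalamic_cells"][pop]["g_l"])

    grid_xy = {}
    for pop, spec in cfg["populations"].items():
        if "grid" in spec and pop_sizes[pop] > 0:
            coords = _grid_coords(spec["grid"])
            if len(coords) != pop_sizes[pop]:
                raise ValueError(f"grid of {pop} does not match its size")
            grid_xy[pop] = coords

    net = Network(config=cfg, seed=seed, pop_sizes=pop_sizes, g_l=g_l, grid_xy=grid_xy)

    receptors = cfg["receptors"]
    dep = cfg["depression"]
    for rule in cfg["projections"]:
        s, t = rule["source"], rule["target"]
        if s not in pop_sizes or t not in pop_sizes:
            raise ValueError(f"projection references unknown population {s} or {t}")
        n_src, n_tgt = pop_sizes[s], pop_sizes[t]
        if n_src == 0 or n_tgt == 0:
            continue
        indptr, src = _random_edges(n_src, n_tgt, float(rule["p"]), rng_conn,
                                    self_connections=False)
        kin = receptors[rule["receptor"]]
        net.projections.append(Projection(
            source=s, target=t, receptor=rule["receptor"],
            g_uS=float(rule["g_uS"]), e_mV=float(rule["e_mV"]),
            alpha=float(kin["alpha"]), beta=float(kin["beta"]),
            U=float(dep["U"]), tau_rec=float(dep["tau_ms"]),
            indptr=indptr, src=src, mg_mM=float(kin.get("mg_mM", 1.0)),
        ))

    for rule in cfg["cortical_projections"]:
        s, t = rule["source"], rule["target"]
        if s not in pop_sizes or t not in pop_sizes:
            raise ValueError(f"cortical projection references unknown population {s} or {t}")
        n_src, n_tgt = pop_sizes[s], pop_sizes[t]
        if n_src == 0 or n_tgt == 0:
            continue
        indptr, src = _random_edges(n_src, n_tgt, float(rule["p"]), rng_conn,
                                    self_connections=(s != t))
        net.cortical_projections.append(CorticalProjection(
            source=s, target=t, kind=rule["kind"], q_nS=float(rule["q_nS"]),
            indptr=indptr, src=src,
        ))

    for pair, spec in cfg["gap_junctions"].items():
        pa, pb = pair.split("-")
        if pop_sizes.get(pa, 0) == 0 or pop_sizes.get(pb, 0) == 0:
            continue
        if pa not in grid_xy or pb not in grid_xy:
            continue
        same = pa == pb
        # map the b-grid onto the a-grid scale for cross-population coupling
        scale = 1.0
        if not same:
            ga = cfg["populations"][pa]["grid"]
            gb = cfg["populations"][pb]["grid"]
            scale = (ga[0] - 1) / max(gb[0] - 1, 1)
        a_idx, b_idx = _gap_pairs(grid_xy[pa], grid_xy[pb], float(spec["radius"]),
                                  same, scale_b=scale)
        net.gap_junctions.append(GapJunction(
            pair_class=pair, pop_a=pa, pop_b=pb, a=a_idx, b=b_idx,
            r_mohm=float(spec["r_mohm"]),
        ))

    return net


def generate_poisson_drive(n_neurons: int, rate_hz: float, duration_ms: float,
                           rng) -> list[np.ndarray]:
    """Independent homogeneous Poisson spike trains, one per neuron (times in ms)."""
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    trains = []
    scale = 1000.0 / rate_hz if rate_hz > 0 else np.inf
    for _ in range(n_neurons):
        if rate_hz <= 0:
            trains.append(np.empty(0))
            continue
        # draw enough exponential gaps to cover the interval
        n_guess = int(rate_hz * duration_ms / 1000.0 * 1.5 + 20)
        times = np.cumsum(rng.exponential(scale, size=n_guess))
        while times.size and times[-1] < duration_ms:
            extra = np.cumsum(rng.exponential(scale, size=n_guess)) + times[-1]
            times = np.concatenate([times, extra])
        trains.append(times[times < duration_ms])
    return trains


def drive_seed_sequence(seed: int):
    """SeedSequence feeding per-run drive substreams (matches build_network)."""
    return np.random.SeedSequence(seed).spawn(4)[2]


def init_rng(seed: int):
    """RNG for initial-condition jitter (matches build_network's substreams)."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
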