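import numpy as np
import pytest

from tcosim.config import default_config, merge_config
from tcosim.engine import SimulationSettings, integrate, single_cell_config
from tcosim.network import build_network


@pytest.fixture(scope="session")
def passive_cell_config():
    """One thalamic cell with every intrinsic channel and drive silenced."""
    cfg = single_cell_config("RTC")
    for name in cfg["thalamic_cells"]["RTC"]["channels"]:
        cfg["thalamic_cells"]["RTC"]["channels"][name]["g"] = 0.0
    cfg["drives"]["thalamic"]["g_nS"] = {"off": 0.0}
    cfg["drives"]["cortical"] = {"train_count": 0, "rate_hz": 0.0, "q_nS": 0.0}
    return cfg


def tiny_network_config(**sizes):
    """Reduced network for fast integration tests (same connectivity rules)."""
    cfg = default_config()
    defaults = {"HTC": 4, "RTC": 9, "IN": 4, "RE": 4, "PY": 8, "FS": 2}
    defaults.update(sizes)
    for pop, n in defaults.items():
        cfg["populations"][pop]["size"] = n
        cfg["populations"][pop].pop("grid", None)
    side = int(np.sqrt(defaults["HTC"]))
    if side * side == defaults["HTC"]:
        cfg["populations"]["HTC"]["grid"] = [side, side]
    return cfg


def run_single_cell(cfg, cell, state, duration, seed=3, warmup=0.0, record=True):
    net = build_network(cfg, seed=seed)
    settings = SimulationSettings(
        duration=duration, warmup_discard=warmup, seed=seed,
        record_neurons=((cell, 0),) if record else (),
    )
    return integrate(net, settings, state=state)
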