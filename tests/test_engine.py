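"""Integration engine: RK4 accuracy, event handling, determinism."""

import numpy as np
import pytest

from conftest import tiny_network_config
from tcosim.config import merge_config
from tcosim.engine import (SimulationSettings, detect_spikes, integrate,
                           run_protocol, single_cell_config)
from tcosim.flicker import FlickerProtocol
from tcosim.network import build_network


class TestDetectSpikes:
    times = np.arange(0, 10, 0.1)

    def test_flat_trace_no_spikes(self):
        v = np.full_like(self.times, -70.0)
        assert detect_spikes(v, self.times).size == 0

    def test_three_separated_crossings(self):
        v = np.full_like(self.times, -70.0)
        for t0 in (2.0, 5.0, 8.0):
            v[np.abs(self.times - t0) < 0.15] = 20.0
        assert detect_spikes(v, self.times).size == 3

    def test_lockout_merges_close_crossings(self):
        times = np.arange(0, 5, 0.05)
        v = np.full_like(times, -70.0)
        v[(times > 1.0) & (times < 1.2)] = 20.0
        v[(times > 1.5) & (times < 1.7)] = 20.0  # 0.5 ms later
        assert detect_spikes(v, times, lockout=1.0).size == 1
        assert detect_spikes(v, times, lockout=0.1).size == 2


class TestPassiveAccuracy:
    def test_leaky_cell_matches_analytic_exponential(self, passive_cell_config):
        """V(t) relaxes to E_L with error < 1e-6 relative at dt = 0.02 ms."""
        cfg = merge_config(passive_cell_config, {})
        cfg["simulation"]["v_init_jitter_mV"] = 0.0
        net = build_network(cfg, seed=0)
        s = SimulationSettings(duration=100.0, warmup_discard=0.0, seed=0,
                               record_neurons=(("RTC", 0),), record_decimation=1)
        res = integrate(net, s, state="off")
        v = res.recorded_voltage[("RTC", 0)]
        t = res.times
        cell = cfg["thalamic_cells"]["RTC"]
        g_l, g_kl = 0.01, cell["g_kl"]
        e_inf = (g_l * cell["e_l"] + g_kl * cell["e_kl"]) / (g_l + g_kl)
        tau = cell["cm"] / (g_l + g_kl)
        v_exact = e_inf + (v[0] - e_inf) * np.exp(-t / tau)
        rel = np.max(np.abs(v - v_exact)) / np.max(np.abs(v_exact))
        assert rel < 1e-6

    def test_voltage_converges_to_leak_steady_state(self, passive_cell_config):
        cfg = merge_config(passive_cell_config, {})
        cfg["simulation"]["v_init_jitter_mV"] = 5.0
        net = build_network(cfg, seed=1)
        cell = cfg["thalamic_cells"]["RTC"]
        tau = cell["cm"] / (0.01 + cell["g_kl"])
        s = SimulationSettings(duration=12 * tau, warmup_discard=0.0, seed=1,
                               record_neurons=(("RTC", 0),))
        res = integrate(net, s, state="off")
        e_inf = (0.01 * cell["e_l"] + cell["g_kl"] * cell["e_kl"]) / (0.01 + cell["g_kl"])
        assert abs(res.recorded_voltage[("RTC", 0)][-1] - e_inf) < 0.01


def _hh_trace(dt, duration=50.0):
    """Deterministic subthreshold relaxation of a full HTC cell (no drives)."""
    cfg = single_cell_config("HTC")
    cfg["drives"]["thalamic"]["g_nS"] = {"off": 0.0}
    cfg["drives"]["cortical"] = {"train_count": 0, "rate_hz": 0.0, "q_nS": 0.0}
    cfg["simulation"]["v_init_jitter_mV"] = 0.0
    net = build_network(cfg, seed=0)
    s = SimulationSettings(duration=duration, warmup_discard=0.0, seed=0,
                           time_step=dt, record_neurons=(("HTC", 0),),
                           record_decimation=int(round(0.2 / dt)))
    res = integrate(net, s, state="off")
    return res.recorded_voltage[("HTC", 0)]


def test_rk4_fourth_order_convergence():
    """Richardson check: halving dt shrinks the error by about 2^4."""
    v_ref = _hh_trace(0.0025)
    e_coarse = np.max(np.abs(_hh_trace(0.02) - v_ref))
    e_fine = np.max(np.abs(_hh_trace(0.01) - v_ref))
    ratio = e_coarse / e_fine
    assert 8.0 < ratio < 40.0  # nominal 16 for a 4th-order scheme


class TestNetworkRuns:
    def test_zero_duration_empty_rasters(self):
        cfg = tiny_network_config()
        net = build_network(cfg, seed=0)
        s = SimulationSettings(duration=0.0, warmup_discard=0.0, seed=0)
        res = integrate(net, s, state="gamma")
        assert all(len(df) == 0 for df in res.spikes.values())

    def test_determinism_same_seed(self):
        cfg = tiny_network_config()
        net = build_network(cfg, seed=4)
        s = SimulationSettings(duration=500.0, warmup_discard=0.0, seed=4)
        r1 = integrate(net, s, state="gamma")
        r2 = integrate(net, s, state="gamma")
        for pop in r1.spikes:
            assert np.array_equal(r1.spikes[pop]["t_ms"], r2.spikes[pop]["t_ms"])
        assert np.array_equal(r1.mean_voltage["RTC"], r2.mean_voltage["RTC"])

    def test_traces_finite_and_spikes_in_range(self):
        cfg = tiny_network_config()
        net = build_network(cfg, seed=2)
        dur = 800.0
        s = SimulationSettings(duration=dur, warmup_discard=0.0, seed=2)
        res = integrate(net, s, state="gamma")
        for pop, v in res.mean_voltage.items():
            assert np.all(np.isfinite(v)), pop
        for pop, df in res.spikes.items():
            if len(df):
                assert df["t_ms"].min() > 0.0
                assert df["t_ms"].max() <= dur

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            SimulationSettings(time_step=0.0)
        with pytest.raises(ValueError):
            SimulationSettings(duration=100.0, warmup_discard=200.0)


class TestRunProtocol:
    def test_grid_reuses_network_and_tags_results(self):
        cfg = tiny_network_config()
        grid = [FlickerProtocol(frequency_hz=f, intensity=1, duration_ms=300.0)
                for f in (35.0, 40.0)]
        s = SimulationSettings(duration=300.0, warmup_discard=0.0, seed=0)
        results = run_protocol(cfg, "gamma", grid, s, seed=0)
        assert len(results) == 2
        assert [r.protocol.frequency_hz for r in results] == [35.0, 40.0]
        assert results[0].config_digest == results[1].config_digest

    def test_empty_grid(self):
        cfg = tiny_network_config()
        s = SimulationSettings(duration=100.0, warmup_discard=0.0, seed=0)
        assert run_protocol(cfg, "gamma", [], s, seed=0) == []
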