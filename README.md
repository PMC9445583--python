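# tcosim — thalamocortical oscillations under rhythmic light flicker

`tcosim` is a biophysical network simulator for studying how rhythmic
visual flicker entrains, accelerates or suppresses ongoing brain rhythms
in the thalamocortical loop.  It is aimed at computational neuroscientists
who want a small, fully scriptable model of state-dependent gamma
entrainment: the kind of question behind 40-Hz light-flicker stimulation
protocols in neurology.

## The model

A thalamic sheet of Hodgkin–Huxley point neurons — 49 high-threshold
bursting cells (HTC), 144 relay cells (RTC), 64 interneurons (IN) and 100
reticular neurons (RE) — is coupled by AMPA/NMDA/GABA-A synapses with
short-term depression and by gap junctions (HTC–HTC 100 MΩ, HTC–RTC and
RE–RE 300 MΩ), and projects to a cortical patch of 80 pyramidal and 20
fast-spiking adaptive-exponential neurons.  Every thalamic neuron receives
an independent 100-Hz Poisson conductance drive whose quantal size selects
the network state:

| drive | state | thalamic rhythm |
|------:|:------|:----------------|
| 2.5 nS | alpha | ≈ 9 Hz, two-spike high-threshold bursts in HTC |
| 15 nS  | beta  | ≈ 25 Hz, tonic spiking |
| 25 nS  | gamma | ≈ 35 Hz, tonic spiking |

Light flicker enters through a single retinal ganglion-cell (GC) spike
source firing periodically at the flicker frequency (intensity = 1–3
spikes per flash, duty cycle in sixths of the period) that contacts every
TC and IN cell.  The per-cell current balance, synapse kinetics
(`I = s·D·g·B(V)(V−E)`), depression rule
`D = 1 − (1 − D_i(1−U)) e^{−(t−t_i)/τ}` and the analysis indices — sLFP
(band-passed 0.5–80 Hz population mean potential), spectral peak `f_d`,
synchronization index `k = |Σ e^{iφ}|/N`, correlation index, and the
entrainment criterion `|f_s − f_d| < 1 Hz` with `P_max/P₀ > 1` — are
described in `docs/methods.md`.

Everything is integrated with classical RK4 at a fixed 0.02 ms step by a
numba-compiled core (about 7× real time for the full 457-cell network on
one CPU).

## Worked example

Simulate the gamma state under 40-Hz flicker and compare it with the
unstimulated baseline:

```bash
tcosim run --state gamma --flicker-freq 40 --intensity 1 \
           --duration 5000 --seed 1 --out results/gamma40
```

which prints (abridged):

```
running gamma state with 40-Hz flicker
dominant_frequency_thalamus_hz: 40.00
dominant_frequency_cortex_hz: 40.00
synchronization_index: 0.359
rate_HTC_hz: 42.69
rate_RTC_hz: 34.55
flicker_frequency_hz: 40
baseline_peak_frequency_hz: 35.50
normalized_power: 9.407
entrained: yes
```

The endogenous ~35.5-Hz gamma rhythm is captured by the 40-Hz stimulus:
the thalamic and cortical sLFP peaks move to the stimulus frequency and
the thalamic spectral peak grows about ninefold over baseline, so the
entrainment criterion is met.  Running the same command with `--state alpha` instead
shows the opposite regime: the 9-Hz rhythm is not captured (`entrained:
no`), its low-frequency power collapses (normalized power ≈ 0.1), and the
residual slow rhythm accelerates into the 12–15 Hz range.

The same objects are available as a library:

```python
from tcosim import build_network, attach_gc_input, integrate, \
    SimulationSettings, FlickerProtocol, analysis

net = attach_gc_input(build_network(seed=1))
s = SimulationSettings(duration=5000, warmup_discard=1000, seed=1)
base = integrate(net, s, state="gamma")
stim = integrate(net, s, state="gamma",
                 protocol=FlickerProtocol(frequency_hz=40, intensity=1,
                                          duration_ms=5000))
spec = analysis.power_spectrum(analysis.thalamic_slfp(stim))
base_spec = analysis.power_spectrum(analysis.thalamic_slfp(base))
print(analysis.judge_entrainment(spec, base_spec, f_s=40.0))
```

The full parameter set (channel densities, synapse strengths, connection
probabilities, drives, flicker defaults) lives in one YAML-compatible
configuration; `tcosim export-config defaults.yaml` dumps it for editing
and `tcosim run --config my.yaml ...` runs with overrides.

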