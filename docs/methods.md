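# Model and methods

`tcosim` simulates a thalamocortical loop whose background-drive level
switches the network between alpha (~9 Hz), beta (~25 Hz) and gamma
(~35 Hz) oscillatory states, and couples a periodic retinal ganglion-cell
(GC) spike source to it so that rhythmic light flicker can entrain, accelerate, or
fail to entrain, the ongoing rhythm depending on the state and the flicker
parameters.

## Network

Four thalamic populations — 49 high-threshold bursting cells (HTC),
144 relay cells (RTC), 64 local interneurons (IN), 100 reticular cells
(RE) — and a cortical patch of 80 pyramidal (PY) and 20 fast-spiking (FS)
neurons.  Cortical cells connect with probability 0.8 (0.5 within PY).
Thalamic chemical projections follow the loop narrated by the physiology
this model family is built on: HTC excite IN and RE; RTC excite RE; RE
inhibit HTC, RTC, IN and one another; IN inhibit RTC; RTC carry the
thalamic rhythm to PY and FS; PY feed weakly back to RTC and RE.
Gap junctions couple HTC–HTC (100 MΩ), HTC–RTC and RE–RE (300 MΩ) pairs
within spatial neighborhoods of the population grids (7×7, 12×12, 10×10);
the HTC sheet is densely coupled (radius 3 grid units) because it is the
pacemaker, while HTC–RTC junctions are sparse (about one partner for half
the HTC cells) so that relay loading does not stall the pacemaker.
Probabilities, strengths and radii are not printed in the source
description and are exposed configuration defaults.

## Thalamic neurons

Hodgkin–Huxley point neurons, current balance

    Cm dV/dt = −g_L(V−E_L) − g_KL(V−E_KL) − Σ I_int − Σ I_syn

with intrinsic currents I_i = g_i m^p h^q (V−E_i), first-order gating
dx/dt = φ(x∞−x)/τ(V,[Ca]) and a calcium pool
d[Ca]/dt = −I_Ca/(zFw) + ([Ca]_rest−[Ca])/τ_Ca.  The channel roster per
cell type (transient Na⁺, delayed-rectifier K⁺, low-threshold T-type Ca²⁺
with relay- and reticular-specific kinetics, a high-threshold Ca²⁺ current
for HTC bursting, the hyperpolarization-activated cation current, fast and
high-threshold M-type K⁺ currents, and a Ca²⁺-activated K⁺
afterhyperpolarization current) follows the Destexhe/Huguenard family of
thalamic models.  The original parameter tables are not reproduced in the
text we implement from, so all kinetic constants and conductance densities
live in the configuration and were fixed **once** by calibrating the model
to the defining property of the study conditions: a 100-Hz Poisson
background drive of 2.5 / 15 / 25 nS per neuron must place the network in
the 9 / 25 / 35 Hz states.  After that calibration nothing was moved.

The mechanism that emerged from the calibration:

- **Alpha.**  At 2.5 nS the HTC sheet rests near −65 mV, where the
  high-threshold Ca²⁺ current's inactivation gate (half-inactivation
  −64 mV, recovery τ ≈ 330 ms at hyperpolarized voltages) recovers.  Each
  cycle a two-spike high-threshold burst fires, the M-type and AHP
  currents hyperpolarize the cell, the h-current ramps it back, and the
  gap-junction-coupled sheet synchronizes the ~9-Hz cycle.  Relay cells
  are mostly silent and follow through their sparse gap junctions, so the
  thalamic sLFP (and, through RTC→cortex synapses, the cortical sLFP)
  oscillates at ~9 Hz.
- **Beta/gamma.**  At 15 and 25 nS the mean drive conductance depolarizes
  all TC cells past the inactivation range of both T-type currents; HTC
  switch to single-spike tonic firing whose rate is set by the balance of
  drive against the two M-type currents (the high-threshold variant
  engages progressively at depolarized inter-spike voltages and flattens
  the frequency–input curve so 15 nS ↦ ~25 Hz and 25 nS ↦ ~35 Hz).  The
  strongly-coupled HTC sheet behaves as a mean-driven ensemble oscillator
  whose rhythm propagates to RTC, IN, RE and cortex.

## Cortical neurons

Adaptive exponential integrate-and-fire (the printed equations), with
conductance-based synapses that jump by Q per presynaptic spike and decay
exponentially (τ_E = 5 ms, τ_I = 15 ms).  A spike is declared at 0 mV; the
membrane is reset and held for the refractory period and the adaptation
current increments by b.  Inside RK4 stages the exponential term's
argument is capped and the adaptation coupling saturates at the cutoff
voltage so stage evaluations stay finite; the event handler performs the
actual reset.  PY/FS parameters are generic regular-spiking and
fast-spiking values; the recurrent cortical loop is kept weak relative to
the thalamocortical drive so the cortex follows the thalamus rather than
generating its own rhythm.

## Synapses

Thalamic chemical synapses use first-order transmitter binding
(ds/dt = α[T](1−s) − β s with a 0.5 mM, 0.3 ms pulse per presynaptic
spike), short-term depression D = 1 − (1 − D_i(1−U)) e^{−(t−t_i)/τ} with
U = 0.07 and τ = 700 ms on every chemical synapse, and currents
I = s·D·g·B(V)·(V−E) where B(V) is the standard sigmoidal magnesium block
for NMDA (1 mM Mg²⁺) and unity otherwise.  Because the 0.3-ms/0.5-mM
pulse opens only ~15 % of AMPA channels per spike, the per-synapse maximal
conductances are correspondingly larger than peak-conductance
parameterizations of the same pathways.  Depression state is stored per
(presynaptic neuron, projection): with identical kinetics within a
projection this is exactly equivalent to per-synapse state.

The single GC cell contacts every HTC, RTC and IN cell.  TC cells receive
monosynaptic AMPA (0.15 µS, reversal +10 mV) — one GC spike fires a
quiescent TC cell.  IN cells receive AMPA+NMDA scaled by a factor
calibrated by bisection (`calibrate_gc_in_scale`) so that three
near-simultaneous GC inputs are needed to fire an interneuron; the
shipped default (0.075) is the result of that calibration.

## Flicker protocols

The GC train is strictly periodic at the flicker frequency.  Intensity is
the number of spikes per flash (1–3).  The duty cycle (k/6 of the period)
defines the ON window; multiple spikes are equally spaced across the
window including its end, a single spike sits at the window onset.  In
the duty-cycle experiment duty k/6 carries min(k, 3) spikes — the
construction in which duty is proportional to spike count, capped at
three.  With a single onset-locked spike the duty cycle would not change
the input at all, so "duty with intensity 1" is not a physically
meaningful protocol in this model; see the limitations below.

## Integration

Classical RK4 with a fixed 0.02 ms step advances all continuous state
(membrane voltages, channel gates, calcium, drive and cortical
conductances, adaptation currents).  Receptor gating s and depression D
are linear ODEs with piecewise-constant coefficients over one step and are
advanced by their exact exponential updates; chemical conductances are
frozen for one step while driving forces and the NMDA block follow the
stage voltages.  Spike detection (0 mV upward crossing, 1 ms lockout),
transmitter-pulse onsets, depression drops, quantal jumps and Poisson
arrivals are processed at step boundaries.  Gate kinetics are evaluated
from 0.05-mV lookup tables (the calcium-gated AHP gate analytically);
initial voltages sit at the leak steady state ±5 mV uniform jitter, gates
at their steady state, calcium at rest, s = 0, D = 1.

## Analysis

The sLFP is the population-mean membrane potential (HTC∪RTC for the
thalamus, PY∪FS for the cortex), decimated to ~1 kHz and band-passed
0.5–80 Hz with a zero-phase FIR filter (window design, order ≈ 1.5 cycles
of the low edge, capped at a third of the record).  Spectra use Welch's
method (Hann, 2-s segments, 50 % overlap, 0.5 Hz resolution): the raw
full-record periodogram of a 4-s noisy record makes the argmax a draw from
the noise — with averaging the dominant frequency is reproducible across
drive realizations.  "Power" is the Welch power estimate, so the
normalized power P_max/P₀ is quadratic in amplitude.  Spike phases are
measured between successive positive sLFP peaks (minimum separation half
the dominant period) and summarized by the resultant length (SI);
population coupling by the signed extremum within ±50 ms lag of the
Pearson-normalized cross-correlation of mean-removed 2-ms PETHs.
Entrainment: |f_s − f_d| < 1 Hz and P_max/P₀ > 1 against a matched
unstimulated run of the same network and seed.

## Reproducibility and problem sizes

One root seed drives independent substreams for connectivity,
heterogeneity (leak conductance uniform in 0.0075–0.0125 mS/cm²),
initial-condition jitter and per-run drive noise, so a protocol sweep
reuses the identical network.  Simulations in the test suite and the
acceptance script run 5 s with a 1-s warmup discard — enough for eight
Welch segments — rather than the 10 s used for the headline figures;
single-cell checks run 0.15–3 s.  The compiled core integrates the full
457-cell network at roughly 7× real time on one CPU.

## What the synthetic conditions do and do not show

All inputs are generated internally: Poisson background drive (the state
selector), i.i.d. cortical noise trains and the deterministic GC train.
Passing tests show that the implemented biophysics reproduces the
state-dependent entrainment phenomenology under these idealized drives;
they do not show that the parameter set matches any particular biological
tissue, and the frequency calibration is specific to the 100-Hz/2.5–25-nS
drive convention.

## Known limitations

- The channel kinetics are reconstructed from the model family, not from
  the original (unavailable) parameter tables; individual current
  densities should be read as effective, calibrated values.
- The alpha state under 40-Hz flicker is strongly suppressed, so the
  accelerated low-band peak (~12–14 Hz) rides on a weak, broad bump and
  its location fluctuates by ±2–3 Hz across drive realizations at 5-s
  duration.
- In the duty-cycle sweep the 5/6 verdict is marginal: the stimulus-evoked
  EPSP wave contributed by the strong GC→TC synapses keeps the 40-Hz sLFP
  peak just above the unstimulated baseline (P_max/P₀ ≈ 1.0–1.7) even
  though the spiking network is no longer phase-locked, so the verdict can
  flip positive depending on the realization, unlike the clean negative
  at 4/6.
- Cortical gamma peaks are broader than thalamic ones; the residual
  PY–FS loop resonance occasionally pulls the cortical argmax a few Hz
  above the thalamic rhythm at the gamma state.
- OFF-type ganglion responses (frequency doubling), GABA_B inhibition,
  synaptic facilitation and conduction delays are not modeled.
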