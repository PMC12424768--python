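# Methods

## Model overview

The network models theta-driven gamma generation in layer II/III of the
medial entorhinal cortex with two single-compartment populations: 100
fast-spiking PV+ interneurons (I) and 400 stellate cells (E). Pyramidal
cells are not modeled separately. All units are absolute: conductances in
nS, capacitance in pF, potentials in mV, time in ms, currents in pA
(nS × mV = pA).

### Fast-spiking interneuron

Wang–Buzsáki formalism: transient Na⁺ (instantaneous activation m∞³, gate
h), delayed-rectifier K⁺ (n⁴) and leak, with a gating temperature factor
φ = 5. Defaults: C = 100 pF, g_Na = 3500 nS, g_K = 900 nS, g_L = 20 nS
(input resistance 50 MΩ, in the range of cortical PV+ basket cells),
E_Na = 55, E_K = −90, E_L = −65 mV. An optional uniform voltage shift of
the gates (`v_shift`, default 0) raises the firing threshold. The cell
fires tonically and non-adaptingly; at the 7 nS peak of the theta drive it
sustains ~150 Hz.

### Stellate cell

The classic Hodgkin–Huxley Na⁺/K⁺/leak equations, modified in three ways to
capture mEC stellate physiology:

* the Na gates are shifted +8 mV and the K-DR gate +25 mV, so the spike
  generator is closed at rest (classic squid kinetics otherwise produce a
  strong ~50–60 Hz subthreshold K-gate resonance that masks the theta
  resonance);
* a persistent Na⁺ current (Magistretti–Alonso-type activation, half
  −48.7 mV, slope 4.4) amplifies subthreshold oscillations;
* an HCN (h) current (activation half −79.2 mV, τ ≈ 80 ms near rest,
  E_h = −20 mV) confers sag and resonance.

Defaults: C = 50 pF, g_Na = 6000, g_K = 1800, g_L = 15, g_NaP = 8.5,
g_h = 15 nS, E_L = −75, E_K = −90 mV. The cell rests near −64 mV, its
subthreshold impedance peaks at ~11 Hz (inside the theta band), and under
the 3 nS theta drive it fires ~1–2 spikes per theta cycle.

### Heterogeneity

Every maximal conductance of every cell is jittered once at network
assembly as Normal(g, cv·g) truncated at zero, cv = 0.1 for both
populations (`jitter_cv_i`, `jitter_cv_e`).

### Synapses and connectivity

| class | probability | kinetics | reversal | peak conductance |
|-------|-------------|----------|----------|------------------|
| E→I | 0.4 | exponential, τ = 1 ms | 0 mV | g_EI / 7 per edge (see below) |
| I→E | 0.3 | bi-exponential 0.4 / 6 ms | −65 mV | lognormal, median 0.4 nS, σ = 0.3 |
| I→I | 0.3 | bi-exponential 0.3 / 2.5 ms | −75 mV (configurable) | 0.45 nS per edge |

No E→E connections exist and I→I autapses are forbidden. Bi-exponential
conductances are normalized so the per-edge peak equals the stated value.
Spikes (upward 0 mV crossings, 2 ms refractory) take effect on the next
time step; an explicit synaptic delay is not modeled.

The I→I kinetics are deliberately faster than the I→E synapse: PV–PV
GABA_A synapses are among the fastest in cortex (decay ~2 ms), and with a
6 ms I–I decay the driven interneuron network cannot sustain the fast
(~140 Hz) ING rhythm that is the model's baseline operating point.

**The E→I conductance axis.** Experiments quote the E→I coupling as an
"average total" conductance estimated by dividing the peak-to-peak
gamma-frequency excitatory current by the holding potential — i.e. the
summed conductance of the synapses active within one synchronized volley,
not the sum over all ~160 anatomical afferents. The package therefore
parameterizes the coupling on that axis (`g_ei`) and converts to a
per-edge peak as g_ei / `ei_edge_divisor`, divisor 7 ≈ p_EI × (volley of
~18 E cells). The divisor is anchored so that the fast→slow regime
transition falls at g_ei ≈ 12 nS; `ei_edge_divisor = 1` recovers raw
per-edge semantics.

### Theta drive and noise

Optogenetic drive is the unique non-negative sinusoid with zero minimum,
g(t) = (g_peak/2)(1 − cos 2πf t), f = 8 Hz, reversal 0 mV, peak 7 nS onto
I cells and 3 nS onto E cells. Phase 0 is the drive trough; cycle windows
are [k/f, (k+1)/f). The I-cell drive additionally receives an independent
per-cell Ornstein–Uhlenbeck conductance perturbation (sd 0.35 nS = 5% of
the peak, τ = 1 ms, exact discretization, total drive clipped at zero);
without it the common sinusoid alone entrains spurious synchrony. An
unconnected I population under the default drive has gamma-band spike-time
vector strength < 0.1.

### Readouts

Five cells per population are voltage-clamped observers (default 0 mV):
they receive afferents sampled by the same rules but never spike and never
project. Their clamp current is Σ g_syn (V_hold − E_rev); at 0 mV the
AMPA and drive conductances (E = 0) contribute nothing, so the recorded
current isolates GABAergic input, mirroring the experimental IPSC
recordings. Connectivity and weights for readouts are drawn after the
active-cell draws in per-class RNG streams, so adding or removing readouts
never changes the network dynamics.

## Numerics

Fixed-step integration at dt = 0.025 ms. Gating variables advance by
exponential Euler; the membrane potential also advances by exponential
Euler on the conductance form of the membrane equation
(V ← V∞ + (V − V∞)·exp(−dt·g_tot/C)), which is unconditionally stable —
forward Euler is unstable at this dt for HH-type channel densities
(g_Na/C ≈ 120 ms⁻¹). In the network kernel the voltage-dependent gate
quantities are evaluated from lookup tables on a 0.05 mV grid with linear
interpolation (error O(10⁻⁶) in the gates); single-cell simulations use
the exact rate functions. Halving dt changes spike times by < 0.5 ms and
subthreshold trajectories by < 0.5 mV over 1 s. Runs abort with a
diagnostic if |V| exceeds 200 mV or the spike buffer overflows. Initial
voltages are drawn U(−75, −60) per cell (gates at steady state) from the
simulation seed; the first theta cycle is discarded by every analysis.

Determinism: a (network seed, simulation seed) pair fixes the adjacency,
weights, heterogeneity, initial state and the in-kernel noise realization
bit-for-bit. Paired control/AMPA-blocked runs share both seeds and differ
only in the E→I weights.

## Analysis pipeline

* **Filtering**: 4th-order Butterworth band-pass 50–200 Hz applied forward
  and reverse (`scipy.signal.sosfiltfilt`), i.e. zero net phase.
* **Scalogram**: analytic Morlet, ω₀ = 6, geometric frequency grid 40–250 Hz
  at 32 scales per octave, computed in the FFT domain. Normalization is
  envelope-amplitude-squared: a tone of amplitude a (pA) has peak power a²
  (pA²), which makes the absolute pA² exclusion thresholds meaningful.
  The printed "rad/sec" unit of ω₀ is treated as the standard
  dimensionless Morlet parameter.
* **Cycle handling**: the scalogram is segmented into theta cycles; the
  first cycle and any cycle whose raw current exceeds 3000 pA are dropped;
  the remaining cycles are averaged.
* **Peak summary**: global maximum of the cycle-averaged power within the
  filter band. SNR = peak power / mean of the cycle-averaged power over
  all computed scales and times (the averaging domain is not pinned down
  by the recording protocol; this is the package's definition). Bandwidth
  = full width at half maximum along frequency through the peak's time
  bin, clipped at the grid edges.
* **Exclusions**: drop if power < 20 pA² (Thy1 mode) / 10 pA² (PV mode),
  bandwidth > 100 / 110 Hz, or SNR < 5.
* **Spike statistics**: peaks above 0 mV with 2 ms separation; theta-phase
  histograms with 30 bins of π/15 rad normalized per cycle; interspike
  rate (1/ISI) histograms with left-closed 10 Hz bins from 0 Hz; spikes
  per cycle as mean ± SEM across cycles.

## Calibration

The recording protocol fixes the architecture, probabilities, drive and
the I→E/E→I kinetics, but the quantitative cell calibrations and the I–I
parameters live in prior work and are not printed. The free parameters
(FS leak, stellate g_NaP, I–I peak conductance and kinetics, I→E lognormal
median/σ, OU noise level, the E→I axis divisor) were fixed once against
the qualitative operating regime the recordings and simulations establish,
and then frozen:

* interneuron-only network (E→I = 0): fast ING, ~105–130 Hz across seeds;
* weak coupling (3.6 nS axis): fast rhythm ~125–140 Hz, E cells firing
  ~1–1.5 spikes/cycle with gamma cycle skipping, readout IPSC amplitudes
  of a few hundred pA;
* increasing coupling: approximately conductance-independent power below
  the transition; a discontinuous, connectivity-dependent switch to a
  60–80 Hz PING rhythm near 12 nS; all-slow behavior at 18 nS;
* strong coupling (120 nS): slow PING whose simulated AMPA block restores
  a fast (>100 Hz), weaker rhythm.

## Known limitations

* The fast/slow switch is a bistable regime with a window of coexistence:
  individual connectivity seeds can fall into the slow attractor slightly
  below 12 nS or stay fast slightly above it (the experimental box plots
  likewise show outliers). The transition *point* is reproduced; its
  sharpness across seeds is not guaranteed at desk scale.
* Simulated AMPA block in the weak regime shifts the peak frequency by
  ~0–35 Hz depending on the seed (median ~15–25 Hz), because removing even
  weak excitation drops some realizations into a lower ING band. The
  experimental paired recordings show shifts of comparable spread (median
  11.4 Hz, IQR ±22 Hz in fast-spiking cells).
* With the Wang–Buzsáki interneuron formalism, the shunting
  (E_GABA = −55 mV) I–I network retains partial gamma synchrony after
  AMPA block rather than losing it: shunting inhibition is known to
  synchronize this cell class robustly. Reproducing shunting-induced
  desynchronization evidently requires the specific calibrated PV+ model
  of the original study, which is not printed.
* The synthetic test signals (theta-gated sinusoidal carrier plus white
  or 1/f noise, rectangular artifacts) validate the analysis pipeline's
  frequency/power recovery and exclusion logic; they do not emulate the
  full biophysical statistics of recorded currents, so passing those
  tests says nothing about biological realism beyond the pipeline.
* No synaptic delays, gap junctions, SST+ interneurons, pyramidal cells,
  or stochastic channel noise. Desk-scale runs analyze 10 theta cycles
  (the protocol's 40-cycle analysis is available via
  `SimConfig(n_theta_cycles=41)`).
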