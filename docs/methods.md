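# Methods

`golgisim` implements a multicompartmental, conductance-based model of the
cerebellar Golgi cell — the main inhibitory interneuron of the granular
layer — together with the machinery needed to build, optimize, validate and
interrogate such models: SWC morphology handling and a surrogate morphology
generator, an implicit cable solver with Hodgkin–Huxley and Markov channel
kinetics and submembrane calcium dynamics, dynamic synapses, an
electrophysiological protocol battery, a seeded evolutionary optimizer for
the per-section maximum conductances, and a calcium-threshold predictor of
spike-timing dependent plasticity (STDP) at the mossy fiber synapse.

## Cable model and numerics

Morphologies are trees of typed sections (soma, axon, AIS, basal and apical
dendrites) discretized into an odd number of cylindrical compartments per
section (center-sampled voltage; compartment diameter is the length-weighted
mean of the diameter profile, so membrane area is conserved exactly under
refinement).  Passive parameters follow the Golgi cell literature values:
Ra = 122 Ω·cm everywhere, Cm = 1 µF/cm² except 2.5 µF/cm² in dendrites,
GL = 3·10⁻⁵ S/cm² except 10⁻⁶ S/cm² in the axonal sections (the AIS is
treated as axonal membrane), E_leak = −55 mV.  The leak reversal above the
K reversal is what slowly drives the pacemaker cycle between spikes.

The voltage update is backward Euler at a fixed 0.025 ms step, solved in
linear time with a Hines ordering of the compartment tree; ideal voltage
clamps enter through a penalty term (10⁹ µS).  Channel states advance at
the pre-step voltage (first-order splitting): HH gates by exponential
integrators with kinetics tabulated on a 0.25 mV grid, Markov channels by a
per-compartment backward-Euler solve of the small (I − dt·Qᵀ) system, which
is unconditionally stable for stiff schemes and conserves probability.
Backward Euler is first order: refining dt from 0.025 to 0.005 ms shifts
spike times by about 1 ms per pacemaker cycle without creating or deleting
spikes; inter-spike statistics agree to better than 2%.  The hot loop is
compiled with numba; the module-level gate/Markov/calcium operations are
plain-numpy reference implementations, and a test asserts that the compiled
path reproduces them.

## Channels and calcium

The channel registry (`golgisim/data/channels.yaml`) mirrors the published
conductance table of the Golgi cell model column-for-column: default
maximum conductance, [min, max] optimization bounds, reversal potential
(Na +60, K −80, HCN −20 mV; Ca fixed at 137.5 mV, no GHK) and model class
per channel and section.  The gating equations themselves are cited, not
printed, in that literature, so the registry ships this package's own
parameterized forms — Boltzmann m∞/τ gates for HH channels and explicit
rate tables for the Markov channels — calibrated as a set so that the
default conductances reproduce the validated Golgi behaviors (below).
Notable choices:

* **Nav1.6** is a 4-state Markov scheme (C ⇌ O ⇌ I plus a slow inactivated
  state I2).  The C ⇌ O equilibrium provides a small persistent "window"
  component above ≈ −60 mV that, with the leak and HCN, drives pacemaking;
  I2 accumulates during sustained depolarization and recovers below
  ≈ −55 mV over a few hundred ms, producing spike-frequency adaptation and
  the slow burst rhythm seen under KCa blockade.
* **Cav3.1** (T-type) carries a de-inactivating window current that
  accelerates the return to firing after release from hyperpolarization
  (the rebound); **Cav2.3** (R-type) includes slow inactivation so that
  depolarized plateaus collapse rather than persist.
* **Kca1.1 (BK) and Kca2.2 (SK)** are Markov schemes whose Ca-binding steps
  read a *channel-local calcium domain* fed exclusively by Cav2.2 (N-type)
  current, reflecting the tight Cav2.2–KCa coupling this cell type shows
  (blocking Cav2.2 and blocking Kca2.2 have the same firing signature).
  The domain is a first-order pool per compartment (gain × shell influx,
  τ = 10.9 ms, gain 1.0).  SK opening after each spike-triggered Cav2.2
  bolus sets the inter-spike interval floor.
* The **submembrane shell** (0.1 µm, resting [Ca] 50 nM) integrates all
  other Ca sources with one lumped buffer (20 µM, k_on 100 /mM/ms, k_off
  0.1 /ms) and a surface pump that is first order in the Ca excess; pump
  densities per section are the published values (apical 2·10⁻⁹, basal
  5·10⁻⁹, soma 10⁻⁷, AIS/axon 10⁻⁸ mol/cm²) with a global turnover chosen
  so the somatic shell clears in milliseconds and dendritic shells in tens
  of milliseconds.  The shell drives Kca3.1 (soma) and the plasticity
  readout.

All kinetics are defined at the 32 °C reference (slice temperature);
simulating at another temperature applies a Q10 factor (default 3).

## Emergent electrophysiology of the default model

With the registry defaults on the compact surrogate morphology the model
pacemakes at ≈ 5.8 Hz with ISI CV ≈ 0; spikes initiate in the AIS and
backpropagate at ≈ 65% of AIS amplitude into distal basal dendrites but
only ≈ 18% into apical dendrites; a −0.2 nA step silences the cell and
reveals a 5–6 mV HCN-dependent sag; release from the step transiently
accelerates firing (Cav3.1-dependent rebound); repetitive current steps
drive preferentially at 1–4 Hz repetition frequencies; 90% Cav2.2 block
uncovers slow oscillatory bursting at ≈ 5 Hz, and Kca2.2 block reproduces
the same signature.  The f–I curve is monotone and close to linear over
0.1–0.5 nA but shallower than the biological cell's (≈ 10 → 16 Hz rather
than tens of Hz); consequently synaptic bursts are 1–2 spikes and the
trimming of burst spikes by inhibition is below the model's discrete
resolution (inhibition lengthens the pause and never increases the
response, which is what the tests assert).  This is the main known
limitation of the shipped calibration.

## Synapses

Presynaptic dynamics are the Tsodyks–Markram resource/utilization model,
advanced event-to-event in closed form (facilitation decays, is incremented
before release, resources recover exponentially; the first event releases
exactly p).  Pathway parameters are the published values — PF/AA p = 0.4,
τ_rec = 35.1 ms, τ_fac = 55 ms; MF p = 0.43, τ_rec = 5 ms, τ_fac = 8 ms;
inhibitory p = 0.5, τ_rec = 15 ms, τ_fac = 4 ms — giving PPR = 1.04 for MF
pairs and 1.10 for PF pairs at 50 Hz.

Receptors are 3-state (closed/open/desensitized) schemes driven by a
biexponential transmitter pulse whose peak scales with the released
fraction.  Binding/unbinding rates are calibrated so a single release
produces the reported unitary currents: PF-AMPA ≈ 25 pA at −70 mV
(G_max 1200 pS), GABA-A ≈ 3.5 pA at −80 mV (G_max 2600 pS, E_rev −70 mV),
and an NMDA component of ≈ 5 pA around rest (G_max 10000 pS) with 10% of
the NMDA current converted to calcium influx.  NMDA Mg unblock is a
Boltzmann sigmoid, 1/(1 + [Mg]/3.57 mM · e^(−0.073 V)); the slope was set
together with the plasticity readout (below) so that NMDA calcium at the
holding potential stays below the LTP/LTD threshold while coincident
backpropagating bursts cross it.

Placement rules: PF on apical compartments (at most one per compartment),
AA one per basal section, MF on basal compartments ≥ 20 µm of path distance
from the soma, inhibitory synapses on both dendrite classes; placement is
deterministic per seed and audited by `audit_placement`.

## Optimization and validation

The genome is the vector of free per-section maximum conductances (25
placements) with the registry's printed ranges as bounds.  Scoring
simulates positive current steps and compares six features (AP width and
height, AHP depth, ISI CV, mean frequency, spike count) to a template as
|x − µ|/σ; missing features incur a fixed penalty.  The optimizer is a
seeded generational GA (tournament selection, uniform crossover, per-gene
Gaussian mutation with σ = 10% of the range, elitism).  The reference
regime for this problem is a 576 × 10 population on an HPC system; the
desk-scale defaults used throughout this package are population 16 × 4
generations with 1 s steps, and the acceptance runs use population 8 × 3.
Because the printed ranges are narrow, any in-bounds genome is close to the
exemplar; the desk-scale GA refines within that family rather than
searching de novo, and the shipped feature template
(`golgisim/data/fitting.yaml`) is a documented approximation meant to be
replaced for serious fits.

Validation is the three-step battery: (1) spontaneous rate in [2, 15] Hz,
ISI CV < 0.3, and f–I points inside a configured envelope (the published
envelope is not printed numerically; the shipped band brackets what this
model family does); (2) sag depth in [4.4, 10] mV at −0.2 nA / 1000 ms;
(3) 90% Cav2.2 block must uncover slow (≤ 5.5 Hz) oscillatory bursting,
with Kca2.2/Kca1.1 reductions reported alongside.

## STDP prediction

The plasticity module implements the calcium-control hypothesis at the MF
synapse: the peak NMDA-driven calcium transient maps to a weight change
through Ω(Ca) = 2·A·(σ(rate·(Ca − θ)) − ½) with θ = 0.75 µM, rate 10 /µM
and A = 50%, so the sign inverts exactly at θ.  A conjunction protocol
delivers one MF event and a 5-impulse 100 Hz PF burst displaced by
`dt_pre_post` (positive dt = MF leads).  A small holding current (−0.02 nA)
suppresses the pacemaker, and the event is placed in a deterministic quiet
window so the backpropagating spikes are those the PF burst elicits.  The
recorded NMDA calcium current is integrated offline into the MF
compartment's calcium model using the whole compartment as the mixing
volume (equivalent depth = diameter/4) and the peak is multiplied by 3 —
standing in for local store amplification — before applying Ω.  With the
defaults, MF-alone transients sit below θ (LTD side), MF-leading
conjunctions cross it (LTP up to ≈ +46% at dt ≈ +40 ms), PF-leading
conjunctions stay below (LTD), and the magnitude grows monotonically with
the number of active parallel fibers (11 → 81).  The LTP peak sits at
larger positive dt than in the biological curve because the model's PF
bursts develop over tens of ms.

## Surrogate morphologies

`make_surrogate` emulates adult mouse Golgi cell reconstructions: a
16–27 µm soma, basal dendrites branching in the granular layer, apical
dendrites ascending into the molecular layer (+y), and an axon with a
distinct initial segment stemming from the soma or from a basal dendrite
with equal probability.  Dendritic labels are assigned with the same
Purkinje-cell-layer boundary rule the classifier uses, so generator labels
and positional classification agree by construction.  The default preset
draws per-cell length/diameter variability (±15%) and yields input
resistances of ≈ 225 ± 10 MΩ across seeds, within one reported standard
deviation of the published population mean (339 ± 128 MΩ).  The `compact`
preset (three unbranched basal dendrites, two once-branching apical
dendrites, ≈ 60 compartments, no variability) is the controlled desk-scale
morphology used for tests and optimization runs; its thin apical branches
also reproduce the strong apical attenuation of backpropagating spikes.
What passing tests on surrogates do *not* show: behavior on real
reconstructions with full axonal/dendritic complexity, or synaptic loads at
the anatomical counts (thousands of PF contacts).

## Problem sizes and determinism

Default problem sizes were chosen so the full test battery runs on a single
workstation core: compact morphology (~60 compartments) for intrinsic
protocols and optimization, full surrogate (~200–300 compartments) for
synaptic-load and STDP protocols, 2–3 s simulated per protocol, GA at
population 8–16 for 2–4 generations.  Every stochastic element (surrogate
geometry, synapse placement, GA) is driven by an explicit seed; the solver
itself is deterministic, so repeated runs are bit-identical.
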