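# golgisim

Multicompartmental, conductance-based modeling of the **cerebellar Golgi
cell**, the principal inhibitory interneuron of the granular layer.  The
package builds morphology-based cable models with Hodgkin–Huxley and Markov
ion channels and submembrane calcium dynamics, attaches dynamic synapses
for the cell's four input pathways, runs the standard electrophysiological
protocol battery, optimizes the per-section maximum conductances with a
seeded evolutionary algorithm, and predicts spike-timing dependent
plasticity (STDP) at the mossy fiber synapse from NMDA-receptor calcium.

It is written for computational neuroscientists who want a self-contained,
testable Python implementation of this model class — no external simulator
required (the cable solver and channel kinetics are built in and compiled
with numba).

## The model in brief

The membrane potential of each cylindrical compartment follows the cable
equation

    Cm dV/dt = -GL (V - EL) - Σ_i g_i(t) (V - E_i) - I_syn + I_axial + I_inj

solved implicitly (backward Euler, fixed 0.025 ms step) on the dendritic
tree via a Hines factorization.  Channels are distributed by section class
(soma, axon, axon initial segment, basal and apical dendrites) following
the published Golgi cell conductance map: Nav1.6 everywhere at graded
density, Kv1/Kv3.4/Kv4.3/Kca3.1/Cav2.2/Cav3.1 in the soma, Kv7/HCN1/HCN2/
Cav2.2/Kca1.1 in the AIS, and Cav/KCa combinations in the dendrites.
KCa channels read a Cav2.2-fed local calcium domain; all other calcium
feeds a buffered, pumped submembrane shell.

Synapses combine Tsodyks–Markram presynaptic dynamics (u, R, with the
published p / τ_REC / τ_FAC per pathway) with 3-state receptor schemes
(AMPA, NMDA-NR2B with Boltzmann Mg unblock, GABA-A).  Plasticity follows
the calcium-control hypothesis: the peak NMDA calcium transient Δ[Ca²⁺]ᵢ
maps to a weight change through the sigmoidal transfer function

    ΔW(%) = 2A (σ(rate · ([Ca] - θ)) - 1/2),   θ = 0.75 µM, rate = 10 /µM, A = 50%

so mossy fiber events that coincide with parallel-fiber-driven
backpropagating bursts cross θ (LTP) while isolated or badly timed events
stay below it (LTD).

See `docs/methods.md` for the full account of the numerics, the calibrated
kinetics, and known limitations.

## Worked example

```python
import golgisim.morphology as morph
from golgisim import solver, protocols

m = morph.make_surrogate(morph.SurrogateParams.compact(), seed=1)
morph.discretize(m, 40.0)
cell = solver.build_cell(m)          # shipped channel registry defaults

fs = protocols.spontaneous(cell)
print(f"spontaneous rate : {fs.mean_frequency:.1f} Hz (ISI CV {fs.isi_cv:.3f})")
print(f"input resistance : {solver.input_resistance(cell):.0f} MOhm")
print(f"sag at -0.2 nA   : {protocols.measure_sag(cell):.1f} mV")
bp = protocols.backprop_ratios(cell)
print(f"backpropagation  : basal {100*bp['basal_ratio']:.0f}% / "
      f"apical {100*bp['apical_ratio']:.0f}% of AIS spike amplitude")
```

prints

```
spontaneous rate : 5.8 Hz (ISI CV 0.000)
input resistance : 461 MOhm
sag at -0.2 nA   : 6.3 mV
backpropagation  : basal 66% / apical 18% of AIS spike amplitude
```

— a pacemaking Golgi cell in the experimental 2–15 Hz band whose spikes
initiate in the AIS and invade basal dendrites far more effectively than
apical ones, with an HCN-dependent sag in the validated 4.4–10 mV range.
Switching off channels reproduces the pharmacology: removing HCN abolishes
the sag, and 90% Cav2.2 (or Kca2.2) block uncovers slow oscillatory
bursting:

```python
blocked = protocols.switch_off(cell, "Cav2.2",
                               ["basal_dendrite", "soma", "AIS"], 0.9)
```

The CLI mirrors the library: `golgisim morph surrogate --seed 1 --out c.swc`,
`golgisim protocol --name sag --config run.yaml`, `golgisim optimize ...`,
`golgisim validate ...`, `golgisim stdp ...`.

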