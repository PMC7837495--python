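"""Spike-timing dependent plasticity prediction at mossy fiber synapses.

The calcium-control hypothesis maps the peak NMDA-receptor-driven calcium
transient in the postsynaptic compartment onto a synaptic weight change
through a sigmoidal transfer function (the omega function): calcium below
the inversion point theta yields depression (LTD), above it potentiation
(LTP).  Coincidence detection arises from voltage-dependent Mg unblock:
when a parallel-fiber-driven backpropagating spike depolarizes the basal
dendrite around the time of mossy fiber transmitter release, the NMDA
conductance unblocks and calcium influx grows.

Defaults: theta = 0.75 uM, rate of change 10 /uM, amplitude 50%, and a x3
amplification of the NMDA shell transient standing in for local
calcium-store amplification.

Timing convention: ``dt_pre_post`` is the PF burst onset minus the MF event
time, so positive dt means the MF event precedes the PF-driven
backpropagating burst.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import membrane, solver
from .solver import CellModel, Recording
from .synapses import place_synapses

__all__ = [
    "OmegaSpec",
    "STDPPoint",
    "omega",
    "nmda_ca_transient",
    "stdp_curve",
    "io_surface",
]


@dataclass
class OmegaSpec:
    theta: float = 0.75  # uM, LTP/LTD inversion point
    rate: float = 10.0  # 1/uM, steepness
    amplitude: float = 50.0  # %, max |weight change|
    amplification: float = 3.0  # multiplier on the NMDA shell transient
    readout_length_um: float = 25.0  # dendritic segment mixing length

    def __post_init__(self):
        if self.theta <= 0 or self.rate <= 0 or self.amplitude <= 0:
            raise ValueError("theta, rate and amplitude must be positive")


@dataclass
class STDPPoint:
    dt_pre_post: float  # ms
    peak_dca: float  # uM
    weight_change: float  # %


def omega(ca_uM, spec: OmegaSpec | None = None):
    """Weight change (%) from peak calcium (uM): logistic with a zero
    crossing exactly at theta, saturating at +/- amplitude."""
    spec = spec or OmegaSpec()
    ca = np.asarray(ca_uM, float)
    if np.any(ca < 0):
        raise ValueError("calcium must be >= 0")
    sig = 1.0 / (1.0 + np.exp(-spec.rate * (ca - spec.theta)))
    out = 2.0 * spec.amplitude * (sig - 0.5)
    return float(out) if out.ndim == 0 else out


def _nmda_shell_peak(model: CellModel, comp: int, t, i_ca_trace,
                     amplification: float,
                     readout_length_um: float = 25.0) -> float:
    """Integrate a recorded NMDA calcium current through the local calcium
    model of the synapse's dendritic segment; return the amplified peak
    above rest (uM).

    The plasticity readout mixes the influx into a fixed-length cylinder of
    dendrite around the synapse (bulk volume, equivalent depth =
    diameter/4) rather than the thin submembrane shell, with the section's
    buffer and surface pump.  The fixed segment length makes the readout
    independent of the numerical compartmentalization.
    """
    import math
    from dataclasses import replace
    label = model.comp_labels[comp]
    cmp_ = model._comps[comp]
    spec = replace(model.calcium[label], depth_um=cmp_.diameter / 4.0)
    area = math.pi * cmp_.diameter * readout_length_um * 1e-8  # cm^2
    state = membrane.CalciumShellState.resting(spec)
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.1
    peak = spec.ca_rest
    for i_ca in i_ca_trace:
        state = membrane.calcium_step(spec, state, float(i_ca), area, dt,
                                      max_sub_dt=dt)
        if state.ca > peak:
            peak = state.ca
    return (peak - spec.ca_rest) * 1e3 * amplification  # mM -> uM


def _conjunction_model(model: CellModel, n_mf: int, n_pf: int, t_mf: float,
                       t_pf: float, seed: int, n_inh: int = 0,
                       t_inh: float | None = None,
                       pf_train=(5, 100.0), mf_train=(1, 100.0)):
    """Model copy with MF/PF (and optional inhibitory) trains attached."""
    counts = {"MF": n_mf}
    if n_pf:
        counts["PF"] = n_pf
    if n_inh:
        counts["INH"] = n_inh
    syns = place_synapses(model, counts, seed=seed)
    for s in syns:
        if s.pathway == "MF":
            n, f = mf_train
            s.spike_times = [t_mf + i * 1000.0 / f for i in range(n)]
        elif s.pathway == "PF":
            n, f = pf_train
            s.spike_times = [t_pf + i * 1000.0 / f for i in range(n)]
        elif s.pathway == "INH":
            n, f = pf_train
            t0 = t_inh if t_inh is not None else t_pf
            s.spike_times = [t0 + i * 1000.0 / f for i in range(n)]
    cell = model.copy_with(synapses=syns)
    mf_index = next(i for i, s in enumerate(syns) if s.pathway == "MF")
    return cell, mf_index


def nmda_ca_transient(model: CellModel, dt_pre_post: float, n_pf: int = 11,
                      n_mf: int = 1, seed: int = 0,
                      spec: OmegaSpec | None = None,
                      t_base: float = 1000.0, t_post: float = 400.0,
                      hold: float = -0.02) -> float:
    """Peak NMDA-driven calcium transient (uM, amplified) at an MF synapse
    for a PF burst displaced by ``dt_pre_post`` from the MF event.

    A small negative holding current (``hold`` nA) suppresses the pacemaker
    so backpropagating spikes are those elicited by the PF burst, making the
    coincidence window unambiguous.
    """
    spec = spec or OmegaSpec()
    t_mf = _quiet_window(model, hold, t_base)
    t_pf = t_mf + dt_pre_post
    cell, mf_index = _conjunction_model(model, n_mf, n_pf, t_mf, t_pf, seed)
    rec = [Recording("I_syn_ca", synapse=mf_index)]
    els = []
    if hold:
        els = [solver.Electrode("current_clamp", cell.soma_comp(),
                                [(0.0, hold)])]
    t_stop = max(t_mf, t_pf) + t_post
    res = solver.run(cell, els, rec, t_stop=t_stop)
    key = list(res.traces)[0]
    comp = cell.synapses[mf_index].comp
    m = res.t > min(t_mf, t_pf) - 50.0
    return _nmda_shell_peak(cell, comp, res.t[m], res.traces[key][m],
                            spec.amplification, spec.readout_length_um)


_QUIET_CACHE: dict = {}


def _quiet_window(model: CellModel, hold: float, t_base: float,
                  pre: float = 150.0, post: float = 250.0) -> float:
    """Earliest MF event time >= t_base with no residual pacemaker spike in
    [t - pre, t + post] under the holding current (deterministic control)."""
    key = (id(model), hold, t_base)
    if key in _QUIET_CACHE:
        return _QUIET_CACHE[key]
    from .protocols import detect_spikes
    els = []
    if hold:
        els = [solver.Electrode("current_clamp", model.soma_comp(),
                                [(0.0, hold)])]
    rec = [Recording("V", comp=model.soma_comp())]
    res = solver.run(model, els, rec, t_stop=t_base + 2000.0)
    st = detect_spikes(res.t, res.traces[list(res.traces)[0]])
    t = t_base
    while ((st > t - pre) & (st < t + post)).any():
        t += 50.0
        if t > t_base + 1500.0:
            break  # accept the least-bad window
    _QUIET_CACHE[key] = t
    return t


def stdp_curve(model: CellModel, dt_grid=None, n_pf: int = 11,
               n_mf: int = 1, seed: int = 0,
               spec: OmegaSpec | None = None) -> list:
    """Predicted STDP curve: one point per pre/post interval."""
    spec = spec or OmegaSpec()
    if dt_grid is None:
        dt_grid = np.arange(-100.0, 101.0, 25.0)
    out = []
    for dt in dt_grid:
        dca = nmda_ca_transient(model, float(dt), n_pf=n_pf, n_mf=n_mf,
                                seed=seed, spec=spec)
        out.append(STDPPoint(dt_pre_post=float(dt), peak_dca=dca,
                             weight_change=float(omega(dca, spec))))
    return out


def io_surface(model: CellModel, n_mf_grid=(0, 5, 10, 20),
               n_pf_grid=(0, 20, 40, 89), n_inh: int = 0,
               seed: int = 0, train=(5, 100.0), t_stim: float = 1000.0,
               window: float = 150.0) -> np.ndarray:
    """Output spike frequency (Hz) for combined MF/PF burst activation.

    Entry [i, j] is the rate in the response window for n_mf_grid[i] mossy
    fiber and n_pf_grid[j] parallel fiber synapses (5 spikes @ 100 Hz each);
    optional inhibition arrives with the excitatory onset.
    """
    from .protocols import detect_spikes
    out = np.zeros((len(n_mf_grid), len(n_pf_grid)))
    for i, n_mf in enumerate(n_mf_grid):
        for j, n_pf in enumerate(n_pf_grid):
            if n_mf == 0 and n_pf == 0 and n_inh == 0:
                cell = model
            elif n_mf:
                cell, _ = _conjunction_model(
                    model, n_mf, n_pf, t_stim, t_stim, seed,
                    n_inh=n_inh, pf_train=train, mf_train=train)
            else:
                cell = _pf_only(model, n_pf, t_stim, seed, n_inh, train)
            rec = [Recording("V", comp=cell.soma_comp())]
            res = solver.run(cell, [], rec, t_stop=t_stim + window + 50.0)
            key = list(res.traces)[0]
            st = detect_spikes(res.t, res.traces[key])
            n = ((st >= t_stim) & (st < t_stim + window)).sum()
            out[i, j] = n / (window / 1000.0)
    return out


def _pf_only(model, n_pf, t_stim, seed, n_inh, train):
    counts = {"PF": n_pf}
    if n_inh:
        counts["INH"] = n_inh
    syns = place_synapses(model, counts, seed=seed)
    n, f = train
    for s in syns:
        s.spike_times = [t_stim + i * 1000.0 / f for i in range(n)]
    return model.copy_with(synapses=syns)
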