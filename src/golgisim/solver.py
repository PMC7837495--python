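"""Implicit compartmental cable solver with electrode support.

``CellModel`` bundles a discretized morphology with passive parameters,
channel placements, calcium shells and synapses.  ``run`` advances the model
with a backward-Euler voltage update (fixed time step, default 0.025 ms)
interleaved with channel, calcium and synapse updates, using the compiled
kernels in :mod:`golgisim.engine`.

Passive defaults follow the Golgi cell model: Ra = 122 Ohm*cm everywhere,
Cm = 1 uF/cm^2 except dendrites 2.5, GL = 3e-5 S/cm^2 except the axonal
sections 1e-6, E_leak = -55 mV; all overridable per section class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import engine, membrane
from .morphology import Morphology, _axial_half_mohm

__all__ = [
    "CellModel",
    "Electrode",
    "Recording",
    "ProtocolResult",
    "build_cell",
    "assemble",
    "run",
    "input_resistance",
]

PASSIVE_DEFAULTS = {
    "ra": {"*": 122.0},
    "cm": {"*": 1.0, "basal_dendrite": 2.5, "apical_dendrite": 2.5},
    "gl": {"*": 3e-5, "axon": 1e-6, "AIS": 1e-6},
    "el": {"*": -55.0},
}


def _per_label(table: dict, label: str) -> float:
    return float(table.get(label, table["*"]))


@dataclass
class Electrode:
    mode: str  # 'current_clamp' | 'voltage_clamp'
    comp: int
    waveform: list  # [(t_ms, value)], piecewise-constant from each time
    series_resistance: float = 0.0  # MOhm (0 = ideal clamp)

    def __post_init__(self):
        ts = [t for t, _ in self.waveform]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError("waveform times must be non-decreasing")

    def sample(self, nsteps: int, dt: float, fill: float) -> np.ndarray:
        out = np.full(nsteps, fill)
        for t, val in self.waveform:
            i = int(round(t / dt))
            if i < nsteps:
                out[i:] = val
        return out


@dataclass
class Recording:
    variable: str  # 'V' | 'Ca' | 'I_channel' | 'I_syn' | 'I_syn_ca' | 'I_clamp'
    comp: int = 0
    channel: str = ""  # for I_channel
    synapse: int = -1  # synapse list index for I_syn / I_syn_ca
    electrode: int = -1  # electrode list index for I_clamp
    sample_interval: float = 0.1  # ms

    def key(self) -> str:
        if self.variable == "V":
            return f"V[{self.comp}]"
        if self.variable == "Ca":
            return f"Ca[{self.comp}]"
        if self.variable == "I_channel":
            return f"I[{self.channel}][{self.comp}]"
        if self.variable == "I_syn":
            return f"Isyn[{self.synapse}]"
        if self.variable == "I_syn_ca":
            return f"IsynCa[{self.synapse}]"
        if self.variable == "I_clamp":
            return f"Iclamp[{self.electrode}]"
        raise ValueError(f"unknown recording variable {self.variable!r}")


@dataclass
class ProtocolResult:
    t: np.ndarray  # ms
    traces: dict  # key -> np.ndarray
    scalars: dict = field(default_factory=dict)
    dt: float = 0.025

    def __getitem__(self, key):
        return self.traces[key]


@dataclass
class CellModel:
    morphology: Morphology  # must be discretized
    channels: dict  # name -> spec
    placements: list  # of membrane.ChannelPlacement
    calcium: dict  # section label -> CalciumShellSpec
    passive: dict = field(default_factory=lambda: {k: dict(v) for k, v in PASSIVE_DEFAULTS.items()})
    synapses: list = field(default_factory=list)  # of SynapseInstance
    temperature: float = 32.0
    ref_temperature: float = 32.0
    q10: float = 3.0
    g_overrides: dict = field(default_factory=dict)  # (channel, section) -> S/cm^2
    domain_params: dict = field(default_factory=lambda: {"tau_ms": 15.0, "gain": 5.0})

    # derived compartment tables, built in __post_init__
    comp_labels: list = field(default_factory=list, repr=False)
    comp_section: list = field(default_factory=list, repr=False)
    comp_path_dist: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.reindex()

    def reindex(self):
        comps = self.morphology.all_compartments()
        if not comps:
            raise ValueError("morphology must be discretized before model assembly")
        self.comp_labels = [c.section.label for c in comps]
        self.comp_section = [c.section for c in comps]
        # parent index per compartment (Hines order = construction order)
        index = {id(c): i for i, c in enumerate(comps)}
        parent = np.full(len(comps), -1, dtype=np.int64)
        for sec in self.morphology.sections:
            for j, c in enumerate(sec.compartments):
                i = index[id(c)]
                if j > 0:
                    parent[i] = index[id(sec.compartments[j - 1])]
                elif sec.parent is not None:
                    parent[i] = index[id(_attachment_comp(sec))]
        self._comps = comps
        self._parent = parent
        # path distance from the soma center (um)
        dist = np.zeros(len(comps))
        for i, c in enumerate(comps):
            p = parent[i]
            if p < 0:
                dist[i] = 0.0
            else:
                dist[i] = dist[p] + 0.5 * (comps[p].length + c.length)
        soma0 = index[id(self.morphology.soma.compartments[0])]
        self.comp_path_dist = np.abs(dist - dist[soma0])

    def g_max(self, placement) -> float:
        return float(self.g_overrides.get((placement.channel, placement.section),
                                          placement.g_max))

    def temp_factor(self) -> float:
        return membrane.q10_factor(self.q10, self.temperature, self.ref_temperature)

    def soma_comp(self) -> int:
        comps = self.morphology.soma.compartments
        return self._comps.index(comps[len(comps) // 2])

    def comps_by_label(self, label: str) -> list:
        return [i for i, l in enumerate(self.comp_labels) if l == label]

    def copy_with(self, g_overrides: dict | None = None, **kw) -> "CellModel":
        d = dict(
            morphology=self.morphology, channels=self.channels,
            placements=self.placements, calcium=self.calcium,
            passive={k: dict(v) for k, v in self.passive.items()},
            synapses=list(self.synapses), temperature=self.temperature,
            ref_temperature=self.ref_temperature, q10=self.q10,
            g_overrides=dict(self.g_overrides),
            domain_params=dict(self.domain_params))
        if g_overrides:
            d["g_overrides"].update(g_overrides)
        d.update(kw)
        return CellModel(**d)


def _attachment_comp(sec):
    """Compartment of the parent section containing the attachment point."""
    parent = sec.parent
    pos = sec.parent_position  # 0..1 along the parent
    comps = parent.compartments
    if not comps:
        raise ValueError("parent section not discretized")
    j = min(int(pos * len(comps)), len(comps) - 1)
    return comps[j]


def build_cell(morph: Morphology, registry_config: dict | None = None,
               synapses: list | None = None, temperature: float = 32.0,
               g_overrides: dict | None = None, passive: dict | None = None) -> CellModel:
    """Assemble a CellModel from a discretized morphology and the channel
    registry (shipped defaults when ``registry_config`` is None)."""
    channels, placements, calcium, temp = membrane.load_channel_registry(registry_config)
    pas = {k: dict(v) for k, v in PASSIVE_DEFAULTS.items()}
    if passive:
        for k, v in passive.items():
            pas[k].update(v)
    cfg = registry_config if registry_config is not None else membrane.default_registry_config()
    dom = dict(cfg.get("calcium", {}).get("domain", {"tau_ms": 15.0, "gain": 5.0}))
    return CellModel(
        morphology=morph, channels=channels, placements=placements,
        calcium=calcium, passive=pas, synapses=list(synapses or []),
        temperature=temperature, ref_temperature=float(temp.get("ref_C", 32.0)),
        q10=float(temp.get("q10", 3.0)), g_overrides=dict(g_overrides or {}),
        domain_params=dom)


# ---------------------------------------------------------------------------
# Packing
# ---------------------------------------------------------------------------

class Workspace:
    """Flat-array representation of a CellModel ready for the engine."""

    def __init__(self, model: CellModel, dt: float, v_init: float):
        self.model = model
        self.dt = dt
        self.v_init = v_init
        tf = model.temp_factor()
        comps = model._comps
        n = len(comps)
        self.n = n
        self.parent = model._parent.copy()
        labels = model.comp_labels

        area = np.array([c.area for c in comps])
        self.area = area
        self.cm_nf = np.array([
            _per_label(model.passive["cm"], l) * a * 1e3
            for l, a in zip(labels, area)])
        self.gl_us = np.array([
            _per_label(model.passive["gl"], l) * a * 1e6
            for l, a in zip(labels, area)])
        self.el = np.array([_per_label(model.passive["el"], l) for l in labels])

        # axial conductances (uS): series half-compartment resistances with
        # the model's per-section Ra
        g_ax = np.zeros(n)
        for i, c in enumerate(comps):
            p = self.parent[i]
            if p < 0:
                continue
            cp = comps[p]
            ra_c = _per_label(model.passive["ra"], c.section.label)
            ra_p = _per_label(model.passive["ra"], cp.section.label)
            r = (_axial_half_mohm(ra_c, c.length / 2.0, c.diameter)
                 + _axial_half_mohm(ra_p, cp.length / 2.0, cp.diameter))
            g_ax[i] = 1.0 / r  # MOhm -> uS
        self.g_ax = g_ax

        # --- HH channels -------------------------------------------------
        vg = engine.V_GRID
        hh_comp, hh_g, hh_e, hh_ca, hh_cadest = [], [], [], [], []
        hh_gstart, hh_gcount = [], []
        hg_state, hg_def = [], []
        gd_kind, gd_exp, gd_minf, gd_efac, gd_kd, gd_hill, gd_efca = \
            [], [], [], [], [], [], []
        gate_def_ids = {}
        self.hh_index = {}  # (channel, comp) -> instance idx

        mk_comp, mk_g, mk_e, mk_ca, mk_scheme, mk_off, mk_p0 = \
            [], [], [], [], [], [], []
        mk_cadest, mk_casrc = [], []
        schemes = {}
        sc_nstates, sc_trstart, sc_trcount, sc_cwstart = [], [], [], []
        tr_from, tr_to, tr_ca_f, tr_tab, cw = [], [], [], [], []
        self.mk_index = {}

        ca_rest = next(iter(model.calcium.values())).ca_rest if model.calcium else 5e-5

        for pl in model.placements:
            spec = model.channels[pl.channel]
            gmax = model.g_max(pl)
            is_ca = 1 if spec.e_rev > 100.0 else 0  # Ca channels: E_rev 137.5
            targets = [i for i, l in enumerate(labels) if l == pl.section]
            if spec.model == "hh":
                gdefs = []
                for gi, gate in enumerate(spec.gates):
                    key = (pl.channel, gi)
                    if key not in gate_def_ids:
                        did = len(gd_kind)
                        gate_def_ids[key] = did
                        if gate.kind == "v":
                            gd_kind.append(0)
                            gd_minf.append(gate.minf(vg))
                            gd_efac.append(np.exp(-dt * tf / gate.tau(vg)))
                            gd_kd.append(1.0)
                            gd_hill.append(1.0)
                            gd_efca.append(1.0)
                        else:
                            gd_kind.append(1)
                            gd_minf.append(np.zeros(engine.NV))
                            gd_efac.append(np.zeros(engine.NV))
                            gd_kd.append(gate.kd)
                            gd_hill.append(gate.hill)
                            gd_efca.append(math.exp(-dt * tf / gate.tau_ca))
                        gd_exp.append(int(gate.exponent))
                    gdefs.append(gate_def_ids[key])
                for i in targets:
                    self.hh_index[(pl.channel, i)] = len(hh_comp)
                    hh_comp.append(i)
                    hh_g.append(gmax * area[i] * 1e6)
                    hh_e.append(spec.e_rev)
                    hh_ca.append(is_ca)
                    hh_cadest.append(1 if spec.ca_dest == "domain" else 0)
                    hh_gstart.append(len(hg_state))
                    hh_gcount.append(len(gdefs))
                    for gi, did in enumerate(gdefs):
                        gate = spec.gates[gi]
                        if gate.kind == "v":
                            m0 = float(gate.minf(v_init))
                        else:
                            m0 = float(gate.minf(0.0, ca_rest))
                        hg_state.append(m0)
                        hg_def.append(did)
            else:  # markov
                if pl.channel not in schemes:
                    sid = len(sc_nstates)
                    schemes[pl.channel] = sid
                    sc_nstates.append(len(spec.states))
                    sc_trstart.append(len(tr_from))
                    idx = {s: i for i, s in enumerate(spec.states)}
                    for frm, to, rate in spec.transitions:
                        tr_from.append(idx[frm])
                        tr_to.append(idx[to])
                        tr_ca_f.append(1 if rate.ca else 0)
                        r = rate(vg, 1.0) if rate.ca else rate(vg)
                        tr_tab.append(np.asarray(r, float) * tf)
                    sc_trcount.append(len(spec.transitions))
                    sc_cwstart.append(len(cw))
                    for s in spec.states:
                        cw.append(1.0 if s in spec.conducting else 0.0)
                sid = schemes[pl.channel]
                p_eq = spec.equilibrium(v_init, ca_rest)
                for i in targets:
                    self.mk_index[(pl.channel, i)] = len(mk_comp)
                    mk_comp.append(i)
                    mk_g.append(gmax * area[i] * 1e6)
                    mk_e.append(spec.e_rev)
                    mk_ca.append(is_ca)
                    mk_cadest.append(1 if spec.ca_dest == "domain" else 0)
                    mk_casrc.append(1 if spec.ca_source == "domain" else 0)
                    mk_scheme.append(sid)
                    mk_off.append(len(mk_p0))
                    mk_p0.extend(p_eq.tolist())

        self.hh_comp = np.array(hh_comp, dtype=np.int64)
        self.hh_g = np.array(hh_g)
        self.hh_e = np.array(hh_e)
        self.hh_ca = np.array(hh_ca, dtype=np.int64)
        self.hh_cadest = np.array(hh_cadest, dtype=np.int64)
        self.hh_gstart = np.array(hh_gstart, dtype=np.int64)
        self.hh_gcount = np.array(hh_gcount, dtype=np.int64)
        self.hg_state0 = np.array(hg_state)
        self.hg_def = np.array(hg_def, dtype=np.int64)
        self.hg_kind = np.array(gd_kind, dtype=np.int64)
        self.hg_exp = np.array(gd_exp, dtype=np.int64)
        self.hg_minf = (np.vstack(gd_minf) if gd_minf
                        else np.zeros((0, engine.NV)))
        self.hg_efac = (np.vstack(gd_efac) if gd_efac
                        else np.zeros((0, engine.NV)))
        self.hg_kd = np.array(gd_kd)
        self.hg_hill = np.array(gd_hill)
        self.hg_efca = np.array(gd_efca)

        self.mk_comp = np.array(mk_comp, dtype=np.int64)
        self.mk_g = np.array(mk_g)
        self.mk_e = np.array(mk_e)
        self.mk_ca = np.array(mk_ca, dtype=np.int64)
        self.mk_cadest = np.array(mk_cadest, dtype=np.int64)
        self.mk_casrc = np.array(mk_casrc, dtype=np.int64)
        self.mk_scheme = np.array(mk_scheme, dtype=np.int64)
        self.mk_off = np.array(mk_off, dtype=np.int64)
        self.mk_p0 = np.array(mk_p0)
        self.sc_nstates = np.array(sc_nstates, dtype=np.int64)
        self.sc_trstart = np.array(sc_trstart, dtype=np.int64)
        self.sc_trcount = np.array(sc_trcount, dtype=np.int64)
        self.sc_cwstart = np.array(sc_cwstart, dtype=np.int64)
        self.tr_from = np.array(tr_from, dtype=np.int64)
        self.tr_to = np.array(tr_to, dtype=np.int64)
        self.tr_ca = np.array(tr_ca_f, dtype=np.int64)
        self.tr_tab = (np.vstack(tr_tab) if tr_tab
                       else np.zeros((0, engine.NV)))
        self.cw = np.array(cw)

        # --- calcium shells ----------------------------------------------
        sh_btot = np.zeros(n)
        sh_kpump = np.zeros(n)
        sh_ifac = np.zeros(n)
        kon = koff = 0.0
        carest = ca_rest
        ca0 = np.full(n, carest)
        b0 = np.zeros(n)
        for i, l in enumerate(labels):
            spec = model.calcium.get(l)
            if spec is None:
                continue
            sh_btot[i] = spec.buffer_total
            sh_kpump[i] = spec.pump_rate_per_ms()
            sh_ifac[i] = spec.influx_factor(area[i])
            kon, koff = spec.kon, spec.koff
            st = membrane.CalciumShellState.resting(spec)
            ca0[i] = st.ca
            b0[i] = st.buf_bound
        self.sh_btot = sh_btot
        self.sh_kon = kon
        self.sh_koff = koff
        self.sh_kpump = sh_kpump
        self.sh_carest = carest
        self.sh_ifac = sh_ifac
        self.sh_ca0 = ca0
        self.sh_b0 = b0
        # Cav2.2-KCa coupling domain: fast local pool, gain x shell influx
        dom = model.domain_params
        self.dm_k = np.full(n, 1.0 / float(dom.get("tau_ms", 15.0)))
        self.dm_ifac = sh_ifac * float(dom.get("gain", 5.0))
        self.dm_ca0 = np.full(n, carest)

        # --- synapses -----------------------------------------------------
        from .synapses import RECEPTOR_KINDS, transmitter_peak_factor, tm_release
        syn_comp, syn_kind, syn_g, syn_e = [], [], [], []
        events = []  # (t, entry, weight)
        # per-kind receptor parameter tables (from the first spec seen)
        nk = 3
        kb = np.zeros(nk); ku = np.zeros(nk); kdes = np.zeros(nk)
        kres = np.zeros(nk); efr = np.ones(nk); efd = np.ones(nk)
        mg_scale = np.zeros(nk); mg_slope = np.zeros(nk)
        cafrac = np.zeros(nk); ev_amp = np.zeros(nk)
        self.syn_entry = {}  # (syn list idx, kind name) -> engine entry
        for si, syn in enumerate(model.synapses):
            rel = tm_release(syn.tm, syn.spike_times) if syn.spike_times else []
            for rec in syn.receptors:
                kidx = RECEPTOR_KINDS[rec.kind]
                entry = len(syn_comp)
                self.syn_entry[(si, rec.kind)] = entry
                syn_comp.append(syn.comp)
                syn_kind.append(kidx)
                syn_g.append(rec.g_max * 1e-6)  # pS -> uS
                syn_e.append(rec.e_rev)
                kb[kidx] = rec.kb; ku[kidx] = rec.ku
                kdes[kidx] = rec.kdes; kres[kidx] = rec.kres
                efr[kidx] = math.exp(-dt / rec.tau_r)
                efd[kidx] = math.exp(-dt / rec.tau_d)
                mg_scale[kidx] = rec.mg_mM / rec.mg_kd
                mg_slope[kidx] = rec.mg_slope
                cafrac[kidx] = rec.ca_fraction
                ev_amp[kidx] = rec.t_amp / transmitter_peak_factor(rec.tau_r, rec.tau_d)
                for t, w in zip(syn.spike_times, rel):
                    events.append((t, entry, w))
        events.sort()
        self.syn_comp = np.array(syn_comp, dtype=np.int64)
        self.syn_kind = np.array(syn_kind, dtype=np.int64)
        self.syn_g = np.array(syn_g)
        self.syn_e = np.array(syn_e)
        self.syn_kb, self.syn_ku = kb, ku
        self.syn_kdes, self.syn_kres = kdes, kres
        self.syn_efr, self.syn_efd = efr, efd
        self.syn_mg_scale, self.syn_mg_slope = mg_scale, mg_slope
        self.syn_cafrac = cafrac
        self.ev_amp = ev_amp
        self.ev_step = np.array([int(round(t / dt)) for t, _, _ in events],
                                dtype=np.int64)
        self.ev_syn = np.array([e for _, e, _ in events], dtype=np.int64)
        self.ev_w = np.array([w for _, _, w in events])

    def dense_matrix(self, dt: float | None = None) -> np.ndarray:
        """Dense (passive) implicit-update matrix, for oracle comparisons."""
        dt = dt or self.dt
        n = self.n
        a = np.zeros((n, n))
        for i in range(n):
            a[i, i] = self.cm_nf[i] / dt + self.gl_us[i]
        for i in range(1, n):
            p = self.parent[i]
            a[i, i] += self.g_ax[i]
            a[p, p] += self.g_ax[i]
            a[i, p] -= self.g_ax[i]
            a[p, i] -= self.g_ax[i]
        return a


def assemble(model: CellModel, dt: float = 0.025, v_init: float = -70.0) -> Workspace:
    """Build the solver workspace (tree-ordered system + packed channels)."""
    for i in range(1, len(model._parent)):
        if model._parent[i] < 0:
            raise ValueError(f"disconnected compartment {i}")
    return Workspace(model, dt, v_init)


# ---------------------------------------------------------------------------
# Running
# ---------------------------------------------------------------------------

def run(model: CellModel, electrodes: list | None = None,
        recordings: list | None = None, t_stop: float = 1000.0,
        v_init: float = -70.0, dt: float = 0.025,
        sample_interval: float = 0.1) -> ProtocolResult:
    """Simulate the model; deterministic given model + protocol.

    Recordings default to the somatic voltage.  Samples are taken every
    ``sample_interval`` ms (rounded to a whole number of steps).
    """
    if t_stop < 0:
        raise ValueError("t_stop must be >= 0")
    electrodes = list(electrodes or [])
    recordings = list(recordings or [Recording("V", comp=model.soma_comp(),
                                               sample_interval=sample_interval)])
    ws = assemble(model, dt=dt, v_init=v_init)
    nsteps = int(round(t_stop / dt))
    rec_every = max(1, int(round(sample_interval / dt)))

    ic = [e for e in electrodes if e.mode == "current_clamp"]
    vc = [e for e in electrodes if e.mode == "voltage_clamp"]
    ic_comp = np.array([e.comp for e in ic], dtype=np.int64)
    vc_comp = np.array([e.comp for e in vc], dtype=np.int64)
    ic_wave = (np.vstack([e.sample(nsteps, dt, 0.0) for e in ic])
               if ic else np.zeros((0, max(nsteps, 1))))
    vc_wave = (np.vstack([e.sample(nsteps, dt, v_init) for e in vc])
               if vc else np.zeros((0, max(nsteps, 1))))

    rec_kind, rec_idx, keys = [], [], []
    for r in recordings:
        if r.variable == "V":
            rec_kind.append(engine.REC_V); rec_idx.append(r.comp)
        elif r.variable == "Ca":
            rec_kind.append(engine.REC_CA); rec_idx.append(r.comp)
        elif r.variable == "I_channel":
            if (r.channel, r.comp) in ws.hh_index:
                rec_kind.append(engine.REC_HH_I)
                rec_idx.append(ws.hh_index[(r.channel, r.comp)])
            elif (r.channel, r.comp) in ws.mk_index:
                rec_kind.append(engine.REC_MK_I)
                rec_idx.append(ws.mk_index[(r.channel, r.comp)])
            else:
                raise ValueError(
                    f"no channel {r.channel!r} at compartment {r.comp}")
        elif r.variable == "I_syn":
            rec_kind.append(engine.REC_SYN_I)
            rec_idx.append(_syn_entry(ws, r.synapse))
        elif r.variable == "I_syn_ca":
            rec_kind.append(engine.REC_SYN_ICA)
            rec_idx.append(ws.syn_entry[(r.synapse, "NMDA")])
        elif r.variable == "I_clamp":
            ei = r.electrode if r.electrode >= 0 else 0
            vci = [i for i, e in enumerate(vc)]
            if ei >= len(vc):
                raise ValueError("I_clamp recording without a voltage clamp")
            rec_kind.append(engine.REC_CLAMP_I)
            rec_idx.append(ei)
        else:
            raise ValueError(f"unknown recording variable {r.variable!r}")
        keys.append(r.key())
    rec_kind = np.array(rec_kind, dtype=np.int64)
    rec_idx = np.array(rec_idx, dtype=np.int64)

    nrec_rows = nsteps // rec_every
    rec_out = np.zeros((max(nrec_rows, 1), len(recordings)))

    v = np.full(ws.n, v_init)
    hg_state = ws.hg_state0.copy()
    mk_p = ws.mk_p0.copy()
    sh_ca = ws.sh_ca0.copy()
    sh_b = ws.sh_b0.copy()
    dm_ca = ws.dm_ca0.copy()

    done = engine.run_kernel(
        nsteps, dt,
        ws.parent, ws.g_ax, ws.cm_nf, ws.gl_us, ws.el, v,
        ws.hh_comp, ws.hh_g, ws.hh_e, ws.hh_ca, ws.hh_gstart, ws.hh_gcount,
        hg_state, ws.hg_def, ws.hg_kind, ws.hg_exp, ws.hg_minf, ws.hg_efac,
        ws.hg_kd, ws.hg_hill, ws.hg_efca,
        ws.mk_comp, ws.mk_g, ws.mk_e, ws.mk_ca, ws.mk_scheme, ws.mk_off, mk_p,
        ws.sc_nstates, ws.sc_trstart, ws.sc_trcount, ws.sc_cwstart,
        ws.tr_from, ws.tr_to, ws.tr_ca, ws.tr_tab, ws.cw,
        sh_ca, sh_b, ws.sh_btot, ws.sh_kon, ws.sh_koff, ws.sh_kpump,
        ws.sh_carest, ws.sh_ifac,
        dm_ca, ws.dm_k, ws.dm_ifac, ws.hh_cadest, ws.mk_cadest, ws.mk_casrc,
        ws.syn_comp, ws.syn_kind, ws.syn_g, ws.syn_e,
        ws.syn_efr, ws.syn_efd, ws.syn_kb, ws.syn_ku, ws.syn_kdes, ws.syn_kres,
        ws.syn_mg_scale, ws.syn_mg_slope, ws.syn_cafrac,
        ws.ev_step, ws.ev_syn, ws.ev_w, ws.ev_amp,
        ic_comp, ic_wave, vc_comp, vc_wave,
        rec_every, rec_kind, rec_idx, rec_out,
    )
    if done < nsteps:
        raise FloatingPointError(
            f"integration failure (non-finite voltage) at t={done * dt:.3f} ms")

    t = (np.arange(nrec_rows) + 1) * rec_every * dt
    traces = {k: rec_out[:nrec_rows, j].copy() for j, k in enumerate(keys)}
    if nsteps == 0:
        t = np.zeros(0)
        traces = {k: np.zeros(0) for k in keys}
    return ProtocolResult(t=t, traces=traces, dt=dt)


def _syn_entry(ws: Workspace, syn_index: int) -> int:
    for kind in ("AMPA", "GABA", "NMDA"):
        if (syn_index, kind) in ws.syn_entry:
            return ws.syn_entry[(syn_index, kind)]
    raise ValueError(f"synapse {syn_index} has no engine entry")


def input_resistance(model: CellModel, settle: float = 300.0,
                     step_dur: float = 100.0, dt: float = 0.025) -> float:
    """Input resistance (MOhm) from a -70 -> -80 mV somatic voltage-clamp step.

    Rin = 10 mV / steady-state current difference, the protocol used for the
    Golgi cell models.
    """
    soma = model.soma_comp()
    el = Electrode("voltage_clamp", soma,
                   [(0.0, -70.0), (settle, -80.0)])
    rec = [Recording("I_clamp", electrode=0)]
    res = run(model, [el], rec, t_stop=settle + step_dur, v_init=-70.0, dt=dt)
    i = res.traces["Iclamp[0]"]
    t = res.t
    i_pre = i[(t > settle - 10.0) & (t <= settle - 1.0)].mean()
    i_post = i[(t > settle + step_dur - 10.0) & (t <= settle + step_dur - 0.5)].mean()
    dI = i_pre - i_post  # nA; hyperpolarizing step draws negative current
    if abs(dI) < 1e-12:
        raise ArithmeticError("no steady-state current difference")
    return 10.0 / abs(dI)  # mV / nA = MOhm
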