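"""Dynamic synapses: Tsodyks-Markram presynaptic release, postsynaptic
receptor kinetics (AMPA / NMDA-NR2B / GABA-A), voltage-dependent NMDA Mg
unblock, and pathway placement rules.

Pathways follow the Golgi cell synaptic architecture: parallel fibers (PF)
on apical dendrites (one synapse per compartment at most), granule cell
ascending axons (AA) on basal dendrites (one per section), mossy fibers (MF)
on basal dendrites at least 20 um of path distance from the soma (AMPA +
NMDA), and inhibitory (INH) GABA-A synapses on both dendrite classes.

Default presynaptic parameters (release probability p, recovery and
facilitation time constants) and receptor peak conductances are the
published values: PF/AA p=0.4, tau_rec=35.1 ms, tau_fac=55 ms, AMPA 1200 pS;
MF p=0.43, tau_rec=5 ms, tau_fac=8 ms, AMPA 1200 pS + NMDA 10000 pS;
INH p=0.5, tau_rec=15 ms, tau_fac=4 ms, GABA 2600 pS (E_rev -70 mV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TMReleaseSpec",
    "ReceptorSpec",
    "PathwaySpec",
    "SynapseInstance",
    "tm_release",
    "transmitter_waveform",
    "mg_unblock",
    "receptor_step",
    "place_synapses",
    "default_pathways",
    "RECEPTOR_KINDS",
]

RECEPTOR_KINDS = {"AMPA": 0, "NMDA": 1, "GABA": 2}


@dataclass
class TMReleaseSpec:
    p: float  # initial utilization / release probability
    tau_rec: float  # ms
    tau_fac: float  # ms

    def __post_init__(self):
        if not 0 < self.p <= 1:
            raise ValueError("release probability must be in (0, 1]")
        if self.tau_rec <= 0 or self.tau_fac <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class ReceptorSpec:
    """Transmitter-driven receptor with a 3-state kinetic scheme.

    States: closed C, open O, desensitized D with transmitter-dependent
    binding C->O (rate ``kb * [T]``), unbinding O->C (``ku``),
    desensitization O->D (``kdes``) and recovery D->C (``kres``).
    The transmitter transient is a biexponential pulse of peak
    ``t_amp * released fraction`` (mM).
    """

    kind: str  # AMPA | NMDA | GABA
    g_max: float  # pS
    e_rev: float  # mV
    kb: float  # 1/(mM*ms)
    ku: float  # 1/ms
    kdes: float  # 1/ms
    kres: float  # 1/ms
    t_amp: float = 1.0  # mM transmitter peak per unit release
    tau_r: float = 0.1  # ms transmitter rise
    tau_d: float = 1.0  # ms transmitter decay
    # NMDA-only
    mg_mM: float = 1.0
    mg_kd: float = 3.57  # mM at 0 mV
    mg_slope: float = 0.073  # 1/mV
    ca_fraction: float = 0.0  # fraction of current converted to Ca influx

    def __post_init__(self):
        if self.g_max <= 0:
            raise ValueError("g_max must be positive")


@dataclass
class PathwaySpec:
    name: str  # PF | AA | MF | INH
    tm: TMReleaseSpec
    receptors: list  # of ReceptorSpec


@dataclass
class SynapseInstance:
    pathway: str
    comp: int  # compartment index in the cell model
    tm: TMReleaseSpec
    receptors: list  # of ReceptorSpec
    spike_times: list = field(default_factory=list)  # ms


# ---------------------------------------------------------------------------
# Presynaptic dynamics (event-driven closed form)
# ---------------------------------------------------------------------------

def tm_release(spec: TMReleaseSpec, spike_times) -> np.ndarray:
    """Released fraction per presynaptic spike (closed-form TM recursion).

    Facilitation decays between events, is incremented before release
    (u <- u + p*(1-u)); resources recover exponentially toward 1 after being
    depleted by the released fraction.  The first spike releases exactly p.
    """
    times = np.asarray(spike_times, float)
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("spike times must be strictly increasing")
    u = 0.0
    r = 1.0
    out = np.empty(times.size)
    for k, t in enumerate(times):
        if k > 0:
            dt = t - times[k - 1]
            u = u * math.exp(-dt / spec.tau_fac)
            r = 1.0 - (1.0 - r) * math.exp(-dt / spec.tau_rec)
        u = u + spec.p * (1.0 - u)
        out[k] = u * r
        r = r * (1.0 - u)
    return out


def transmitter_peak_factor(tau_r: float, tau_d: float) -> float:
    """Peak of exp(-t/tau_d) - exp(-t/tau_r) for unit amplitudes."""
    tp = math.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)
    return math.exp(-tp / tau_d) - math.exp(-tp / tau_r)


def transmitter_waveform(release: float, t, spec: ReceptorSpec) -> np.ndarray:
    """Transmitter concentration (mM) at times t (ms) after one event."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    pf = transmitter_peak_factor(spec.tau_r, spec.tau_d)
    return release * spec.t_amp / pf * (np.exp(-t / spec.tau_d) - np.exp(-t / spec.tau_r))


def mg_unblock(v, mg_mM: float = 1.0, kd_mM: float = 3.57,
               slope: float = 0.073) -> np.ndarray:
    """Voltage-dependent NMDA Mg-unblock fraction (monotone sigmoid of V)."""
    v = np.asarray(v, float)
    return 1.0 / (1.0 + (mg_mM / kd_mM) * np.exp(-slope * v))


def receptor_step(spec: ReceptorSpec, state, transmitter: float, v: float,
                  dt: float):
    """Advance receptor state one step; returns (state, current pA, i_ca pA).

    ``state`` is (open, desensitized).  Outward positive; for NMDA the
    conductance is scaled by Mg unblock and ``ca_fraction`` of the current is
    reported as calcium influx.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    o, d = state
    c = 1.0 - o - d
    do = spec.kb * transmitter * c - spec.ku * o - spec.kdes * o
    dd = spec.kdes * o - spec.kres * d
    o = max(o + dt * do, 0.0)
    d = max(d + dt * dd, 0.0)
    if o + d > 1.0:
        s = 1.0 / (o + d)
        o *= s
        d *= s
    # current pA = g_max(pS) * open * (V-E)(mV) * 1e-3
    unb = 1.0
    if spec.kind == "NMDA":
        unb = float(mg_unblock(v, spec.mg_mM, spec.mg_kd, spec.mg_slope))
    i_pA = spec.g_max * o * unb * (v - spec.e_rev) * 1e-3
    i_ca = spec.ca_fraction * i_pA if spec.kind == "NMDA" else 0.0
    return (o, d), i_pA, i_ca


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------

def default_pathways() -> dict:
    """Shipped pathway definitions with the published TM and G_max values."""
    # binding/unbinding rates calibrated so single-release peak currents
    # match the reported unitary EPSC/IPSC amplitudes (see methods note)
    ampa = ReceptorSpec(kind="AMPA", g_max=1200.0, e_rev=0.0,
                        kb=3.0, ku=1.2, kdes=0.6, kres=0.05,
                        tau_r=0.1, tau_d=1.0)
    nmda = ReceptorSpec(kind="NMDA", g_max=10000.0, e_rev=0.0,
                        kb=0.28, ku=0.012, kdes=0.01, kres=0.002,
                        tau_r=0.1, tau_d=1.5, ca_fraction=0.1)
    gaba = ReceptorSpec(kind="GABA", g_max=2600.0, e_rev=-70.0,
                        kb=0.45, ku=0.2, kdes=0.25, kres=0.02,
                        tau_r=0.1, tau_d=1.0)
    fac = TMReleaseSpec(p=0.4, tau_rec=35.1, tau_fac=55.0)
    return {
        "PF": PathwaySpec("PF", fac, [ampa]),
        "AA": PathwaySpec("AA", replace(fac), [replace(ampa)]),
        "MF": PathwaySpec("MF", TMReleaseSpec(p=0.43, tau_rec=5.0, tau_fac=8.0),
                          [replace(ampa), nmda]),
        "INH": PathwaySpec("INH", TMReleaseSpec(p=0.5, tau_rec=15.0, tau_fac=4.0),
                           [gaba]),
    }


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

class PlacementError(ValueError):
    pass


def place_synapses(model, counts: dict, seed: int = 0,
                   pathways: dict | None = None,
                   mf_min_distance: float = 20.0) -> list:
    """Place synapses on a cell model; deterministic for a fixed seed.

    counts: mapping pathway name -> number of synapses.
    Rules: PF -> apical compartments (at most one per compartment);
    AA -> one per basal section (middle compartment); MF -> basal
    compartments with path distance >= ``mf_min_distance`` um from the soma;
    INH -> compartments of both dendrite classes.
    """
    pw = pathways or default_pathways()
    rng = np.random.default_rng(seed)
    labels = model.comp_labels
    dist = model.comp_path_dist

    apical = [i for i, l in enumerate(labels) if l == "apical_dendrite"]
    basal = [i for i, l in enumerate(labels) if l == "basal_dendrite"]
    basal_far = [i for i in basal if dist[i] >= mf_min_distance]
    # one representative compartment per basal section (its middle)
    sec_mid = {}
    for i in basal:
        sec = model.comp_section[i]
        sec_mid.setdefault(id(sec), []).append(i)
    aa_sites = [c[len(c) // 2] for c in sec_mid.values()]

    eligible = {
        "PF": apical,
        "AA": aa_sites,
        "MF": basal_far,
        "INH": apical + basal,
    }
    replace_ok = {"PF": False, "AA": False, "MF": True, "INH": True}

    out = []
    for name in ("MF", "AA", "PF", "INH"):
        nreq = int(counts.get(name, 0))
        if nreq == 0:
            continue
        sites = eligible[name]
        if not sites or (not replace_ok[name] and nreq > len(sites)):
            raise PlacementError(
                f"{name}: requested {nreq} synapses but only {len(sites)} "
                f"eligible sites")
        if replace_ok[name]:
            chosen = rng.choice(sites, size=nreq, replace=True)
        else:
            chosen = rng.choice(sites, size=nreq, replace=False)
        spec = pw[name]
        for c in np.sort(chosen):
            out.append(SynapseInstance(pathway=name, comp=int(c), tm=spec.tm,
                                       receptors=spec.receptors))
    return out


def audit_placement(model, synapses, mf_min_distance: float = 20.0) -> None:
    """Verify placement rules; raise PlacementError on violation."""
    labels = model.comp_labels
    dist = model.comp_path_dist
    pf_seen = set()
    for s in synapses:
        lab = labels[s.comp]
        if s.pathway == "PF":
            if lab != "apical_dendrite":
                raise PlacementError("PF synapse off apical dendrites")
            if s.comp in pf_seen:
                raise PlacementError("two PF synapses in one compartment")
            pf_seen.add(s.comp)
        elif s.pathway in ("AA",):
            if lab != "basal_dendrite":
                raise PlacementError("AA synapse off basal dendrites")
        elif s.pathway == "MF":
            if lab != "basal_dendrite" or dist[s.comp] < mf_min_distance:
                raise PlacementError("MF synapse violates basal/20um rule")
        elif s.pathway == "INH":
            if lab not in ("apical_dendrite", "basal_dendrite"):
                raise PlacementError("INH synapse off dendrites")
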