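"""Stimulation/measurement battery and scalar feature extraction.

Implements the standard Golgi cell protocol set: spontaneous pacemaking,
frequency-intensity curves (2 s current steps), sag under hyperpolarizing
steps, post-hyperpolarization rebound, phase reset by a brief pulse,
resonance under repetitive current steps (1-15 Hz), synaptic threshold
counts, PSTH burst/pause analysis with excitatory/inhibitory lags, and
selective channel switch-off.

Feature definitions (used by the optimizer): spike threshold is an upward
crossing of -20 mV; AP width is measured at half height between the
crossing voltage and the peak; AHP depth is the crossing voltage minus the
post-spike minimum; ISI_CV is sd(ISI)/mean(ISI).  Features requiring >= 2
spikes are reported as None when undefined, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import solver
from .solver import CellModel, Electrode, Recording
from .synapses import place_synapses

__all__ = [
    "FeatureSet",
    "detect_spikes",
    "extract_features",
    "run_fi",
    "measure_sag",
    "measure_rebound",
    "measure_phase_reset",
    "measure_resonance",
    "synapse_threshold",
    "psth",
    "switch_off",
    "backprop_ratios",
    "spontaneous",
]

SPIKE_THRESHOLD = -20.0  # mV


@dataclass
class FeatureSet:
    spike_count: int
    mean_frequency: float | None  # Hz
    isi_cv: float | None
    ap_width: float | None  # ms
    ap_height: float | None  # mV
    ahp_depth: float | None  # mV

    NAMES = ("spike_count", "mean_frequency", "isi_cv",
             "ap_width", "ap_height", "ahp_depth")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.NAMES}


def detect_spikes(t, v, threshold: float = SPIKE_THRESHOLD) -> np.ndarray:
    """Spike peak times from upward threshold crossings (one event each)."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    up = np.flatnonzero((v[1:] > threshold) & (v[:-1] <= threshold))
    peaks = []
    for k, i in enumerate(up):
        j_end = up[k + 1] if k + 1 < len(up) else len(v)
        # peak within this suprathreshold excursion (samples after the
        # crossing sample, which itself sits at or below threshold)
        start = i + 1
        sub = v[start:j_end]
        below = np.flatnonzero(sub < threshold)
        stop = start + (below[0] if len(below) else len(sub))
        if stop <= start:
            stop = min(start + 1, len(v))
        peaks.append(t[start + int(np.argmax(v[start:stop]))])
    return np.asarray(peaks)


def extract_features(t, v, window=None, threshold: float = SPIKE_THRESHOLD) -> FeatureSet:
    """Scalar electrophysiological features of a voltage trace."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    if window is not None:
        t0, t1 = window
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
            raise ValueError("window outside trace")
        m = (t >= t0) & (t <= t1)
        t, v = t[m], v[m]
    peaks = detect_spikes(t, v, threshold)
    n = len(peaks)
    if n < 2:
        return FeatureSet(spike_count=n, mean_frequency=None, isi_cv=None,
                          ap_width=_ap_width(t, v, peaks, threshold),
                          ap_height=_ap_height(t, v, peaks),
                          ahp_depth=_ahp_depth(t, v, peaks, threshold))
    isi = np.diff(peaks)
    return FeatureSet(
        spike_count=n,
        mean_frequency=1000.0 / isi.mean(),
        isi_cv=float(isi.std() / isi.mean()),
        ap_width=_ap_width(t, v, peaks, threshold),
        ap_height=_ap_height(t, v, peaks),
        ahp_depth=_ahp_depth(t, v, peaks, threshold),
    )


def _spike_slices(t, v, peaks, pad_ms=15.0):
    for pt in peaks:
        m = (t >= pt - pad_ms) & (t <= pt + pad_ms)
        yield t[m], v[m], pt


def _ap_height(t, v, peaks):
    if not len(peaks):
        return None
    vals = []
    for ts, vs, pt in _spike_slices(t, v, peaks):
        i = int(np.argmin(np.abs(ts - pt)))
        base = vs[: max(i, 1)].min() if i > 0 else vs.min()
        vals.append(vs[i] - base)
    return float(np.mean(vals))


def _ap_width(t, v, peaks, threshold):
    if not len(peaks):
        return None
    vals = []
    for ts, vs, pt in _spike_slices(t, v, peaks, pad_ms=5.0):
        i = int(np.argmin(np.abs(ts - pt)))
        half = 0.5 * (vs[i] + threshold)
        above = vs >= half
        # width of the contiguous above-half region around the peak
        lo = i
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = i
        while hi < len(vs) - 1 and above[hi + 1]:
            hi += 1
        vals.append(ts[hi] - ts[lo])
    return float(np.mean(vals))


def _ahp_depth(t, v, peaks, threshold):
    if not len(peaks):
        return None
    vals = []
    for k, pt in enumerate(peaks):
        t_end = peaks[k + 1] if k + 1 < len(peaks) else t[-1]
        m = (t > pt) & (t <= t_end)
        if m.sum() < 2:
            continue
        vals.append(threshold - v[m].min())
    return float(np.mean(vals)) if vals else None


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def _soma_run(model: CellModel, electrodes, t_stop, **kw):
    rec = [Recording("V", comp=model.soma_comp())]
    res = solver.run(model, electrodes, rec, t_stop=t_stop, **kw)
    key = list(res.traces)[0]
    return res.t, res.traces[key]


def spontaneous(model: CellModel, t_stop: float = 3000.0,
                settle: float = 500.0) -> FeatureSet:
    """Pacemaking features from a free run (first ``settle`` ms discarded)."""
    t, v = _soma_run(model, [], t_stop)
    return extract_features(t, v, window=(settle, t_stop))


def run_fi(model: CellModel, amplitudes, step_dur: float = 2000.0,
           pre: float = 500.0) -> list:
    """Frequency-intensity curve: (amplitude nA, frequency Hz, block flag).

    Frequency is the spike count in the step window divided by its duration.
    Depolarization block is flagged when spiking ceases before the step ends.
    """
    out = []
    soma = model.soma_comp()
    for amp in amplitudes:
        if amp < 0:
            raise ValueError("f-I amplitudes must be >= 0")
        el = [Electrode("current_clamp", soma, [(pre, float(amp))])] if amp else []
        t, v = _soma_run(model, el, pre + step_dur)
        peaks = detect_spikes(t, v)
        peaks = peaks[(peaks > pre) & (peaks <= pre + step_dur)]
        freq = len(peaks) / (step_dur / 1000.0)
        blocked = bool(len(peaks) >= 2
                       and peaks[-1] < pre + step_dur - 3 * np.diff(peaks).mean()
                       and v[t > peaks[-1] + 20.0].mean() > -45.0)
        out.append((float(amp), freq, blocked))
    return out


def measure_sag(model: CellModel, amp: float = -0.2, dur: float = 1000.0,
                pre: float = 1000.0) -> float:
    """Sag depth (mV): |V_min - V_steady| during a hyperpolarizing step."""
    if amp >= 0:
        raise ValueError("sag protocol needs a negative current step")
    soma = model.soma_comp()
    el = Electrode("current_clamp", soma, [(pre, amp), (pre + dur, 0.0)])
    t, v = _soma_run(model, [el], pre + dur + 200.0)
    m = (t > pre) & (t <= pre + dur)
    if (v[m] > SPIKE_THRESHOLD).any():
        # cell still firing: sag undefined on a spiking trace
        return 0.0
    vmin = v[m].min()
    vss = v[(t > pre + dur - 200.0) & (t <= pre + dur)].mean()
    return float(max(vss - vmin, 0.0))


def measure_rebound(model: CellModel, amp: float = -0.2, dur: float = 1000.0,
                    pre: float = 1500.0, n_isi: int = 3) -> dict:
    """Rebound burst after release from a hyperpolarizing step.

    Returns baseline rate, the transient post-release rate (first ``n_isi``
    intervals), and their ratio.
    """
    soma = model.soma_comp()
    el = Electrode("current_clamp", soma, [(pre, amp), (pre + dur, 0.0)])
    t, v = _soma_run(model, [el], pre + dur + 1500.0)
    peaks = detect_spikes(t, v)
    base = np.diff(peaks[(peaks > 500.0) & (peaks < pre)])
    post = peaks[peaks > pre + dur]
    isi = np.diff(post[: n_isi + 1])
    f_base = 1000.0 / base.mean() if len(base) else 0.0
    f_reb = 1000.0 / isi.mean() if len(isi) else 0.0
    return {"baseline_hz": f_base, "rebound_hz": f_reb,
            "ratio": (f_reb / f_base) if f_base > 0 else np.inf,
            "latency_ms": float(post[0] - (pre + dur)) if len(post) else np.inf}


def measure_phase_reset(model: CellModel, pulse_amp: float = 0.2,
                        pulse_dur: float = 20.0, t_pulse: float = 2000.0) -> dict:
    """Pause after a brief depolarizing pulse during pacemaking.

    Pause = first post-pulse ISI minus the mean baseline ISI (ms).
    """
    soma = model.soma_comp()
    els = []
    if pulse_amp:
        els = [Electrode("current_clamp", soma,
                         [(t_pulse, pulse_amp), (t_pulse + pulse_dur, 0.0)])]
    t, v = _soma_run(model, els, t_pulse + 2000.0)
    peaks = detect_spikes(t, v)
    base = np.diff(peaks[(peaks > 500.0) & (peaks < t_pulse)])
    if not len(base):
        raise ValueError("phase reset undefined without baseline pacing")
    post = peaks[peaks > t_pulse + pulse_dur]
    if len(post) < 2:
        return {"pause_ms": np.inf, "baseline_isi": float(base.mean())}
    pause = (post[1] - post[0]) - base.mean()
    return {"pause_ms": float(max(pause, 0.0) if pulse_amp else 0.0),
            "baseline_isi": float(base.mean())}


def measure_resonance(model: CellModel, freqs=None, amp: float = 0.2,
                      n_cycles: int = 8) -> dict:
    """Resonance: repetition frequency maximizing intra-burst output rate.

    Repetitive half-duty current steps at 1-15 Hz; the output measure is the
    mean instantaneous spike rate within the ON phases, relative to each
    frequency's own baseline.
    """
    freqs = list(freqs) if freqs is not None else [1, 2, 3, 4, 6, 8, 10, 12, 15]
    soma = model.soma_comp()
    out = []
    for f in freqs:
        period = 1000.0 / f
        wave = [(0.0, 0.0)]
        t0 = 500.0
        for c in range(n_cycles):
            wave.append((t0 + c * period, amp))
            wave.append((t0 + c * period + period / 2.0, 0.0))
        el = Electrode("current_clamp", soma, wave)
        t, v = _soma_run(model, [el], t0 + n_cycles * period + 200.0)
        peaks = detect_spikes(t, v)
        rates = []
        for c in range(n_cycles):
            on0 = t0 + c * period
            on1 = on0 + period / 2.0
            p = peaks[(peaks >= on0) & (peaks < on1)]
            if len(p) >= 2:
                # intra-burst rate from the first interval of the onset burst
                rates.append(1000.0 / (p[1] - p[0]))
        out.append((float(f), float(np.mean(rates)) if rates else 0.0))
    best = max(out, key=lambda fr: fr[1])
    return {"curve": out, "resonance_hz": best[0]}


def switch_off(model: CellModel, channel: str, sections, block_fraction: float) -> CellModel:
    """Scale a channel's maximum conductance by (1 - block_fraction)."""
    if isinstance(sections, str):
        sections = [sections]
    overrides = {}
    for sect in sections:
        pls = [p for p in model.placements
               if p.channel == channel and p.section == sect]
        if not pls:
            raise ValueError(f"channel {channel!r} not placed in {sect!r}")
        for p in pls:
            overrides[(channel, sect)] = model.g_max(p) * (1.0 - block_fraction)
    return model.copy_with(g_overrides=overrides)


def synapse_threshold(model: CellModel, pathway: str, max_n: int = 40,
                      hold: float = -0.03, seed: int = 0,
                      window: float = 50.0) -> int:
    """Smallest synchronous synapse count eliciting >= 1 spike within the
    window (pacemaking suppressed by a small negative holding current).

    The model is deterministic, so a synapse-free control run pins down any
    residual pacemaker spikes; the stimulus is placed in a window where the
    control is silent and a response counts only if the control had none.
    Returns ``max_n + 1`` when even ``max_n`` synapses fail.
    """
    soma = model.soma_comp()
    el = Electrode("current_clamp", soma, [(0.0, hold)])
    t, v = _soma_run(model, [el], 2000.0)
    control = detect_spikes(t, v)
    t_stim = 600.0
    while ((control > t_stim - 20.0) & (control <= t_stim + window + 20.0)).any():
        t_stim += 100.0
        if t_stim > 1800.0 - window:
            raise ValueError("holding current does not suppress pacemaking")
    from .synapses import PlacementError
    for n in range(1, max_n + 1):
        try:
            syns = place_synapses(model, {pathway: n}, seed=seed)
        except PlacementError:
            return n  # capacity exhausted without a spike: report > capacity
        for s in syns:
            s.spike_times = [t_stim]
        cell = model.copy_with(synapses=syns)
        t, v = _soma_run(cell, [el], t_stim + window + 20.0)
        peaks = detect_spikes(t, v)
        if ((peaks > t_stim) & (peaks <= t_stim + window)).any():
            return n
    return max_n + 1


def psth(model: CellModel, counts: dict | None = None, n_inh: int = 0,
         ei_lag: float = 10.0, n_trials: int = 5, seed: int = 0,
         bin_ms: float = 5.0, stim_t: float = 1500.0,
         train=(5, 100.0)) -> dict:
    """Peristimulus time histogram for a short synaptic burst.

    ``counts`` defaults to the reference load of 20 MF + 20 AA + 89 PF;
    ``n_inh`` inhibitory synapses are activated ``ei_lag`` ms after the
    excitatory train onset.  Trials differ only in the placement seed.
    Returns the PSTH, burst spike count, and pause length statistics.
    """
    counts = dict(counts or {"MF": 20, "AA": 20, "PF": 89})
    n_spk, f_hz = train
    ex_times = [stim_t + i * 1000.0 / f_hz for i in range(n_spk)]
    inh_times = [t + ei_lag for t in ex_times]
    edges = np.arange(-500.0, 1000.0 + bin_ms, bin_ms)
    hist = np.zeros(len(edges) - 1)
    bursts, pauses = [], []
    for trial in range(n_trials):
        cnt = dict(counts)
        if n_inh:
            cnt["INH"] = n_inh
        syns = place_synapses(model, cnt, seed=seed + trial)
        for s in syns:
            s.spike_times = list(inh_times if s.pathway == "INH" else ex_times)
        cell = model.copy_with(synapses=syns)
        t, v = _soma_run(cell, [], stim_t + 1000.0)
        peaks = detect_spikes(t, v)
        rel = peaks - stim_t
        hist += np.histogram(rel, bins=edges)[0]
        base_isi = np.diff(peaks[(peaks > 500.0) & (peaks < stim_t)])
        base = base_isi.mean() if len(base_isi) else np.inf
        burst_win = n_spk * 1000.0 / f_hz + 20.0
        burst = rel[(rel >= 0) & (rel <= burst_win)]
        bursts.append(len(burst))
        after = rel[rel > (burst[-1] if len(burst) else 0.0)]
        if len(after):
            pauses.append(float(after[0] - (burst[-1] if len(burst) else 0.0)))
        else:
            pauses.append(np.inf)
    return {
        "edges": edges, "psth": hist / n_trials,
        "burst_spikes": float(np.mean(bursts)),
        "pause_ms": float(np.mean([p for p in pauses if np.isfinite(p)] or [np.inf])),
        "baseline_isi": float(base) if np.isfinite(base) else np.inf,
    }


def backprop_ratios(model: CellModel, t_stop: float = 1500.0) -> dict:
    """Spike amplitude in distal dendrites relative to the AIS.

    Amplitudes are measured on a spontaneous spike as peak minus the local
    voltage a few ms before the AIS spike peak.
    """
    ais = model.comps_by_label("AIS")
    if not ais:
        raise ValueError("model has no AIS")
    dist = model.comp_path_dist
    bas = model.comps_by_label("basal_dendrite")
    api = model.comps_by_label("apical_dendrite")
    bd = bas[int(np.argmax(dist[bas]))]
    ad = api[int(np.argmax(dist[api]))]
    soma = model.soma_comp()
    comps = [ais[0], soma, bd, ad]
    recs = [Recording("V", comp=c, sample_interval=0.05) for c in comps]
    res = solver.run(model, [], recs, t_stop=t_stop, sample_interval=0.05)
    t = res.t
    keys = list(res.traces)
    va = res.traces[keys[0]]
    peaks = detect_spikes(t, va)
    peaks = peaks[peaks > 500.0]
    if not len(peaks):
        raise ValueError("no spontaneous spikes for backpropagation measure")
    pk = peaks[len(peaks) // 2]
    pre = pk - 6.0
    out = {}
    names = ["AIS", "soma", "basal", "apical"]
    for name, key in zip(names, keys):
        v = res.traces[key]
        m = (t >= pre) & (t <= pk + 10.0)
        base = v[np.argmin(np.abs(t - pre))]
        out[name] = float(v[m].max() - base)
    out["basal_ratio"] = out["basal"] / out["AIS"]
    out["apical_ratio"] = out["apical"] / out["AIS"]
    return out
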