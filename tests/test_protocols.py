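import numpy as np
import pytest

from golgisim import protocols, solver
from golgisim.protocols import (FeatureSet, backprop_ratios, detect_spikes,
                                extract_features, measure_phase_reset,
                                measure_rebound, measure_resonance,
                                measure_sag, psth, run_fi, spontaneous,
                                switch_off, synapse_threshold)


def synth_spike_trace(peak_times, t_end=200.0, dt=0.1, width=1.0,
                      baseline=-65.0, amp=95.0):
    t = np.arange(0.0, t_end, dt)
    v = np.full_like(t, baseline)
    for pt in peak_times:
        v += amp * np.exp(-0.5 * ((t - pt) / (width / 2.355)) ** 2)
    return t, v


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 100, 0.1)
        assert len(detect_spikes(t, np.full_like(t, -70.0))) == 0

    def test_three_synthetic_spikes_recovered(self):
        peaks = [40.0, 90.0, 147.0]
        t, v = synth_spike_trace(peaks)
        st = detect_spikes(t, v)
        assert len(st) == 3
        assert np.abs(st - peaks).max() <= 0.1 + 1e-9  # within one sample

    def test_threshold_above_max_yields_none(self):
        t, v = synth_spike_trace([50.0])
        assert len(detect_spikes(t, v, threshold=100.0)) == 0


class TestExtractFeatures:
    def test_periodic_spikes_have_zero_cv(self):
        t, v = synth_spike_trace([20.0, 60.0, 100.0, 140.0, 180.0])
        fs = extract_features(t, v)
        assert fs.spike_count == 5
        assert fs.isi_cv == pytest.approx(0.0, abs=1e-9)
        assert fs.mean_frequency == pytest.approx(25.0, rel=1e-6)

    def test_isi_cv_hand_arithmetic(self):
        # ISIs {10, 20}: mean 15, population sd 5, CV = 1/3
        t, v = synth_spike_trace([50.0, 60.0, 80.0], t_end=120.0)
        fs = extract_features(t, v)
        assert fs.isi_cv == pytest.approx(1.0 / 3.0, rel=1e-6)

    def test_single_spike_leaves_rates_absent(self):
        t, v = synth_spike_trace([50.0])
        fs = extract_features(t, v)
        assert fs.spike_count == 1
        assert fs.mean_frequency is None
        assert fs.isi_cv is None

    def test_spike_count_consistent_with_detector(self, cell):
        res = solver.run(cell, [], t_stop=1500.0)
        key = list(res.traces)[0]
        fs = extract_features(res.t, res.traces[key], window=(200.0, 1500.0))
        st = detect_spikes(res.t, res.traces[key])
        st = st[(st >= 200.0) & (st <= 1500.0)]
        assert fs.spike_count == len(st)

    def test_window_outside_trace_rejected(self):
        t, v = synth_spike_trace([50.0])
        with pytest.raises(ValueError):
            extract_features(t, v, window=(0.0, 1e6))


class TestSwitchOff:
    def test_zero_block_is_identity(self, cell):
        b = switch_off(cell, "Cav2.2", ["soma"], 0.0)
        r1 = solver.run(cell, [], t_stop=300.0)
        r2 = solver.run(b, [], t_stop=300.0)
        k = list(r1.traces)[0]
        assert np.array_equal(r1.traces[k], r2.traces[k])

    def test_unknown_channel_rejected(self, cell):
        with pytest.raises(ValueError, match="not placed"):
            switch_off(cell, "Cav2.2", ["apical_dendrite"], 0.5)


class TestPacemakingBattery:
    def test_spontaneous_rate_and_regularity(self, cell):
        fs = spontaneous(cell)
        assert fs.mean_frequency is not None
        assert 2.0 <= fs.mean_frequency <= 15.0
        assert fs.isi_cv < 0.3

    def test_fi_monotone_and_near_linear(self, cell):
        pts = run_fi(cell, [0.1, 0.2, 0.3, 0.4, 0.5], step_dur=1500.0)
        freqs = [f for _, f, _ in pts]
        assert all(b >= a - 0.5 for a, b in zip(freqs, freqs[1:]))
        assert not any(blocked for *_, blocked in pts)
        amps = [a for a, *_ in pts]
        r = np.corrcoef(amps, freqs)[0, 1]
        assert r ** 2 > 0.9  # close to linear over the driven range

    def test_zero_amplitude_gives_spontaneous_rate(self, cell):
        pts = run_fi(cell, [0.0], step_dur=1500.0)
        assert pts[0][1] > 0


class TestSagRebound:
    def test_passive_model_shows_no_sag(self, passive_cell):
        c = passive_cell.copy_with()
        c.passive["el"] = {"*": -70.0}
        assert measure_sag(c) < 0.1

    def test_sag_in_validated_range(self, cell):
        sag = measure_sag(cell, amp=-0.2, dur=1000.0)
        assert 4.4 <= sag <= 10.0

    def test_hcn_block_abolishes_sag(self, cell):
        b = switch_off(switch_off(cell, "HCN1", ["AIS"], 1.0),
                       "HCN2", ["AIS"], 1.0)
        assert measure_sag(b) < 0.5

    def test_rebound_is_transiently_accelerated(self, cell):
        r = measure_rebound(cell)
        assert r["rebound_hz"] > r["baseline_hz"]


class TestPhaseResetResonance:
    def test_no_pulse_no_pause(self, cell):
        r = measure_phase_reset(cell, pulse_amp=0.0)
        assert r["pause_ms"] == 0.0

    def test_pulse_resets_pacing(self, cell):
        r = measure_phase_reset(cell, pulse_amp=0.2, pulse_dur=20.0)
        assert np.isfinite(r["pause_ms"])
        assert r["pause_ms"] >= 0.0

    def test_resonance_peak_at_low_frequency(self, cell):
        r = measure_resonance(cell, freqs=[1, 2, 3, 4, 6, 8, 12])
        assert r["resonance_hz"] <= 4.0


class TestSynapticProtocols:
    # the reference synaptic load (20 MF + 20 AA + 89 PF) needs the full
    # surrogate's section inventory; the compact morphology uses a scaled
    # load with the same 5-impulse 100 Hz trains
    COMPACT_LOAD = {"MF": 10, "AA": 3, "PF": 20}

    def test_zero_synapses_no_spike_under_hold(self, cell):
        # a small negative holding current suppresses pacemaking almost
        # completely, leaving long silent windows for the threshold search
        el = solver.Electrode("current_clamp", cell.soma_comp(), [(0.0, -0.05)])
        res = solver.run(cell, [el], t_stop=700.0)
        key = list(res.traces)[0]
        st = detect_spikes(res.t, res.traces[key])
        assert len(st[st > 300.0]) == 0

    def test_threshold_counts_small_and_monotone(self, cell):
        n_mf = synapse_threshold(cell, "MF", max_n=15)
        n_pf = synapse_threshold(cell, "PF", max_n=30)
        assert 1 <= n_mf <= 6  # a handful of mossy fibers suffice
        assert n_pf > n_mf  # parallel fibers are individually weaker
        assert n_pf <= 30

    def test_threshold_monotonicity(self, cell):
        # if n synapses elicit a spike, n+1 do as well
        from golgisim.synapses import place_synapses
        n = synapse_threshold(cell, "MF", max_n=15)
        el = solver.Electrode("current_clamp", cell.soma_comp(), [(0.0, -0.03)])
        for count in (n, n + 1):
            syns = place_synapses(cell, {"MF": count}, seed=0)
            for s in syns:
                s.spike_times = [600.0]
            c = cell.copy_with(synapses=syns)
            res = solver.run(c, [el], t_stop=680.0)
            key = list(res.traces)[0]
            st = detect_spikes(res.t, res.traces[key])
            assert ((st > 600.0) & (st <= 650.0)).any()

    def test_psth_burst_then_pause(self, cell):
        r = psth(cell, counts=self.COMPACT_LOAD, n_trials=2, seed=0)
        assert r["burst_spikes"] >= 2.0
        assert np.isfinite(r["pause_ms"])
        assert r["pause_ms"] > 0.5 * r["baseline_isi"]

    def test_inhibition_never_helps_and_lengthens_pause(self, cell):
        counts = {"MF": 6, "PF": 10}
        ex = psth(cell, counts=counts, n_trials=2, seed=0)
        inh = psth(cell, counts=counts, n_trials=2, n_inh=20, ei_lag=10.0,
                   seed=0)
        assert inh["burst_spikes"] <= ex["burst_spikes"]
        assert inh["pause_ms"] >= ex["pause_ms"]

    def test_pause_present_across_ei_lags(self, cell):
        # a finite burst-pause pattern survives E/I lags across +/-10 ms
        # (in this calibration the pause lengthens when inhibition trails
        # the excitatory burst)
        pauses = []
        for lag in (-10.0, 0.0, 10.0):
            r = psth(cell, counts=self.COMPACT_LOAD, n_trials=1, n_inh=15,
                     ei_lag=lag, seed=0)
            pauses.append(r["pause_ms"])
        assert all(np.isfinite(p) and p > 0 for p in pauses)


class TestBackpropagation:
    def test_spike_origin_and_asymmetry(self, cell):
        r = backprop_ratios(cell)
        assert r["basal_ratio"] > r["apical_ratio"]
        assert r["apical_ratio"] <= 0.25
        assert 0.4 <= r["basal_ratio"] <= 0.95

    def test_ais_crosses_threshold_before_soma(self, cell):
        ais = cell.comps_by_label("AIS")[0]
        soma = cell.soma_comp()
        recs = [solver.Recording("V", comp=c, sample_interval=0.025)
                for c in (ais, soma)]
        res = solver.run(cell, [], recs, t_stop=1500.0, sample_interval=0.025)
        keys = list(res.traces)
        st_ais = detect_spikes(res.t, res.traces[keys[0]])
        st_soma = detect_spikes(res.t, res.traces[keys[1]])
        st_ais, st_soma = st_ais[st_ais > 400], st_soma[st_soma > 400]
        assert len(st_ais) == len(st_soma)
        # compare upward threshold-crossing sample times spike by spike
        va, vs = res.traces[keys[0]], res.traces[keys[1]]
        up_a = res.t[np.flatnonzero((va[1:] > -20) & (va[:-1] <= -20))]
        up_s = res.t[np.flatnonzero((vs[1:] > -20) & (vs[:-1] <= -20))]
        up_a, up_s = up_a[up_a > 400], up_s[up_s > 400]
        assert np.all(up_a <= up_s + 1e-9)


class TestChannelBlocks:
    def test_cav22_block_uncovers_slow_bursting(self, cell):
        from golgisim.fitting import burst_structure
        b = switch_off(cell, "Cav2.2", ["basal_dendrite", "soma", "AIS"], 0.9)
        res = solver.run(b, [], t_stop=3000.0)
        key = list(res.traces)[0]
        st = detect_spikes(res.t, res.traces[key])
        info = burst_structure(st[st > 500.0], 2500.0)
        assert info["bursting"]
        assert info["burst_rate_hz"] <= 5.5

    def test_kca22_block_matches_cav22_signature(self, cell):
        from golgisim.fitting import burst_structure
        b = switch_off(cell, "Kca2.2", ["basal_dendrite", "apical_dendrite"], 0.9)
        res = solver.run(b, [], t_stop=3000.0)
        key = list(res.traces)[0]
        st = detect_spikes(res.t, res.traces[key])
        info = burst_structure(st[st > 500.0], 2500.0)
        # same qualitative signature: clustered, slow-rhythm firing
        assert info["isi_cv"] > 0.5 or info["bursting"]
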