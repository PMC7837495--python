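# Validation thresholds for the Golgi cell model pipeline.
# Step 1: spontaneous rate and ISI regularity plus the f-I envelope
# (the experimental band is approximate; the published figure's dotted
# envelope is not printed numerically).
# Step 2: sag bounds at -0.2 nA / 1000 ms.
# Step 3: 90% Cav2.2 block must uncover slow oscillatory bursting.

rate_hz: [2.0, 15.0]
isi_cv_max: 0.3
fi_envelope:        # amplitude nA -> [lo, hi] Hz (approximate band)
  0.4: [6.0, 60.0]
  0.6: [8.0, 80.0]
fi_dur_ms: 2000.0
spont_dur_ms: 3000.0
sag_mv: [4.4, 10.0]
sag_amp_nA: -0.2
sag_dur_ms: 1000.0
block_fraction: 0.9
block_dur_ms: 3000.0
burst_rate_max_hz: 5.5
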