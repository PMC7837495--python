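# Approximate feature template for conductance optimization.
#
# The reference template comes from whole-cell Golgi cell recordings whose
# numeric feature values are not published as a table; the values below are
# documented approximations describing the response family this registry's
# kinetics produce, and are meant to be replaced by a user-supplied template
# for serious fits against recordings.
# Each entry is [mean, sd]; stimulus amplitudes in nA, 2 s steps.

step_dur_ms: 2000.0
pre_ms: 500.0
targets:
  0.2:
    mean_frequency: [14.0, 4.0]
    isi_cv: [0.05, 0.05]
    ap_height: [86.0, 10.0]
    ap_width: [0.15, 0.08]
    ahp_depth: [57.0, 8.0]
    spike_count: [28.0, 8.0]
  0.4:
    mean_frequency: [17.0, 5.0]
    isi_cv: [0.05, 0.05]
    ap_height: [88.0, 10.0]
    ap_width: [0.15, 0.08]
    ahp_depth: [56.0, 8.0]
    spike_count: [34.0, 10.0]
  0.6:
    mean_frequency: [20.0, 6.0]
    isi_cv: [0.05, 0.05]
    ap_height: [87.0, 10.0]
    ap_width: [0.15, 0.08]
    ahp_depth: [55.0, 8.0]
    spike_count: [40.0, 12.0]
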