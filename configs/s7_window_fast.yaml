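# Desk-scale bimodality window (N = 100, m = 0.05).
N: 100
m_grid: [5.0e-2]
tau_grid: {start: 1.0e-5, stop: 1.0e-1, per_decade: 5}
targets:
  - {kind: taxon, taxon_index: 1, p_focal: 1.0}
zero_threshold: 1.0e-9
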