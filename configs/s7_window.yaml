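# Bimodality window of tau for a single colonizing taxon (p_1 = 1) at
# m = 1e-3: scan for the tau-interval with a bimodal stationary law.
N: 10000
m_grid: [1.0e-3]
tau_grid: {start: 1.0e-8, stop: 1.0e-5, per_decade: 5}
targets:
  - {kind: taxon, taxon_index: 1, p_focal: 1.0}
zero_threshold: 1.0e-9
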