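# Desk-scale variant of the taxon sweep.
N: 100
m_grid: {start: 1.0e-3, stop: 1.0e-1, per_decade: 2}
tau_grid: {start: 1.0e-5, stop: 1.0e-1, per_decade: 2}
targets:
  - {kind: taxon, taxon_index: 1, p_focal: 1.0}
  - {kind: taxon, taxon_index: 1, p_focal: 0.5}
zero_threshold: 1.0e-9
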