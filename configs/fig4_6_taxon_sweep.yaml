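# Single-taxon phase maps (difference, modality, colonization probability)
# for pool frequencies 1, 0.5, 0.1.
N: 10000
m_grid: {start: 1.0e-4, stop: 1.0e-1, per_decade: 5}
tau_grid: {start: 1.0e-8, stop: 1.0e-1, per_decade: 5}
targets:
  - {kind: taxon, taxon_index: 1, p_focal: 1.0}
  - {kind: taxon, taxon_index: 1, p_focal: 0.5}
  - {kind: taxon, taxon_index: 1, p_focal: 0.1}
zero_threshold: 1.0e-9
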