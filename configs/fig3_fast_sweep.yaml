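# Desk-scale variant of the load sweep (N = 100, coarse grids).
N: 100
m_grid: {start: 1.0e-3, stop: 1.0e-1, per_decade: 2}
tau_grid: {start: 1.0e-5, stop: 1.0e-1, per_decade: 2}
targets:
  - {kind: empty_space}
alpha0_values: [0.0, -0.5]
zero_threshold: 1.0e-9
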