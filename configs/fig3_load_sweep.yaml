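# Microbial load phase maps: empty-space marginal over the (m, tau) plane,
# slow (alpha_0 = 0) and rapid (alpha_0 = -0.5) occupation of empty space.
N: 10000
m_grid: {start: 1.0e-4, stop: 1.0e-1, per_decade: 5}
tau_grid: {start: 1.0e-8, stop: 1.0e-1, per_decade: 5}
targets:
  - {kind: empty_space}
alpha0_values: [0.0, -0.5]
zero_threshold: 1.0e-9
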