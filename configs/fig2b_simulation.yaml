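# Rapid occupation of empty space. The published value of alpha_0 for this
# regime is not stated; alpha_0 = -0.9 is an illustrative rapid-occupation
# choice (alpha_0 -> -1 removes host resistance to colonization).
N: 10000
m: 0.01
tau: 0.0
p: [0.5, 0.5]
alpha: [-0.9, 0.0, 0.0]
n_hosts: 500
n_steps: 10000000
sample_every: 1000
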