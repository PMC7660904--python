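# Slow occupation of empty space (alpha_0 = 0): two neutral taxa colonize
# simultaneously. Full-scale study conditions; recording thinned to keep the
# trajectory within the memory budget.
N: 10000
m: 0.01
tau: 0.0
p: [0.5, 0.5]
alpha: [0.0, 0.0, 0.0]
n_hosts: 500
n_steps: 10000000
sample_every: 1000
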