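# Desk-scale variant of the colonization simulation (reduced N, hosts, steps).
N: 100
m: 0.01
tau: 0.0
p: [0.5, 0.5]
alpha: [0.0, 0.0, 0.0]
n_hosts: 100
n_steps: 20000
sample_every: 10
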