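# microhost

Stochastic colonization of microbe-free hosts that do not live forever.

Neutral ("Sloan-type") models of host-associated microbiomes usually assume
an effectively immortal host, so that the within-host community has time to
relax to its long-term equilibrium. Many well-studied hosts — *C. elegans*,
*D. melanogaster*, *D. rerio*, arguably newborn humans — are born
microbe-free and live for a time comparable to, or shorter than, the time
colonization takes. `microhost` implements a nearly-neutral model of this
situation and the machinery to analyse it: host lifespan enters as a
per-time-step probability τ of host death-and-replacement, which *resets*
the within-host community to the microbe-free state.

## The model

A host is `N` microbe-sized slots; `n_i` slots hold taxon `i` (`i = 1..M`),
`n_0 = N − Σ n_i` are empty, and `x_i = n_i/N`. Each time step, one of:

* **host death-birth** (probability τ): all slots empty, `x_0 → 1`;
* otherwise a uniformly chosen slot is vacated and refilled — by a migrant
  from the environmental pool of colonizers (probability `m`, taxon `i`
  proportional to its pool frequency `p_i`, with `p_0 = 0`), or by local
  reproduction (probability `1 − m`, type `j` proportional to
  `(1 + α_j) x_j`, where type 0 "reproducing" means the slot stays empty).

The per-step probabilities of the focal frequency moving by `±1/N` are

    P[x → x + 1/N] = (1 − τ)(1 − x) ( m p + (1 − m)(1 + α) x / Σ_j (1 + α_j) x_j )
    P[x → x − 1/N] = (1 − τ) x ( m (1 − p) + (1 − m)(1 − (1 + α) x / Σ_j (1 + α_j) x_j) )

plus the reset with probability τ. For a single focal type this is a
birth–death chain on `{0, 1/N, …, 1}` with *resetting* (a Markov chain with
catastrophes). The package computes:

* the exact stationary distribution `Φ[x]` of that chain (an O(N)
  flux-balance elimination; the production solver),
* the drift `a(x)` and diffusion `b²(x)` of the Fokker–Planck approximation
  with resetting, and a (deliberately second-class) stationary FP solver,
* individual-based simulations of whole multi-taxon host populations,
* summaries: the difference statistic `½ Σ_x |Φ_a − Φ_b|` between
  finite- and infinite-lifespan predictions, probabilities of
  non-colonization `Φ[0]` and full occupancy `Φ[1]`, modality
  classification (alternative microbiome states), and lifespan-weighted
  sampling of simulated trajectories,
* `(m, τ)` sweeps producing tidy phase-map tables, from a CLI.

## Worked example

A single colonizing taxon (`p₁ = 1`), scarce migration (`m = 10⁻³`),
host capacity `N = 10⁴`, and a host lifespan of ~3×10⁶ microbial events
(`τ = 3×10⁻⁷`):

```python
import numpy as np
from microhost import (
    FocalTarget, ModelParams, build_reset_chain, stationary_distribution,
    classify_modality, colonization_probabilities, total_variation,
)

N, m = 10_000, 1e-3
target = FocalTarget.taxon(1, p_focal=1.0)

def stationary(tau):
    params = ModelParams(N=N, m=m, tau=tau, p=[1.0])
    return stationary_distribution(build_reset_chain(target, params))

finite = stationary(tau=3e-7)
infinite = stationary(tau=0.0)

label = classify_modality(finite)
probs = colonization_probabilities(finite, target)
print(f"modality:        {label.category}")
for i, mass in label.maxima:
    print(f"  maximum at x = {finite.grid[i]:.4g} with mass {mass:.4g}")
print(f"P[taxon absent]: {probs.p_absent:.4f}")
print(f"P[full host]:    {probs.p_full:.4f}")
print(f"difference to infinite-lifespan model: {total_variation(finite, infinite):.4f}")
```

prints

```
modality:        bimodal_0_and_1
  maximum at x = 1 with mass 0.001206
  maximum at x = 0 with mass 0.0003332
P[taxon absent]: 0.0003
P[full host]:    0.0012
difference to infinite-lifespan model: 0.9988
```

With an infinite lifespan this taxon would end up fixed in every host
(`Φ` a point mass at `x = 1`). A finite lifespan splits the host population
into two coexisting states — microbe-free hosts and fully colonized hosts
(the distribution has maxima at both boundaries) — and the stationary law
differs from the immortal-host prediction by almost the maximal amount.
No selection is involved: migration limitation plus host turnover suffice.

The same analyses run from the shell:

```bash
microhost stationary --target taxon --p 1.0 --N 10000 --m 1e-3 --tau 3e-7 --out dist.tsv
microhost classify --dist dist.tsv
microhost sweep --config configs/fig4_6_taxon_sweep.yaml --out results/
microhost boundaries --config configs/s7_window.yaml --target taxon --p 1.0
```

`configs/` ships ready-made sweep and simulation configurations (full-scale
`N = 10⁴` versions and fast `N = 10²` variants).

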