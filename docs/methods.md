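# Methods

## Model

A host carries a fixed capacity of `N` microbe-sized slots. Slot contents
are tracked as counts `n_0..n_M` (type 0 = empty space, `Σ n_j = N`,
frequencies `x_j = n_j/N`). Time is discrete and measured in microbial
death-birth events; each step one of:

* **host death-birth**, probability `τ`: the host is replaced by a
  microbe-free newborn (`x_0 → 1`, all `x_i → 0`). Host lifespans are
  therefore geometric with mean `(1−τ)/τ` steps — the discrete counterpart
  of an exponential lifespan density, which it approaches for small `τ`.
* otherwise (probability `1−τ`), a uniformly chosen slot is vacated and
  refilled: with probability `m` by a migrant from a fixed environmental
  pool (taxon `i` w.p. `p_i`; empty space never immigrates, `p_0 = 0`),
  with probability `1−m` by "local reproduction" of type `j` with weight
  `(1+α_j) x_j` (type 0 reproducing = the slot stays empty).

`α_0` is the host's resistance to occupation of empty space (`α_0 < 0`:
empty slots fill faster); `α_i` (`i ≥ 1`) are selection coefficients, zero
in the neutral case that all population-level analyses assume. All
parameters are validated eagerly (`N ≥ 2`, `m, τ ∈ [0,1]`, `p_i ∈ [0,1]`,
`α > −1`); a full-community simulation additionally requires `Σ p_i = 1`
(a *marginal* analysis of one focal taxon does not).

### Marginal closure

The one-step probabilities of a focal type contain `Σ_j (1+α_j) x_j`. This
is a function of the focal frequency alone only in two cases, and the
marginal machinery (chain solver, diffusion coefficients) refuses anything
else rather than inventing a mean-field closure:

* **empty space** (`i = 0`): autonomous for any `α_0` provided all taxa are
  neutral, since `Σ_j (1+α_j) x_j = (1+α_0) x_0 + (1−x_0)`;
* **a taxon**: autonomous only when every `α` (including `α_0`) vanishes,
  making the sum exactly 1.

The individual-based simulator has no such restriction (arbitrary `α`).

## Stationary solver

For a focal type the dynamics is an `(N+1)`-state birth–death chain on
`{0, 1/N, …, 1}` with an added resetting flow `τ` from every state into the
reset state (index 0 for taxa; index `N` for empty space — a newborn host
is entirely empty). Including the reset state's self-loop, the one-step
matrix `R` is column-stochastic by construction; the stationary law is the
eigenvector of `R` at eigenvalue 1.

We solve for it with an O(N) *cut-flow elimination*: stationarity forces
the probability flux crossing the cut between states `{0..k}` and
`{k+1..N}` to balance, e.g. for reset-to-0 chains

    up_k π_k = down_{k+1} π_{k+1} + τ Σ_{j>k} π_j ,

a recursion solved from the top state downward (mirrored for reset-to-N).
Every term is non-negative, so the elimination involves no cancellation and
is stable across the whole regime the analyses scan (`τ` from 1 down to
1e−9 and below, `N` up to 10⁴); periodic rescaling guards against overflow
when mass ratios span hundreds of orders of magnitude. A zero denominator
(`up_k = 0` below the top) means no flux can reach the states above, whose
mass is exactly zero; the recursion restarts below — this handles `τ = 1`,
`m = 0` and `p = 0` boundaries exactly. At `τ = 0` the recursion reduces to
the detailed-balance product form of the reset-free chain.

Every solve is certified by the fixed-point residual
`max |R π − π| < 1e−12`; if certification fails (never observed on the
tested lattices) the code falls back to a sparse direct solve of
`(R − I) π = 0` with one row replaced by the normalization, clipping and
reporting any negative entries beyond 1e−10. Uniqueness requires `τ > 0`
or `m > 0`; `τ = m = 0` (both boundaries absorbing) raises an explicit
error.

`propagate` applies `R` repeatedly in O(N) per step without forming the
matrix; for `τ > 0` it contracts to the stationary law at rate ≥ `1 − τ`
per step.

### Renewal identity

Conditional on survival, the resetting chain moves with the `τ = 0`
transition probabilities, so its stationary law is exactly the
geometric-lifespan mixture of reset-free transients started from the reset
state: `Φ = Σ_t τ(1−τ)^t Q^t δ_reset`. The test suite verifies this to
TV ≤ 1e−3 at a truncation horizon of `20/τ` steps (truncated tail mass
`(1−τ)^{20/τ} ≈ e^{−20}`). The same identity dictates how simulations are
compared with the solver (below).

## Diffusion approximation

The drift `a(x)` and squared noise `b²(x)` of the Fokker–Planck equation
with resetting are exposed as closed forms; they satisfy the exact
identities `a = (p_up − p_down)/N` and `b² = (p_up + p_down)/N²` with the
discrete kernel, asserted to 1e−14 on dense grids (this is the algebraic
content of the large-`N` expansion, so the "approximation" enters only
through truncation, not through the coefficients).

The stationary FP solver discretizes the flux form
`0 = d/dx[−aΦ + ½ d/dx(b²Φ)] + τ(δ_reset − Φ)` by finite volumes: central
fluxes at cell faces, no-flux boundaries, resetting as a global sink plus a
point source in the reset cell, normalization replacing one (linearly
dependent) row. Mass is conserved by construction. This solver is
deliberately second-class: the discrete chain is the model, the FP solve is
a continuum approximation whose near-boundary layers sharpen as `τ → 0`,
where it becomes unreliable — it warns below `τ = 1e−6` and raises on NaN
or substantial negative mass instead of returning garbage. Documented
accuracy is by comparison with the master equation only (TV < 0.05 on the
tested configurations, e.g. empty-space target at `N = 10³`, `m = 0.01`,
`τ = 1e−4`).

## Individual-based simulator

Hosts are independent replicate chains (the model couples them only
through the constant pool), so the population is stepped in parallel on a
`(n_hosts, M+1)` count array. Determinism contract: each host owns a
spawned child stream of the master seed and consumes exactly three
uniforms per step (death test, vacated slot, refill draw), drawn even on
death steps — trajectories are bit-reproducible and independent of the
number of hosts simulated alongside. A scalar reference kernel
(`step_host`) implements the same draw order and is tested to reproduce
the vectorized engine exactly.

Defaults mirror the reference study conditions: 500 hosts, `N = 10⁴`, two
equally abundant pool taxa, microbe-free initial hosts, recording every 10
steps. Recording is refused above a configurable memory budget (default
512 MiB) with an explicit message. Tests and the shipped "fast" configs
use desk-scale sizes (`N` 40–200, hosts 100–2000, 2×10⁴–10⁵ steps), which
keep the full suite around half a minute while leaving every assertion's
Monte-Carlo error well inside its tolerance.

### Comparing simulations with the solver

Host mortality enters the comparison through *sampling*, not dynamics:
trajectories are simulated reset-free (`τ = 0` colonization trajectories
from microbe-free hosts), then each host is sampled at an independent
geometric lifespan (nearest recorded time), and the histogram of sampled
frequencies is compared with the resetting chain's stationary law. By the
renewal identity this sampling is exactly stationary-distributed up to
recording granularity. Sampling a trajectory that itself resets would
count host death twice (measurably so: TV ≈ 0.11 vs ≈ 0.04 at `N = 100`,
`m = 0.01`, `τ = 10⁻³`, 2000 hosts), so `sample_at_host_death` warns if
handed a `τ > 0` trajectory. The sampler warns when the recorded horizon
truncates more than 1% of the lifespan distribution; `~20/τ` recorded
steps make truncation negligible.

## Summaries

* **Difference statistic**: `½ Σ_x |Φ_a − Φ_b|` (total variation), used to
  quantify how far the finite-lifespan stationary law is from the
  infinite-lifespan (`τ = 0`) reference.
* **Colonization probabilities**: `Φ[0]` (focal taxon absent, i.e. below
  the observation limit `1/N`), `1 − Φ[0]` (present), `Φ[1]` (full
  occupancy). For the empty-space target the ends are relabelled: mass at
  `x_0 = 1` is the probability of microbe-free hosts, mass at `x_0 = 0`
  the probability of fully colonized hosts.
* **Modality** (alternative microbiome states): entries below a zero
  threshold (default 1e−9) are zeroed, then local maxima are found with a
  deterministic, tie-stable rule — a maximal run of equal values is one
  maximum at its first index iff its flanking values are strictly smaller
  (boundary runs need only one flank); zero-valued runs never count. The
  label records whether the (at most two) maxima sit at `x = 0`, `x = 1`
  or inside. More than two surviving maxima fall outside the taxonomy; the
  two largest are kept and the result flagged `truncated`. The exact
  maxima rule is a design choice (plateaus and strictness are not forced
  by the model); the classification boundaries in `(m, τ)` could shift
  slightly under a different rule.

## Sweeps and CLI

`run_sweep` evaluates the stationary law and all summaries on an `(m, τ)`
lattice per target (log-spaced grids, default 5 points per decade — the
original phase maps' resolution is not known, so this is a package
choice), caching the `τ = 0` reference per column; per-cell failures are
recorded in a `status` column without aborting the sweep. Output is a tidy
CSV whose header comment carries the SHA-256 of the run manifest (config +
package version + seed); re-running a config yields a byte-identical
table. `find_bimodality_boundaries` scans the `τ` grid at fixed `m` and
refines both window edges by log-bisection to a relative tolerance
(default 5%); "no bimodal cell" is an explicit empty result. The CLI
(`microhost simulate/stationary/fp-stationary/classify/compare/sweep/
boundaries`) is a thin layer over these functions; configs are flat YAML
with strict schema validation.

## Known limitations

* No joint multi-taxon master equation (state space `N^M`); only
  single-type marginals are solved exactly, under the closure above.
* The pool is constant: no environmental dynamics, no vertical
  transmission, no host–host transmission, no host population structure
  beyond instant replacement.
* The FP stationary solver is untrustworthy as `τ → 0` (see above) and is
  shipped for comparison, not production.
* The synthetic populations are idealized: every host shares identical
  `N`, `m`, `τ` and pool, and "time" abstracts all physiological detail
  into event counts. Agreement of tests on these populations validates the
  mathematics, not the fit of the model to any real microbiome dataset —
  fitting to data is out of scope.
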