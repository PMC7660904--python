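"""Individual-based simulation of a host population.

Each host is an independent replicate of the within-host chain (the model has
no host-host interaction; hosts share only the constant pool of colonizers),
so the population is simulated as ``n_hosts`` parallel chains.  Arbitrary
fitness offsets ``alpha`` are permitted here -- the closure restrictions of
the marginal solvers do not apply to the full multi-taxon kernel.

Reproducibility contract
------------------------
Every host owns a child random stream spawned from the master seed
(``numpy.random.SeedSequence.spawn``), and consumes exactly three uniform
variates per time step, in a fixed order:

1. ``u_death``: host death-birth test against ``tau``;
2. ``u_site``:  which of the ``N`` slots is vacated (by type, via counts);
3. ``u_fill``:  which type refills it (replacement distribution).

All three are drawn even on steps where the host dies, so trajectories are
bit-reproducible and adding hosts never perturbs the trajectories of
existing ones.  "Time step" is host-local: each host experiences one event
per step, and population time is the shared step counter.

Defaults mirror the study conditions of the underlying model: 500 hosts,
``N = 10^4``, two equally abundant pool taxa, initially microbe-free hosts,
and a recording cadence of one sample every 10 steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import HostState, ModelParams, replacement_distribution

__all__ = [
    "PopulationTrajectory",
    "MemoryBudgetError",
    "step_host",
    "simulate_population",
    "two_taxon_study_params",
    "trajectory_to_tidy",
    "trajectory_to_tsv",
    "trajectory_from_tsv",
]

DEFAULT_N_HOSTS = 500
DEFAULT_SAMPLE_EVERY = 10
DEFAULT_MEMORY_BUDGET = 512 * 1024**2  # bytes of recorded trajectory


class MemoryBudgetError(RuntimeError):
    """The requested recording would exceed the configured memory budget."""


def two_taxon_study_params(
    m: float, tau: float, alpha_0: float = 0.0, N: int = 10_000
) -> ModelParams:
    """The reference two-taxon configuration: ``p_1 = p_2 = 0.5``, neutral taxa."""
    return ModelParams(
        N=N, m=m, tau=tau, p=np.array([0.5, 0.5]), alpha=np.array([alpha_0, 0.0, 0.0])
    )


@dataclass(frozen=True)
class PopulationTrajectory:
    """Recorded states of every host at the sampled times.

    ``counts`` has shape ``(n_hosts, n_samples, M + 1)``; slice
    ``counts[h, t]`` is the occupancy vector ``(n_0, ..., n_M)`` of host
    ``h`` at ``sample_times[t]``.  Every recorded vector sums to ``N``.
    """

    sample_times: np.ndarray
    counts: np.ndarray
    params: ModelParams
    seed: int

    @property
    def n_hosts(self) -> int:
        return self.counts.shape[0]

    def state(self, host: int, time_index: int) -> HostState:
        return HostState(self.counts[host, time_index])

    def frequencies(self, type_index: int) -> np.ndarray:
        """Frequency of one type: array of shape (n_hosts, n_samples)."""
        return self.counts[:, :, type_index] / self.params.N


def step_host(state: HostState, params: ModelParams, rng: np.random.Generator) -> HostState:
    """Advance one host by a single time step (reference scalar kernel).

    Draws the three per-step uniforms in the documented order, so a loop of
    ``step_host`` over a host's own spawned stream reproduces that host's
    row of :func:`simulate_population` exactly.
    """
    state.check_capacity(params)
    u_death, u_site, u_fill = rng.random(3)
    if u_death < params.tau:
        return HostState.microbe_free(params.N, params.M)
    n = state.n.copy()
    cum = np.cumsum(n)
    site = int(np.searchsorted(cum, u_site * params.N, side="right"))
    repl_cum = np.cumsum(replacement_distribution(state, params))
    fill = int(np.searchsorted(repl_cum, u_fill * repl_cum[-1], side="right"))
    fill = min(fill, params.M)
    n[site] -= 1
    n[fill] += 1
    return HostState(n)


def _step_all(
    counts: np.ndarray,
    u: np.ndarray,
    params: ModelParams,
    p_full: np.ndarray,
    one_plus_alpha: np.ndarray,
) -> None:
    """Vectorized step of all hosts in place. ``u`` has shape (H, 3)."""
    N, m, tau = params.N, params.m, params.tau
    H = counts.shape[0]
    dead = u[:, 0] < tau
    cum = np.cumsum(counts, axis=1)
    site = np.argmax(u[:, 1, None] * N < cum, axis=1)
    w = one_plus_alpha[None, :] * counts  # fitness-weighted counts; /N cancels
    cw = np.cumsum(m * p_full[None, :] + (1.0 - m) * w / w.sum(axis=1, keepdims=True), axis=1)
    fill = np.argmax(u[:, 2, None] * cw[:, -1, None] < cw, axis=1)
    idx = np.arange(H)
    live = idx[~dead]
    counts[live, site[live]] -= 1
    counts[live, fill[live]] += 1
    if dead.any():
        counts[dead] = 0
        counts[dead, 0] = N


def simulate_population(
    params: ModelParams,
    n_hosts: int = DEFAULT_N_HOSTS,
    n_steps: int = 10_000,
    sample_every: int = DEFAULT_SAMPLE_EVERY,
    seed: int = 0,
    initial: HostState | None = None,
    memory_budget: int = DEFAULT_MEMORY_BUDGET,
) -> PopulationTrajectory:
    """Simulate ``n_hosts`` independent hosts for ``n_steps`` steps.

    States are recorded at every multiple of ``sample_every`` (including time
    0).  The result is deterministic given ``seed``.  ``initial`` defaults to
    the microbe-free host.  Configurations whose recorded array would exceed
    ``memory_budget`` bytes are refused with an explicit error.
    """
    params.require_community_pool()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if sample_every < 1:
        raise ValueError("sample_every must be >= 1")
    if n_hosts < 1:
        raise ValueError("n_hosts must be >= 1")
    if initial is None:
        initial = HostState.microbe_free(params.N, params.M)
    initial.check_capacity(params)

    sample_times = np.arange(0, n_steps + 1, sample_every, dtype=np.int64)
    n_rec = sample_times.size
    rec_bytes = n_hosts * n_rec * (params.M + 1) * 4
    if rec_bytes > memory_budget:
        raise MemoryBudgetError(
            f"recording {n_hosts} hosts x {n_rec} samples x {params.M + 1} types "
            f"needs {rec_bytes / 1e6:.0f} MB, exceeding the budget of "
            f"{memory_budget / 1e6:.0f} MB; increase sample_every or the budget"
        )

    streams = [
        np.random.Generator(np.random.PCG64(s))
        for s in np.random.SeedSequence(seed).spawn(n_hosts)
    ]
    counts = np.tile(initial.n.astype(np.int64), (n_hosts, 1))
    recorded = np.empty((n_hosts, n_rec, params.M + 1), dtype=np.int32)
    recorded[:, 0, :] = counts
    rec_i = 1

    p_full = params.pool_with_empty
    one_plus_alpha = 1.0 + params.alpha
    chunk = 1024
    t = 0
    while t < n_steps:
        length = min(chunk, n_steps - t)
        u = np.empty((n_hosts, length, 3))
        for h, g in enumerate(streams):
            u[h] = g.random((length, 3))
        for s in range(length):
            _step_all(counts, u[:, s, :], params, p_full, one_plus_alpha)
            t += 1
            if t % sample_every == 0:
                recorded[:, rec_i, :] = counts
                rec_i += 1
    assert rec_i == n_rec
    return PopulationTrajectory(
        sample_times=sample_times, counts=recorded, params=params, seed=int(seed)
    )


# ---------------------------------------------------------------------------
# tidy export


def trajectory_to_tidy(traj: PopulationTrajectory) -> pd.DataFrame:
    """Long-format view: columns host_id, time, type_index, count."""
    H, T, K = traj.counts.shape
    host_id = np.repeat(np.arange(H), T * K)
    time = np.tile(np.repeat(traj.sample_times, K), H)
    type_index = np.tile(np.arange(K), H * T)
    return pd.DataFrame(
        {
            "host_id": host_id,
            "time": time,
            "type_index": type_index,
            "count": traj.counts.reshape(-1),
        }
    )


def trajectory_to_tsv(traj: PopulationTrajectory, path) -> None:
    trajectory_to_tidy(traj).to_csv(path, sep="\t", index=False)


def trajectory_from_tsv(
    path, params: ModelParams | None = None, seed: int = -1
) -> PopulationTrajectory:
    """Rebuild a trajectory from its tidy TSV export.

    ``params`` cannot be recovered from the table; pass them to reattach, or
    omit to get a parameter-less container (N inferred from the counts).
    """
    df = pd.read_csv(path, sep="\t")
    hosts = np.sort(df["host_id"].unique())
    times = np.sort(df["time"].unique())
    types = np.sort(df["type_index"].unique())
    H, T, K = hosts.size, times.size, types.size
    pivot = df.sort_values(["host_id", "time", "type_index"])
    counts = pivot["count"].to_numpy().reshape(H, T, K).astype(np.int32)
    if params is None:
        N = int(counts[0, 0].sum())
        params = ModelParams(N=N, m=0.0, tau=0.0, p=np.full(K - 1, 1.0 / (K - 1)))
    return PopulationTrajectory(
        sample_times=times.astype(np.int64), counts=counts, params=params, seed=seed
    )
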