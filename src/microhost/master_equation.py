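"""Reset-augmented birth-death chain for a focal type, and its distributions.

The frequency of a single (focal) type inside one host performs a birth-death
random walk on the grid ``{0, 1/N, ..., 1}`` whose one-step up/down
probabilities come from the replacement kernel, interrupted by host
death-birth events: with probability ``tau`` per step the walk is *reset* --
to frequency 0 for a microbial taxon, to frequency 1 for empty space (a
newborn host is entirely empty).  Across a large host population the
collection of such walks has a well-defined stationary distribution even
though every individual host is perpetually in transient colonization.

The one-step transition structure is a column-stochastic ``(N+1) x (N+1)``
matrix: tridiagonal birth-death part, the stay probability on the diagonal,
plus a resetting flow ``tau`` from every state into the reset state (the
reset state resets to itself, so columns still sum to one).

The stationary distribution is computed exactly (up to rounding) by an O(N)
elimination based on probability-flux balance across each cut of the chain:
for a cut between states ``k`` and ``k+1`` the upward flux must equal the
downward flux plus the resetting flow crossing the cut.  Every term in the
recursion is non-negative, so there is no cancellation and the method is
stable for ``tau`` spanning many orders of magnitude (down to 1e-9 and
below).  A sparse direct solve of the same linear system is kept as a
fallback, cross-checked by a residual bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import (
    FocalTarget,
    ModelParams,
    marginal_step_probabilities,
)

__all__ = [
    "ResetChain",
    "MarginalDistribution",
    "NonUniqueStationaryError",
    "build_reset_chain",
    "stationary_distribution",
    "propagate",
]

_RESIDUAL_TOL = 1e-12
_CLIP_WARN = 1e-10


class NonUniqueStationaryError(ValueError):
    """The chain has absorbing boundaries and no unique stationary law."""


class GridMismatchError(ValueError):
    """Two distributions/chains live on different frequency grids."""


@dataclass(frozen=True)
class MarginalDistribution:
    """Probability mass vector over the frequency grid ``{0, 1/N, ..., 1}``."""

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if grid.shape != mass.shape or grid.ndim != 1:
            raise ValueError("grid and mass must be 1-D arrays of equal length")
        if np.any(mass < 0.0):
            raise ValueError("probability mass must be non-negative")
        if abs(mass.sum() - 1.0) > 1e-10:
            raise ValueError(f"mass must sum to 1 within 1e-10, got {mass.sum()!r}")
        grid.setflags(write=False)
        mass.setflags(write=False)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mass", mass)

    @property
    def n_states(self) -> int:
        return self.grid.size

    def mean(self) -> float:
        """Mean focal frequency under the distribution."""
        return float(self.grid @ self.mass)

    def variance(self) -> float:
        mu = self.mean()
        return float(((self.grid - mu) ** 2) @ self.mass)

    @classmethod
    def point_mass(cls, grid: np.ndarray, index: int) -> "MarginalDistribution":
        mass = np.zeros(len(grid))
        mass[index] = 1.0
        return cls(np.asarray(grid, dtype=float), mass)

    @classmethod
    def uniform(cls, grid: np.ndarray) -> "MarginalDistribution":
        g = np.asarray(grid, dtype=float)
        return cls(g, np.full(g.size, 1.0 / g.size))


@dataclass(frozen=True)
class ResetChain:
    """One-step transition structure of the focal-type chain.

    ``up[k]``/``down[k]`` are the probabilities of moving from grid state
    ``k`` one step up/down (they already carry the survival factor
    ``1 - tau``); ``tau`` is the resetting probability, flowing from every
    state into ``reset_index`` (0 for taxa, N for empty space).
    """

    grid: np.ndarray
    up: np.ndarray
    down: np.ndarray
    tau: float
    reset_index: int
    target: FocalTarget
    params: ModelParams

    @property
    def n_states(self) -> int:
        return self.grid.size

    @property
    def stay(self) -> np.ndarray:
        return 1.0 - self.tau - self.up - self.down

    def to_matrix(self) -> sp.csc_matrix:
        """The full column-stochastic matrix R (dense resetting row included)."""
        n = self.n_states
        R = sp.lil_matrix((n, n))
        R.setdiag(self.stay)
        for k in range(n - 1):
            R[k + 1, k] = self.up[k]
        for k in range(1, n):
            R[k - 1, k] = self.down[k]
        if self.tau:
            R[self.reset_index, :] = R[self.reset_index, :].toarray() + self.tau
        return R.tocsc()

    def apply(self, mass: np.ndarray) -> np.ndarray:
        """One application of R to a mass vector (O(N), no matrix built)."""
        out = self.stay * mass
        out[1:] += self.up[:-1] * mass[:-1]
        out[:-1] += self.down[1:] * mass[1:]
        if self.tau:
            out[self.reset_index] += self.tau * mass.sum()
        return out


def build_reset_chain(target: FocalTarget, params: ModelParams) -> ResetChain:
    """Assemble the ``(N+1)``-state chain for a focal type.

    Requires the marginal closure (enforced by the step-probability kernel).
    The resetting flow goes into frequency 0 for a taxon target and into
    frequency 1 (an entirely empty newborn host) for the empty-space target.
    """
    N = params.N
    grid = np.arange(N + 1) / N
    _, up, down, _ = marginal_step_probabilities(grid, target, params)
    # exact boundary zeros, immune to rounding in the vectorized formulas
    up[-1] = 0.0
    down[0] = 0.0
    reset_index = 0 if target.kind == "taxon" else N
    return ResetChain(
        grid=grid,
        up=up,
        down=down,
        tau=params.tau,
        reset_index=reset_index,
        target=target,
        params=params,
    )


def _fluxes_reset_low(up: np.ndarray, down: np.ndarray, tau: float) -> np.ndarray:
    """Cut-flow elimination when the reset state is grid index 0.

    Flux balance across the cut between ``{0..k}`` and ``{k+1..N}``::

        up[k] * pi[k] = down[k+1] * pi[k+1] + tau * sum_{j>k} pi[j]

    solved downward from ``k = N - 1`` with only positive additions.
    """
    n = up.size
    pi = np.zeros(n)
    pi[-1] = 1.0
    tail = 1.0  # running sum of pi[k+1:]
    for k in range(n - 2, -1, -1):
        num = down[k + 1] * pi[k + 1] + tau * tail
        if up[k] <= 0.0:
            if num > 0.0:
                # no upward flux can feed the states above k: they carry no mass
                pi[k + 1 :] = 0.0
                tail = 0.0
            pi[k] = 1.0
            tail += 1.0
        else:
            v = num / up[k]
            pi[k] = v
            tail += v
            if tail > 1e250:
                pi[k:] /= tail
                tail = 1.0
    return pi / pi.sum()


def _fluxes_reset_high(up: np.ndarray, down: np.ndarray, tau: float) -> np.ndarray:
    """Mirror elimination when the reset state is the top grid index."""
    n = up.size
    pi = np.zeros(n)
    pi[0] = 1.0
    head = 1.0  # running sum of pi[:k+1]
    for k in range(n - 1):
        num = up[k] * pi[k] + tau * head
        if down[k + 1] <= 0.0:
            if num > 0.0:
                pi[: k + 1] = 0.0
                head = 0.0
            pi[k + 1] = 1.0
            head += 1.0
        else:
            v = num / down[k + 1]
            pi[k + 1] = v
            head += v
            if head > 1e250:
                pi[: k + 2] /= head
                head = 1.0
    return pi / pi.sum()


def _stationary_linear_solve(chain: ResetChain) -> np.ndarray:
    """Fallback: replace one row of (R - I) by the normalization constraint."""
    n = chain.n_states
    A = sp.lil_matrix((n, n))
    A.setdiag(chain.stay - 1.0)
    for k in range(n - 1):
        A[k + 1, k] = chain.up[k]
    for k in range(1, n):
        A[k - 1, k] = chain.down[k]
    if chain.tau:
        A[chain.reset_index, :] = (
            A[chain.reset_index, :].toarray() + chain.tau
        )
    r = chain.reset_index
    A[r, :] = 1.0
    b = np.zeros(n)
    b[r] = 1.0
    pi = spla.spsolve(A.tocsc(), b)
    return pi


def stationary_distribution(chain: ResetChain) -> MarginalDistribution:
    """Stationary law of the reset chain: the eigenvector of R at eigenvalue 1.

    Uniqueness requires ``tau > 0``, or ``tau = 0`` together with ``m > 0``
    (otherwise both boundaries are absorbing and the long-run law depends on
    the start).

    The primary path is the exact cut-flow elimination; its result is
    certified by the residual bound ``max |R pi - pi| < 1e-12`` and the
    sparse direct solve is used only if certification fails.
    """
    if chain.tau == 0.0 and chain.params.m == 0.0:
        raise NonUniqueStationaryError(
            "tau = 0 and m = 0: both boundaries are absorbing, the stationary "
            "distribution is not unique"
        )
    if chain.reset_index == 0:
        pi = _fluxes_reset_low(chain.up, chain.down, chain.tau)
    else:
        pi = _fluxes_reset_high(chain.up, chain.down, chain.tau)
    resid = float(np.max(np.abs(chain.apply(pi) - pi)))
    if not np.isfinite(resid) or resid > _RESIDUAL_TOL:
        pi = _stationary_linear_solve(chain)
        neg = pi < 0.0
        if np.any(neg):
            clipped = float(-pi[neg].sum())
            if clipped > _CLIP_WARN:
                warnings.warn(
                    f"stationary solve clipped negative mass {clipped:.3e}",
                    RuntimeWarning,
                    stacklevel=2,
                )
            pi = np.where(neg, 0.0, pi)
        pi = pi / pi.sum()
        resid = float(np.max(np.abs(chain.apply(pi) - pi)))
        if not np.isfinite(resid) or resid > 1e-8:
            raise RuntimeError(
                f"stationary solve failed to certify: residual {resid:.3e}"
            )
    return MarginalDistribution(chain.grid, pi)


def propagate(
    dist: MarginalDistribution, chain: ResetChain, steps: int
) -> MarginalDistribution:
    """Evolve a distribution ``steps`` applications of the transition matrix.

    Mass is conserved to floating precision per application; for ``tau > 0``
    repeated application converges geometrically (rate at least ``1 - tau``)
    to the stationary distribution from any start.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if dist.n_states != chain.n_states or not np.array_equal(dist.grid, chain.grid):
        raise GridMismatchError("distribution and chain grids differ")
    mass = dist.mass.copy()
    for _ in range(int(steps)):
        mass = chain.apply(mass)
    # guard against slow drift of the total after very many applications
    mass = np.clip(mass, 0.0, None)
    return MarginalDistribution(chain.grid, mass / mass.sum())
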