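"""Parameters, state types and the one-step stochastic kernel.

The model describes a single host as a fixed array of ``N`` microbe-sized
slots, each either empty (type 0) or occupied by one of ``M`` microbial taxa.
In each time step one of three things happens:

* with probability ``tau`` the host dies and is replaced by a microbe-free
  newborn (all slots empty) -- a *resetting* event;
* otherwise a uniformly chosen slot is vacated and immediately refilled,
  either by a migrant drawn from the environmental pool of colonizers
  (probability ``m``, taxon ``i`` proportional to its pool frequency ``p_i``,
  with ``p_0 = 0``: empty space never immigrates), or by local reproduction
  (probability ``1 - m``, type ``j`` proportional to its fitness-weighted
  frequency ``(1 + alpha_j) x_j``, where type 0 "reproducing" means the slot
  stays empty).

``alpha_0`` tunes how strongly the host resists occupation of empty space;
``alpha_i > 0`` (``i >= 1``) promotes taxon ``i``.  The neutral case is
``alpha = 0`` everywhere.

The functions here are pure and shared by the individual-based simulator and
the marginal (single-type) chain solvers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "ModelParams",
    "HostState",
    "FocalTarget",
    "MarginalClosureError",
    "replacement_distribution",
    "marginal_step_probabilities",
    "check_marginal_closure",
]

_POOL_SUM_TOL = 1e-12


class MarginalClosureError(ValueError):
    """Raised when a single-type marginal description is not autonomous.

    The marginal dynamics of a focal taxon involves the total fitness-weighted
    frequency ``sum_j (1 + alpha_j) x_j``, which is a function of the focal
    frequency alone only when every ``alpha`` vanishes (then the sum is 1).
    The empty-space marginal is autonomous for any ``alpha_0`` provided the
    taxa themselves are neutral, because then the sum equals
    ``(1 + alpha_0) x_0 + (1 - x_0)``.  Outside these cases no closure is
    available and we refuse rather than silently approximate.
    """


@dataclass(frozen=True)
class ModelParams:
    """All scalar/vector parameters of the stochastic process.

    Parameters
    ----------
    N : int
        Host capacity: number of microbe-sized slots, ``N >= 2``.
    m : float
        Migration probability per replacement event, in ``[0, 1]``.
    tau : float
        Host death-birth probability per (microbial) time step, in ``[0, 1]``.
    p : array-like of float, shape (M,)
        Pool-of-colonizers frequencies ``p_1 .. p_M``, each in ``[0, 1]``.
        A full-community simulation requires them to sum to 1; the marginal
        (single focal type) view does not.
    alpha : array-like of float, shape (M + 1,), optional
        Fitness offsets ``alpha_0 .. alpha_M``, each ``> -1``.  ``alpha[0]``
        is the empty-space occupation resistance.  Defaults to all zeros
        (the neutral model).
    """

    N: int
    m: float
    tau: float
    p: np.ndarray
    alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.N, (int, np.integer)) or isinstance(self.N, bool):
            raise TypeError(f"N must be an integer, got {self.N!r}")
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        for name in ("m", "tau"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        p = np.atleast_1d(np.asarray(self.p, dtype=float))
        if p.ndim != 1 or p.size < 1:
            raise ValueError("p must be a non-empty 1-D vector of pool frequencies")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise ValueError(f"pool frequencies must lie in [0, 1], got {p}")
        alpha = self.alpha
        if alpha is None:
            alpha = np.zeros(p.size + 1)
        alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
        if alpha.shape != (p.size + 1,):
            raise ValueError(
                f"alpha must have length M + 1 = {p.size + 1} "
                f"(alpha_0 plus one entry per taxon), got shape {alpha.shape}"
            )
        if np.any(alpha <= -1.0):
            raise ValueError(f"all alpha entries must exceed -1, got {alpha}")
        p.setflags(write=False)
        alpha.setflags(write=False)
        object.__setattr__(self, "N", int(self.N))
        object.__setattr__(self, "m", float(self.m))
        object.__setattr__(self, "tau", float(self.tau))
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "alpha", alpha)

    @property
    def M(self) -> int:
        """Number of microbial taxa."""
        return self.p.size

    @property
    def pool_with_empty(self) -> np.ndarray:
        """Pool frequencies over types ``0..M`` with ``p_0 = 0``."""
        return np.concatenate(([0.0], self.p))

    def require_community_pool(self) -> None:
        """Validate that ``p`` is a complete community (sums to 1).

        Required for full multi-taxon simulation; the marginal view of a
        single focal taxon places no constraint on the remaining pool.
        """
        s = float(self.p.sum())
        if abs(s - 1.0) > _POOL_SUM_TOL:
            raise ValueError(
                f"full-community simulation requires sum(p) = 1 "
                f"(within {_POOL_SUM_TOL}); got sum(p) = {s!r}"
            )


@dataclass(frozen=True)
class HostState:
    """Integer occupancy counts ``n_0 .. n_M`` of one host (``n_0`` = empty slots)."""

    n: np.ndarray

    def __post_init__(self) -> None:
        n = np.atleast_1d(np.asarray(self.n))
        if n.ndim != 1 or n.size < 2:
            raise ValueError("n must be a 1-D vector (n_0, n_1, ..., n_M)")
        if not np.issubdtype(n.dtype, np.integer):
            if not np.all(n == np.floor(n)):
                raise TypeError("occupancy counts must be integers")
            n = n.astype(np.int64)
        if np.any(n < 0):
            raise ValueError(f"occupancy counts must be non-negative, got {n}")
        n = n.astype(np.int64)
        n.setflags(write=False)
        object.__setattr__(self, "n", n)

    @property
    def N(self) -> int:
        """Total capacity (sum of all counts, conserved by the dynamics)."""
        return int(self.n.sum())

    @property
    def x(self) -> np.ndarray:
        """Frequencies ``x_j = n_j / N`` over types ``0..M``."""
        return self.n / self.N

    @classmethod
    def microbe_free(cls, N: int, M: int) -> "HostState":
        """The newborn-host state: all ``N`` slots empty, ``M`` taxa absent."""
        n = np.zeros(M + 1, dtype=np.int64)
        n[0] = N
        return cls(n)

    def check_capacity(self, params: ModelParams) -> None:
        if self.n.size != params.M + 1:
            raise ValueError(
                f"state has {self.n.size - 1} taxa but params define {params.M}"
            )
        if self.N != params.N:
            raise ValueError(f"sum(n) = {self.N} does not equal N = {params.N}")


@dataclass(frozen=True)
class FocalTarget:
    """Which single type a marginal description tracks.

    ``kind = "empty_space"`` tracks the unoccupied fraction ``x_0`` (pool
    frequency fixed at 0, resetting sends ``x_0 -> 1``); ``kind = "taxon"``
    tracks one microbial taxon with pool frequency ``p_focal`` (resetting
    sends ``x_i -> 0``).
    """

    kind: Literal["empty_space", "taxon"]
    taxon_index: int | None = None
    p_focal: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("empty_space", "taxon"):
            raise ValueError(f"kind must be 'empty_space' or 'taxon', got {self.kind!r}")
        if not 0.0 <= self.p_focal <= 1.0:
            raise ValueError(f"p_focal must lie in [0, 1], got {self.p_focal}")
        if self.kind == "empty_space":
            if self.p_focal != 0.0:
                raise ValueError("the empty-space type has pool frequency 0")
        else:
            if self.taxon_index is None or int(self.taxon_index) < 1:
                raise ValueError("taxon targets need taxon_index >= 1")
            object.__setattr__(self, "taxon_index", int(self.taxon_index))

    @classmethod
    def empty_space(cls) -> "FocalTarget":
        return cls(kind="empty_space")

    @classmethod
    def taxon(cls, index: int = 1, p_focal: float = 1.0) -> "FocalTarget":
        return cls(kind="taxon", taxon_index=index, p_focal=p_focal)


def check_marginal_closure(target: FocalTarget, params: ModelParams) -> None:
    """Raise :class:`MarginalClosureError` unless the marginal is autonomous.

    Empty-space target: requires ``alpha_i = 0`` for every taxon (``alpha_0``
    free).  Taxon target: requires every ``alpha`` (including ``alpha_0``) to
    vanish.
    """
    alpha = params.alpha
    if target.kind == "taxon":
        if np.any(alpha != 0.0):
            raise MarginalClosureError(
                "marginal closure unavailable: a taxon marginal is autonomous "
                f"only when all alpha vanish (alpha_0 = ... = alpha_M = 0); got alpha = {alpha}"
            )
    else:
        if np.any(alpha[1:] != 0.0):
            raise MarginalClosureError(
                "marginal closure unavailable: the empty-space marginal is "
                f"autonomous only for neutral taxa (alpha_i = 0, i >= 1); got alpha = {alpha}"
            )


def replacement_distribution(state: HostState, params: ModelParams) -> np.ndarray:
    """Probability that a vacated slot is refilled by each type ``0..M``.

    Entry ``j`` equals ``m p_j + (1 - m) (1 + alpha_j) x_j / sum_k (1 + alpha_k) x_k``
    with ``p_0 = 0``.  The entries sum to 1.
    """
    state.check_capacity(params)
    x = state.x
    w = (1.0 + params.alpha) * x
    total = w.sum()
    # total > 0 always: counts sum to N >= 2 and every 1 + alpha > 0
    return params.m * params.pool_with_empty + (1.0 - params.m) * w / total


def marginal_step_probabilities(
    x: float | np.ndarray, target: FocalTarget, params: ModelParams
):
    """One-step event probabilities ``(p_reset, p_up, p_down, p_stay)``.

    For the focal frequency ``x`` (scalar or array in ``[0, 1]``):

    * ``p_reset = tau`` -- host death; the focal frequency jumps to 0 for a
      taxon, to 1 for empty space;
    * ``p_up``   -- the frequency increases by ``1/N``;
    * ``p_down`` -- it decreases by ``1/N``;
    * ``p_stay`` -- no change.

    Requires the marginal closure (see :func:`check_marginal_closure`); under
    it the total fitness-weighted frequency is ``1`` for a neutral taxon and
    ``(1 + alpha_0) x_0 + (1 - x_0)`` for empty space.
    """
    check_marginal_closure(target, params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    m, tau = params.m, params.tau
    surv = 1.0 - tau
    if target.kind == "taxon":
        p = target.p_focal
        up = surv * (1.0 - x) * (m * p + (1.0 - m) * x)
        down = surv * x * (m * (1.0 - p) + (1.0 - m) * (1.0 - x))
    else:
        a0 = float(params.alpha[0])
        s = (1.0 + a0) * x + (1.0 - x)
        up = surv * (1.0 - x) * (1.0 - m) * (1.0 + a0) * x / s
        down = surv * x * (m + (1.0 - m) * (1.0 - x) / s)
    reset = np.broadcast_to(np.asarray(tau, dtype=float), up.shape).copy()
    stay = 1.0 - reset - up - down
    if x.ndim == 0:
        return float(reset), float(up), float(down), float(stay)
    return reset, up, down, stay
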