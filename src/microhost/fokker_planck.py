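"""Diffusion approximation with resetting: drift/diffusion coefficients.

In the large-``N`` limit the focal-frequency chain is approximated by a
Fokker-Planck equation with resetting,

    dPhi/dt = d/dx [ -a(x) Phi + (1/2) d/dx ( b2(x) Phi ) ] + tau (delta_reset - Phi),

where the drift ``a(x)`` is the per-step first moment of the frequency
increment and ``b2(x)`` its second moment (both conditional on host
survival, which carries the factor ``1 - tau``).  Closed forms under the
marginal closure:

taxon (all alpha = 0)::

    a(x)  = (1 - tau) m (p - x) / N
    b2(x) = (1 - tau) [ m (p + x - 2 p x) + 2 (1 - m) x (1 - x) ] / N^2

empty space (alpha_i = 0 for i >= 1, any alpha_0; S = (1+alpha_0) x + 1 - x)::

    a(x)  = (1 - tau) [ -m x - (1 - m) x (1 - (1 + alpha_0) / S) ] / N
    b2(x) = (1 - tau) [  m x + (1 - m) x (1 + (1 + alpha_0)(1 - 2x) / S) ] / N^2

These coefficients satisfy the exact algebraic identities
``a = (p_up - p_down) / N`` and ``b2 = (p_up + p_down) / N^2`` with the
discrete one-step probabilities -- the property tests assert this to 1e-14.

A stationary finite-difference solver for the resetting Fokker-Planck
equation is provided for completeness but is explicitly second-class: the
discrete master-equation solver is the source of truth, and the continuum
discretization degrades as ``tau -> 0`` where the stationary law develops
near-singular boundary layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .master_equation import MarginalDistribution
from .model import FocalTarget, ModelParams, check_marginal_closure

__all__ = [
    "DiffusionCoefficients",
    "FPSolveError",
    "drift",
    "diffusion_sq",
    "coefficients",
    "stationary_fp",
]


class FPSolveError(RuntimeError):
    """The finite-difference stationary solve did not produce a usable law."""


def drift(x, target: FocalTarget, params: ModelParams):
    """Per-step expected change of the focal frequency at ``x`` (units: 1/step)."""
    check_marginal_closure(target, params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    surv = 1.0 - params.tau
    m, N = params.m, params.N
    if target.kind == "taxon":
        a = surv * m * (target.p_focal - x) / N
    else:
        a0 = float(params.alpha[0])
        s = (1.0 + a0) * x + (1.0 - x)
        a = surv * (-m * x - (1.0 - m) * x * (1.0 - (1.0 + a0) / s)) / N
    return float(a) if a.ndim == 0 else a


def diffusion_sq(x, target: FocalTarget, params: ModelParams):
    """Per-step second moment of the focal-frequency change at ``x`` (1/step)."""
    check_marginal_closure(target, params)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    surv = 1.0 - params.tau
    m, N = params.m, params.N
    if target.kind == "taxon":
        p = target.p_focal
        b2 = surv * (m * (p + x - 2.0 * p * x) + 2.0 * (1.0 - m) * x * (1.0 - x)) / N**2
    else:
        a0 = float(params.alpha[0])
        s = (1.0 + a0) * x + (1.0 - x)
        b2 = surv * (m * x + (1.0 - m) * x * (1.0 + (1.0 + a0) * (1.0 - 2.0 * x) / s)) / N**2
    return float(b2) if b2.ndim == 0 else b2


@dataclass(frozen=True)
class DiffusionCoefficients:
    """Bundle of drift/diffusion callables for a fixed target and parameters."""

    drift: Callable[[np.ndarray], np.ndarray]
    diffusion_sq: Callable[[np.ndarray], np.ndarray]
    target: FocalTarget
    params: ModelParams


def coefficients(target: FocalTarget, params: ModelParams) -> DiffusionCoefficients:
    check_marginal_closure(target, params)
    return DiffusionCoefficients(
        drift=lambda x: drift(x, target, params),
        diffusion_sq=lambda x: diffusion_sq(x, target, params),
        target=target,
        params=params,
    )


def stationary_fp(
    target: FocalTarget,
    params: ModelParams,
    grid_size: int | None = None,
    scheme: str = "flux",
) -> MarginalDistribution:
    """Stationary law of the resetting Fokker-Planck equation (fragile).

    Conservative (flux-form) central differencing with no-flux boundaries:
    node fluxes ``F = -a Phi + d/dx (b2 Phi / 2)`` are balanced per finite
    volume, the resetting term removes mass everywhere at rate ``tau`` and
    reinjects it at the reset boundary (frequency 0 for taxa, 1 for empty
    space).  Mass is conserved by construction; one row of the singular
    system is replaced by the normalization.

    Returns the *cell masses* on an equispaced grid of ``grid_size`` nodes
    (default ``N + 1``, making the result directly comparable with the
    master-equation distribution).  Accuracy is documented only by
    comparison with the master equation; for ``tau < 1e-6`` a fragility
    warning is emitted.  A solve with NaNs or substantial negative mass
    raises :class:`FPSolveError` rather than returning silent garbage.
    """
    if scheme != "flux":
        raise ValueError(f"unknown scheme {scheme!r}; available: 'flux'")
    check_marginal_closure(target, params)
    if params.tau < 1e-6:
        warnings.warn(
            "stationary_fp is fragile for tau < 1e-6 (near-singular boundary "
            "layers); prefer the master-equation solver",
            RuntimeWarning,
            stacklevel=2,
        )
    G = int(grid_size) if grid_size is not None else params.N + 1
    if G < 3:
        raise ValueError("grid_size must be >= 3")
    grid = np.linspace(0.0, 1.0, G)
    h = grid[1] - grid[0]
    w = np.full(G, h)
    w[0] = w[-1] = h / 2.0  # finite-volume cell widths (trapezoid weights)
    b2 = diffusion_sq(grid, target, params)
    mid = 0.5 * (grid[:-1] + grid[1:])
    a_mid = drift(mid, target, params)
    reset_index = 0 if target.kind == "taxon" else G - 1

    A = sp.lil_matrix((G, G))
    # face j+1/2 between nodes j, j+1:
    #   F = -a_mid (Phi_j + Phi_{j+1})/2 + (b2_{j+1} Phi_{j+1} - b2_j Phi_j)/(2h)
    cj = -a_mid / 2.0 - b2[:-1] / (2.0 * h)
    cj1 = -a_mid / 2.0 + b2[1:] / (2.0 * h)
    for j in range(G - 1):
        A[j, j] += cj[j] / w[j]
        A[j, j + 1] += cj1[j] / w[j]
        A[j + 1, j] -= cj[j] / w[j + 1]
        A[j + 1, j + 1] -= cj1[j] / w[j + 1]
    tau = params.tau
    if tau:
        # resetting: sink -tau*Phi everywhere, source tau * total mass at the
        # reset cell (delta represented as 1/w_r on its node)
        A = A.tocsr()
        A = A - tau * sp.identity(G, format="csr")
        A = A.tolil()
        A[reset_index, :] = A[reset_index, :].toarray() + tau * w / w[reset_index]
    r = reset_index
    A[r, :] = w  # normalization: integral of the density equals 1
    b = np.zeros(G)
    b[r] = 1.0
    phi = spla.spsolve(A.tocsc(), b)
    if not np.all(np.isfinite(phi)):
        raise FPSolveError("finite-difference stationary solve produced NaN/inf")
    neg_mass = float(-(w * np.clip(phi, None, 0.0)).sum())
    if neg_mass > 1e-2:
        raise FPSolveError(
            f"discretization failed: negative probability mass {neg_mass:.3e}"
        )
    mass = np.clip(w * phi, 0.0, None)
    total = mass.sum()
    if total <= 0.0:
        raise FPSolveError("discretization failed: zero total mass")
    return MarginalDistribution(grid, mass / total)
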