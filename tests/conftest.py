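"""Shared fixtures and independent oracles.

The oracles re-derive quantities from the event definitions directly (never
through the package's own solver paths) so that solver/implementation tests
compare two genuinely independent routes.
"""

from __future__ import annotations

import numpy as np
import pytest

from microhost import FocalTarget, ModelParams


def taxon_up_down(N: int, m: float, p: float, tau: float):
    """One-step up/down probabilities of a neutral taxon, written out directly.

    up(x)   = (1 - tau) (1 - x) (m p + (1 - m) x)
    down(x) = (1 - tau) x (m (1 - p) + (1 - m)(1 - x))
    """
    x = np.arange(N + 1) / N
    up = (1.0 - tau) * (1.0 - x) * (m * p + (1.0 - m) * x)
    down = (1.0 - tau) * x * (m * (1.0 - p) + (1.0 - m) * (1.0 - x))
    return up, down


def product_form_stationary(N: int, m: float, p: float) -> np.ndarray:
    """Detailed-balance solution of the reset-free (tau = 0) taxon chain.

    pi_k proportional to prod_{j<k} up_j / down_{j+1}, evaluated in log space.
    Independent of the package's elimination solver.
    """
    up, down = taxon_up_down(N, m, p, 0.0)
    log_pi = np.zeros(N + 1)
    for k in range(N):
        if up[k] == 0.0 or down[k + 1] == 0.0:
            raise ValueError("product form needs an irreducible chain")
        log_pi[k + 1] = log_pi[k] + np.log(up[k]) - np.log(down[k + 1])
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    return pi / pi.sum()


def enumerate_one_step_moments(n: np.ndarray, params: ModelParams, focal: int):
    """Exact conditional-on-survival moments of the focal frequency change.

    Enumerates every (vacated site type, refilling type) pair of the full
    multi-taxon kernel; returns (E[dx], E[dx^2]) including the survival
    factor (1 - tau).  No sampling involved.
    """
    n = np.asarray(n, dtype=float)
    N = n.sum()
    x = n / N
    w = (1.0 + params.alpha) * x
    fill = params.m * params.pool_with_empty + (1.0 - params.m) * w / w.sum()
    e1 = 0.0
    e2 = 0.0
    for site in range(len(n)):
        for repl in range(len(n)):
            dx = (int(repl == focal) - int(site == focal)) / N
            prob = x[site] * fill[repl]
            e1 += prob * dx
            e2 += prob * dx * dx
    surv = 1.0 - params.tau
    return surv * e1, surv * e2


@pytest.fixture
def small_neutral_params() -> ModelParams:
    return ModelParams(N=50, m=0.01, tau=1e-3, p=np.array([0.5]))


@pytest.fixture
def taxon_half() -> FocalTarget:
    return FocalTarget.taxon(1, 0.5)
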