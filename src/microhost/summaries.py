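"""Summary statistics and classification of within-host frequency laws.

* :func:`total_variation` -- the difference statistic used to compare the
  finite-lifespan (``tau > 0``) and infinite-lifespan (``tau = 0``) models:
  half the summed absolute difference of two mass vectors, ranging from 0
  (identical) to 1 (disjoint support).
* :func:`colonization_probabilities` -- boundary masses of a stationary law:
  probability that the focal taxon is absent (``x < 1/N``), present, or at
  full occupancy (``x > (N-1)/N``); for the empty-space target the ends are
  relabelled (empty space at 1 means a microbe-free host; at 0, a host full
  of microbes).
* :func:`classify_modality` -- the alternative-microbiome-states
  classification: locate the maxima of a mass vector after zeroing entries
  below a threshold (default 1e-9) and name the uni-/bimodal configuration.
* :func:`sample_at_host_death` -- draw, per host, a geometric lifespan and
  read the host state at (the recorded time nearest to) its death, turning a
  transient trajectory into a sample of the population-level stationary law.
* :func:`empirical_distribution` -- histogram of sampled states on the
  frequency grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .master_equation import GridMismatchError, MarginalDistribution
from .model import FocalTarget, HostState
from .simulate import PopulationTrajectory

__all__ = [
    "ModalityLabel",
    "ColonizationProbabilities",
    "total_variation",
    "colonization_probabilities",
    "classify_modality",
    "sample_at_host_death",
    "empirical_distribution",
    "DEFAULT_ZERO_THRESHOLD",
]

DEFAULT_ZERO_THRESHOLD = 1e-9

UNIMODAL_AT_0 = "unimodal_at_0"
UNIMODAL_AT_1 = "unimodal_at_1"
UNIMODAL_INTERNAL = "unimodal_internal"
BIMODAL_0_AND_1 = "bimodal_0_and_1"
BIMODAL_0_AND_INTERNAL = "bimodal_0_and_internal"
BIMODAL_INTERNAL_AND_1 = "bimodal_internal_and_1"
BIMODAL_INTERNAL_PAIR = "bimodal_internal_pair"


def total_variation(a: MarginalDistribution, b: MarginalDistribution) -> float:
    """Half the summed absolute difference between two mass vectors.

    A metric on distributions over a common grid; 0 iff the distributions
    are identical, 1 iff their supports are disjoint.
    """
    if a.n_states != b.n_states or not np.allclose(
        a.grid, b.grid, rtol=0.0, atol=1e-12
    ):
        raise GridMismatchError("total variation requires a common frequency grid")
    return float(0.5 * np.abs(a.mass - b.mass).sum())


@dataclass(frozen=True)
class ColonizationProbabilities:
    """Boundary probabilities of a focal type's stationary law.

    For a taxon target: ``p_absent`` is the chance the taxon is not observed
    in a host (``x_i < 1/N``), ``p_present = 1 - p_absent`` the colonization
    probability, ``p_full`` the chance it occupies the host entirely.  For
    the empty-space target the same fields describe *microbes as a whole*:
    ``p_absent`` is the probability of a microbe-free host (``x_0 = 1``),
    ``p_present`` that the host carries any microbe, and ``p_full`` the
    probability of full colonization (``x_0 < 1/N``).
    """

    p_absent: float
    p_present: float
    p_full: float


def colonization_probabilities(
    dist: MarginalDistribution, target: FocalTarget
) -> ColonizationProbabilities:
    lo = float(dist.mass[0])
    hi = float(dist.mass[-1])
    if target.kind == "taxon":
        return ColonizationProbabilities(
            p_absent=lo, p_present=1.0 - lo, p_full=hi
        )
    return ColonizationProbabilities(p_absent=hi, p_present=1.0 - hi, p_full=lo)


@dataclass(frozen=True)
class ModalityLabel:
    """Outcome of the modality classification.

    ``maxima`` lists the retained maxima as ``(grid_index, mass)`` pairs,
    largest first, at most two.  ``truncated`` flags the (off-taxonomy) case
    of more than two raw maxima, of which only the two largest are kept.
    """

    category: str
    maxima: tuple[tuple[int, float], ...]
    truncated: bool = False


def _plateau_maxima(v: np.ndarray) -> list[tuple[int, float]]:
    """Indices of local maxima of ``v`` with plateau handling.

    A maximal run of equal values is one maximum, reported at its first
    index, if the adjacent values on both sides (where they exist) are
    strictly smaller.  Zero-valued runs are never maxima.
    """
    out: list[tuple[int, float]] = []
    n = v.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok and v[i] > 0.0:
            out.append((i, float(v[i])))
        i = j + 1
    return out


def classify_modality(
    dist: MarginalDistribution, zero_threshold: float = DEFAULT_ZERO_THRESHOLD
) -> ModalityLabel:
    """Classify a mass vector as uni- or bimodal with boundary/internal maxima.

    Entries below ``zero_threshold`` are zeroed before the maxima search, so
    vanishing numerical tails cannot masquerade as support.  The taxonomy is
    at most bimodal; if more than two maxima survive thresholding, the two
    largest are kept and the label is flagged ``truncated``.  The
    classification is invariant to positive rescaling of the input followed
    by renormalization (thresholding applies to the normalized mass).
    """
    if zero_threshold < 0.0:
        raise ValueError("zero_threshold must be >= 0")
    v = dist.mass.copy()
    v[v < zero_threshold] = 0.0
    maxima = _plateau_maxima(v)
    if not maxima:
        # only possible if thresholding wiped everything (e.g. a very diffuse
        # law with every entry below threshold): fall back to the raw argmax
        i = int(np.argmax(dist.mass))
        maxima = [(i, float(dist.mass[i]))]
    truncated = len(maxima) > 2
    if truncated:
        warnings.warn(
            f"{len(maxima)} maxima found; keeping the two largest "
            "(multimodal beyond the bimodal taxonomy)",
            RuntimeWarning,
            stacklevel=2,
        )
    kept = sorted(maxima, key=lambda t: (-t[1], t[0]))[:2]
    last = dist.n_states - 1
    kinds = sorted(
        ("b0" if i == 0 else "b1" if i == last else "int") for i, _ in kept
    )
    if len(kept) == 1:
        category = {
            ("b0",): UNIMODAL_AT_0,
            ("b1",): UNIMODAL_AT_1,
            ("int",): UNIMODAL_INTERNAL,
        }[tuple(kinds)]
    else:
        category = {
            ("b0", "b1"): BIMODAL_0_AND_1,
            ("b0", "int"): BIMODAL_0_AND_INTERNAL,
            ("b1", "int"): BIMODAL_INTERNAL_AND_1,
            ("int", "int"): BIMODAL_INTERNAL_PAIR,
        }[tuple(kinds)]
    return ModalityLabel(
        category=category, maxima=tuple(kept), truncated=truncated
    )


def sample_at_host_death(
    trajectory: PopulationTrajectory,
    tau: float,
    seed: int,
    return_times: bool = False,
):
    """Sample each host's state at a geometrically distributed death time.

    For every host a lifespan ``t_r`` is drawn with ``P[t_r = t] =
    tau (1 - tau)^t`` (``t = 0, 1, ...``, the discrete counterpart of the
    exponential lifespan density), and the recorded state nearest in time to
    ``t_r`` is returned.

    The trajectory should be simulated *without* host death (``tau = 0`` in
    its parameters): host mortality enters through the sampling weight, not
    the dynamics.  By the renewal representation, geometric sampling of the
    reset-free colonization trajectory reproduces the stationary law of the
    resetting chain; sampling a trajectory that already resets would count
    host death twice.

    Warns if the geometric tail beyond the recorded horizon exceeds 1%
    (lifespans past the end are clamped to the final record).
    """
    if not 0.0 < tau <= 1.0:
        raise ValueError(f"tau must lie in (0, 1], got {tau}")
    if trajectory.params.tau != 0.0:
        warnings.warn(
            "trajectory was simulated with tau > 0; lifespan sampling assumes "
            "a reset-free colonization trajectory (host death would be "
            "counted twice)",
            RuntimeWarning,
            stacklevel=2,
        )
    times = trajectory.sample_times
    tail = (1.0 - tau) ** (float(times[-1]) + 1.0)
    if tail > 0.01:
        warnings.warn(
            f"trajectory horizon {times[-1]} truncates {tail:.1%} of the "
            "lifespan distribution; simulate longer (e.g. ~20/tau steps)",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    lifespans = rng.geometric(tau, size=trajectory.n_hosts) - 1
    # nearest recorded time
    pos = np.searchsorted(times, lifespans)
    pos = np.clip(pos, 0, times.size - 1)
    prev = np.clip(pos - 1, 0, times.size - 1)
    use_prev = (lifespans - times[prev]) <= (times[pos] - lifespans)
    idx = np.where(use_prev & (pos > 0), prev, pos)
    states = [
        HostState(trajectory.counts[h, idx[h]].astype(np.int64))
        for h in range(trajectory.n_hosts)
    ]
    if return_times:
        return states, lifespans
    return states


def empirical_distribution(
    states: list[HostState], target: FocalTarget
) -> MarginalDistribution:
    """Normalized histogram of focal-type frequencies on the grid ``{0..N}/N``."""
    if not states:
        raise ValueError("empty state collection")
    type_index = 0 if target.kind == "empty_space" else target.taxon_index
    N = states[0].N
    counts = np.zeros(N + 1)
    for s in states:
        if s.N != N:
            raise ValueError("states mix different capacities N")
        counts[int(s.n[type_index])] += 1
    grid = np.arange(N + 1) / N
    return MarginalDistribution(grid, counts / counts.sum())
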