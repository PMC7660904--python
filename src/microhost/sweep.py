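"""Parameter sweeps over the (m, tau) life-history plane.

A sweep evaluates, for every cell of an (m, tau) grid and every focal
target, the stationary law of the reset chain and its summaries: boundary
colonization probabilities, modality class and internal maximum location,
and the total-variation difference to the infinite-lifespan (``tau = 0``)
reference at the same migration rate.  These tables are the engine behind
phase diagrams of colonization regimes (microbe-free vs fully colonized vs
bimodal host populations).

Per-cell failures (e.g. no closure, no unique stationary law at
``tau = m = 0``) are recorded in the row's ``status`` column and the sweep
continues.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SweepConfig
from .master_equation import (
    MarginalDistribution,
    build_reset_chain,
    stationary_distribution,
)
from .model import FocalTarget, MarginalClosureError, ModelParams
from .summaries import classify_modality, colonization_probabilities, total_variation

__all__ = ["run_sweep", "find_bimodality_boundaries", "BimodalityWindow"]

logger = logging.getLogger("microhost.sweep")

_COLUMNS = [
    "m",
    "tau",
    "target_kind",
    "taxon_index",
    "p_focal",
    "alpha0",
    "status",
    "p_absent",
    "p_present",
    "p_full",
    "modality",
    "internal_max_location",
    "tv_vs_tau0",
]


def _params_for(target: FocalTarget, N: int, m: float, tau: float, alpha0: float) -> ModelParams:
    # the marginal solvers need only the focal pool frequency; a one-taxon
    # pool vector is enough to carry (N, m, tau, alpha0)
    p = np.array([target.p_focal if target.kind == "taxon" else 1.0])
    return ModelParams(N=N, m=m, tau=tau, p=p, alpha=np.array([alpha0, 0.0]))


def _stationary_for(
    target: FocalTarget, N: int, m: float, tau: float, alpha0: float
) -> MarginalDistribution:
    chain = build_reset_chain(target, _params_for(target, N, m, tau, alpha0))
    return stationary_distribution(chain)


def run_sweep(config: SweepConfig, out_dir=None) -> pd.DataFrame:
    """Evaluate stationary summaries over the full parameter lattice.

    Returns a tidy table with one row per (m, tau, target, alpha0) cell.
    If ``out_dir`` is given, writes ``sweep.csv`` (with the manifest hash as
    a header comment) and ``manifest.txt`` alongside.  Deterministic: the
    same config yields a byte-identical table.
    """
    rows = []
    for target in config.targets:
        alpha0_values = config.alpha0_values if target.kind == "empty_space" else (0.0,)
        for alpha0 in alpha0_values:
            for m in config.m_grid:
                reference = None
                ref_status = None
                try:
                    reference = _stationary_for(target, config.N, float(m), 0.0, alpha0)
                except Exception as exc:  # noqa: BLE001 - recorded per row
                    ref_status = f"reference_failed: {type(exc).__name__}"
                for tau in config.tau_grid:
                    row = {
                        "m": float(m),
                        "tau": float(tau),
                        "target_kind": target.kind,
                        "taxon_index": target.taxon_index,
                        "p_focal": target.p_focal,
                        "alpha0": float(alpha0),
                        "status": "ok",
                        "p_absent": np.nan,
                        "p_present": np.nan,
                        "p_full": np.nan,
                        "modality": "",
                        "internal_max_location": np.nan,
                        "tv_vs_tau0": np.nan,
                    }
                    try:
                        dist = _stationary_for(
                            target, config.N, float(m), float(tau), alpha0
                        )
                        probs = colonization_probabilities(dist, target)
                        label = classify_modality(dist, config.zero_threshold)
                        row["p_absent"] = probs.p_absent
                        row["p_present"] = probs.p_present
                        row["p_full"] = probs.p_full
                        row["modality"] = label.category
                        internal = [
                            dist.grid[i]
                            for i, _ in label.maxima
                            if 0 < i < dist.n_states - 1
                        ]
                        if internal:
                            row["internal_max_location"] = float(internal[0])
                        if reference is not None:
                            row["tv_vs_tau0"] = total_variation(dist, reference)
                        elif ref_status is not None:
                            row["status"] = ref_status
                    except (MarginalClosureError, ValueError, RuntimeError) as exc:
                        row["status"] = f"failed: {type(exc).__name__}: {exc}"
                        logger.warning(
                            "cell (m=%g, tau=%g, %s) failed: %s", m, tau, target.kind, exc
                        )
                    rows.append(row)
    table = pd.DataFrame(rows, columns=_COLUMNS)
    if out_dir is not None:
        _write_outputs(table, config, Path(out_dir))
    return table


def _write_outputs(table: pd.DataFrame, config: SweepConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = (
        f"microhost version: {__version__}\n"
        f"seed: {config.seed}\n"
        f"config:\n{config.canonical_text()}"
    )
    digest = hashlib.sha256(manifest.encode()).hexdigest()
    (out_dir / "manifest.txt").write_text(manifest + f"sha256: {digest}\n")
    csv_path = out_dir / "sweep.csv"
    with open(csv_path, "w") as fh:
        fh.write(f"# manifest_sha256: {digest}\n")
        table.to_csv(fh, index=False, float_format="%.17g")
    logger.info("sweep table written to %s (%d rows)", csv_path, len(table))


@dataclass(frozen=True)
class BimodalityWindow:
    """The tau-interval over which the stationary law is bimodal.

    ``found`` is False (and the edges None) when no grid cell classified as
    bimodal -- an explicit empty result, not an exception.
    """

    tau_low: float | None
    tau_high: float | None
    found: bool


def _is_bimodal(
    target: FocalTarget, N: int, m: float, tau: float, alpha0: float, zero_threshold: float
) -> bool:
    dist = _stationary_for(target, N, m, tau, alpha0)
    return classify_modality(dist, zero_threshold).category.startswith("bimodal")


def _bisect_edge(
    lo: float,
    hi: float,
    want_bimodal_high: bool,
    probe,
    rtol: float,
) -> float:
    """Log-bisection of a modality change between tau=lo and tau=hi.

    ``want_bimodal_high`` says whether the bimodal side is at ``hi``.
    Returns the bimodal-side edge at relative tolerance ``rtol``.
    """
    while hi / lo > 1.0 + rtol:
        mid = float(np.sqrt(lo * hi))
        if probe(mid) == want_bimodal_high:
            hi = mid
        else:
            lo = mid
    return hi if want_bimodal_high else lo


def find_bimodality_boundaries(
    config: SweepConfig,
    target: FocalTarget,
    alpha0: float = 0.0,
    rtol: float = 0.05,
) -> BimodalityWindow:
    """Locate the tau-window of bimodality at fixed migration rate.

    Scans ``config.tau_grid`` (which should span the candidate region with at
    least ~5 points per decade), then refines each edge by log-bisection to
    relative tolerance ``rtol``.  Requires a single-valued ``m_grid``.
    """
    if config.m_grid.size != 1:
        raise ValueError(
            "bimodality boundaries are computed at fixed m; give a single-point m_grid"
        )
    m = float(config.m_grid[0])
    taus = config.tau_grid

    def probe(tau: float) -> bool:
        return _is_bimodal(target, config.N, m, float(tau), alpha0, config.zero_threshold)

    flags = np.array([probe(t) for t in taus])
    if not flags.any():
        return BimodalityWindow(tau_low=None, tau_high=None, found=False)
    first = int(np.argmax(flags))
    last = int(len(flags) - 1 - np.argmax(flags[::-1]))
    tau_low = float(taus[first])
    tau_high = float(taus[last])
    if first > 0:
        tau_low = _bisect_edge(float(taus[first - 1]), tau_low, True, probe, rtol)
    if last < len(taus) - 1:
        tau_high = _bisect_edge(tau_high, float(taus[last + 1]), False, probe, rtol)
    return BimodalityWindow(tau_low=tau_low, tau_high=tau_high, found=True)
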