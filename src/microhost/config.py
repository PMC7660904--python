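"""Flat YAML configuration files with explicit schema validation.

Two schemas are understood: a *simulation* config (the individual-based
simulator) and a *sweep* config (an (m, tau) grid of stationary summaries).
Configs are flat key-value mappings; unknown keys are rejected with a hint,
so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import FocalTarget, ModelParams

__all__ = ["SimulationConfig", "SweepConfig", "ConfigError", "load_yaml_mapping"]


class ConfigError(ValueError):
    """A configuration file failed schema validation."""


def load_yaml_mapping(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    return raw


def _require(raw: dict, key: str, path):
    if key not in raw:
        raise ConfigError(f"{path}: missing required key {key!r}")
    return raw[key]


def _check_unknown(raw: dict, allowed: set[str], path) -> None:
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(
            f"{path}: unknown keys {sorted(unknown)}; allowed keys are {sorted(allowed)}"
        )


def config_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass(frozen=True)
class SimulationConfig:
    params: ModelParams
    n_hosts: int
    n_steps: int
    sample_every: int

    _KEYS = {"N", "m", "tau", "p", "alpha", "n_hosts", "n_steps", "sample_every"}

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = load_yaml_mapping(path)
        _check_unknown(raw, cls._KEYS, path)
        p = np.atleast_1d(np.asarray(_require(raw, "p", path), dtype=float))
        alpha = raw.get("alpha")
        if alpha is not None:
            alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
        try:
            params = ModelParams(
                N=int(_require(raw, "N", path)),
                m=float(_require(raw, "m", path)),
                tau=float(_require(raw, "tau", path)),
                p=p,
                alpha=alpha,
            )
            params.require_community_pool()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        n_hosts = int(raw.get("n_hosts", 500))
        n_steps = int(_require(raw, "n_steps", path))
        sample_every = int(raw.get("sample_every", 10))
        if n_hosts < 1 or n_steps < 1 or sample_every < 1:
            raise ConfigError(f"{path}: n_hosts, n_steps, sample_every must be >= 1")
        return cls(params=params, n_hosts=n_hosts, n_steps=n_steps, sample_every=sample_every)


def _parse_grid(values, name: str, path) -> np.ndarray:
    grid = np.atleast_1d(np.asarray(values, dtype=float))
    if grid.size == 0:
        raise ConfigError(f"{path}: {name} must be non-empty")
    if grid.size > 1 and np.any(np.diff(grid) <= 0.0):
        raise ConfigError(f"{path}: {name} must be strictly increasing")
    return grid


def _parse_targets(raw_targets, path) -> tuple[FocalTarget, ...]:
    targets = []
    for entry in raw_targets:
        if not isinstance(entry, dict) or "kind" not in entry:
            raise ConfigError(
                f"{path}: each target must be a mapping with a 'kind' key "
                "('taxon' or 'empty_space')"
            )
        kind = entry["kind"]
        if kind == "empty_space":
            targets.append(FocalTarget.empty_space())
        elif kind == "taxon":
            targets.append(
                FocalTarget.taxon(
                    index=int(entry.get("taxon_index", 1)),
                    p_focal=float(entry.get("p_focal", 1.0)),
                )
            )
        else:
            raise ConfigError(f"{path}: unknown target kind {kind!r}")
    return tuple(targets)


@dataclass(frozen=True)
class SweepConfig:
    """An (m, tau) log-grid sweep of stationary summaries.

    ``m_grid`` and ``tau_grid`` may be given explicitly or as
    ``{start, stop, per_decade}`` log-range mappings in the YAML file.
    ``alpha0_values`` applies to empty-space targets only (taxon marginals
    require full neutrality).
    """

    m_grid: np.ndarray
    tau_grid: np.ndarray
    targets: tuple[FocalTarget, ...]
    alpha0_values: tuple[float, ...]
    N: int
    zero_threshold: float
    seed: int

    _KEYS = {
        "m_grid",
        "tau_grid",
        "targets",
        "alpha0_values",
        "N",
        "zero_threshold",
        "seed",
    }

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigError("N must be >= 2")
        if not self.targets:
            raise ConfigError("at least one target is required")
        for g, name in ((self.m_grid, "m_grid"), (self.tau_grid, "tau_grid")):
            if np.any(g < 0.0) or np.any(g > 1.0):
                raise ConfigError(f"{name} values must lie in [0, 1]")

    @staticmethod
    def _grid_from_spec(spec, name: str, path) -> np.ndarray:
        if isinstance(spec, dict):
            extra = set(spec) - {"start", "stop", "per_decade"}
            if extra:
                raise ConfigError(f"{path}: {name} log-range has unknown keys {sorted(extra)}")
            start, stop = float(spec["start"]), float(spec["stop"])
            per_decade = int(spec.get("per_decade", 5))
            if not 0.0 < start < stop:
                raise ConfigError(f"{path}: {name} needs 0 < start < stop")
            n = int(round(np.log10(stop / start) * per_decade)) + 1
            return np.logspace(np.log10(start), np.log10(stop), max(n, 2))
        return _parse_grid(spec, name, path)

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        raw = load_yaml_mapping(path)
        _check_unknown(raw, cls._KEYS, path)
        return cls(
            m_grid=cls._grid_from_spec(_require(raw, "m_grid", path), "m_grid", path),
            tau_grid=cls._grid_from_spec(_require(raw, "tau_grid", path), "tau_grid", path),
            targets=_parse_targets(_require(raw, "targets", path), path),
            alpha0_values=tuple(
                float(a) for a in np.atleast_1d(raw.get("alpha0_values", [0.0]))
            ),
            N=int(_require(raw, "N", path)),
            zero_threshold=float(raw.get("zero_threshold", 1e-9)),
            seed=int(raw.get("seed", 0)),
        )

    def canonical_text(self) -> str:
        """Deterministic textual form used for the manifest hash."""
        return yaml.safe_dump(
            {
                "m_grid": [float(v) for v in self.m_grid],
                "tau_grid": [float(v) for v in self.tau_grid],
                "targets": [
                    {
                        "kind": t.kind,
                        "taxon_index": t.taxon_index,
                        "p_focal": t.p_focal,
                    }
                    for t in self.targets
                ],
                "alpha0_values": list(self.alpha0_values),
                "N": self.N,
                "zero_threshold": self.zero_threshold,
                "seed": self.seed,
            },
            sort_keys=True,
        )
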