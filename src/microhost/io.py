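"""Plain-text import/export of distributions (TSV, full double precision)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .master_equation import MarginalDistribution

__all__ = ["distribution_to_tsv", "distribution_from_tsv"]


def distribution_to_tsv(dist: MarginalDistribution, path) -> None:
    """Write columns (state_index, frequency, mass) at full double precision."""
    df = pd.DataFrame(
        {
            "state_index": np.arange(dist.n_states),
            "frequency": dist.grid,
            "mass": dist.mass,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def distribution_from_tsv(path) -> MarginalDistribution:
    df = pd.read_csv(path, sep="\t")
    for col in ("frequency", "mass"):
        if col not in df.columns:
            raise ValueError(f"distribution TSV lacks required column {col!r}")
    return MarginalDistribution(
        df["frequency"].to_numpy(float), df["mass"].to_numpy(float)
    )
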