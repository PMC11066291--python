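"""AIC selection among candidate phylogenetic-network fits.

Network searches (maximum pseudo-likelihood with a fixed number of
reticulations) are consumed here as fitted-model summaries — log
pseudo-likelihood, mean branch-length parameter count, reticulation count —
and compared by ``AIC = 2k − 2·lnL``.

Two conventions for ``k`` are exposed. Published network-selection tables
are sometimes computed with ``k`` = the branch-length parameter count alone
even when the accompanying text defines ``k`` as branch lengths *plus*
reticulations; mode ``"branch"`` (the default) reproduces such tables
exactly, mode ``"total"`` follows the textual definition. The two differ by
exactly ``2·n_reticulations`` per model.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ModelFit", "aic", "select", "read_model_fits", "write_selection"]


@dataclass(frozen=True)
class ModelFit:
    """Summary of one fitted candidate network."""

    model_id: str
    n_reticulations: int
    lnl: float
    k_branch: float  # mean branch-length parameter count

    def __post_init__(self) -> None:
        if self.n_reticulations < 0:
            raise ValueError("n_reticulations must be >= 0")
        if self.k_branch <= 0:
            raise ValueError("k_branch must be > 0")

    @property
    def k_total(self) -> float:
        return self.k_branch + self.n_reticulations


def aic(lnl: float, k: float) -> float:
    """Akaike information criterion, ``2k − 2·lnL``."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * lnl


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def select(
    models: Sequence[ModelFit],
    k_mode: str = "branch",
    rounded: bool = False,
) -> pd.DataFrame:
    """Score models by AIC and flag the best (min AIC; ties → fewest reticulations).

    Columns: ``k``, ``aic``, ``delta_lnl`` (improvement over the model with
    one fewer reticulation, NaN where absent), ``delta_aic`` (excess over
    the best model) and ``best``. With ``rounded=True`` the delta columns
    are rounded half-up to integers, as printed selection tables usually
    are.
    """
    if not models:
        raise ValueError("no models given")
    if k_mode not in ("branch", "total"):
        raise ValueError("k_mode must be 'branch' or 'total'")
    rows = []
    by_ret = {m.n_reticulations: m for m in models}
    for m in models:
        k = m.k_branch if k_mode == "branch" else m.k_total
        prev = by_ret.get(m.n_reticulations - 1)
        dlnl = m.lnl - prev.lnl if prev is not None else np.nan
        rows.append(
            {
                "model_id": m.model_id,
                "n_reticulations": m.n_reticulations,
                "lnl": m.lnl,
                "k": k,
                "aic": aic(m.lnl, k),
                "delta_lnl": dlnl,
            }
        )
    df = pd.DataFrame(rows)
    best_aic = df["aic"].min()
    df["delta_aic"] = df["aic"] - best_aic
    best_pos = df.sort_values(["aic", "n_reticulations"]).index[0]
    df["best"] = False
    df.loc[best_pos, "best"] = True
    if rounded:
        df["delta_lnl"] = df["delta_lnl"].map(
            lambda v: np.nan if pd.isna(v) else _round_half_up(float(v))
        )
        df["delta_aic"] = df["delta_aic"].map(lambda v: _round_half_up(float(v)))
    return df


def read_model_fits(path: str | Path) -> list[ModelFit]:
    """Read a TSV with columns model_id, n_reticulations, lnL, k_branch."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    try:
        return [
            ModelFit(
                model_id=str(r[cols["model_id"]]),
                n_reticulations=int(r[cols["n_reticulations"]]),
                lnl=float(r[cols["lnl"]]),
                k_branch=float(r[cols["k_branch"]]),
            )
            for _, r in df.iterrows()
        ]
    except KeyError as exc:
        raise ValueError(f"missing column in model-fit table: {exc}") from exc


def write_selection(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
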