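"""Genome-size-scaled repeat quantification.

Read counts become genomic mass by the proportionality
``Mb = (reads_in_cluster / total_reads) × 1C``, so that cluster masses and
the unclustered remainder partition the genome exactly. Summaries: percent
repeat content per species, the top-N cluster cut used for comparative
analyses, and max/min fold ranges of genome size.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .readgraph import ClusterTable

__all__ = [
    "load_genome_sizes",
    "AbundanceMatrix",
    "cluster_mb",
    "abundance_matrix",
    "repeat_fraction",
    "top_clusters",
    "fold_range",
]


def load_genome_sizes(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (species, 1C_mb[, ploidy]) into a species-indexed frame."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    sp = cols.get("species", df.columns[0])
    c1 = cols.get("1c_mb", cols.get("c1_mb", df.columns[1]))
    out = df.rename(columns={sp: "species", c1: "c1_mb"}).set_index("species")
    if (out["c1_mb"] <= 0).any():
        raise ValueError("1C values must be > 0")
    return out


def cluster_mb(reads_cs: int, total_s: int, gs_s: float) -> float:
    """Genomic mass (Mb) of one cluster in one species."""
    if total_s <= 0:
        raise ValueError("total read count must be > 0")
    if reads_cs < 0 or reads_cs > total_s:
        raise ValueError("cluster read count must be in [0, total]")
    return (reads_cs / total_s) * gs_s


@dataclass
class AbundanceMatrix:
    """Cluster × species matrix in Mb, plus per-species remainder mass.

    ``mb`` rows sum with ``remainder_mb`` to the 1C genome size of each
    species (mass conservation); ``annot`` carries the small/plastid flags
    inherited from the cluster table.
    """

    mb: pd.DataFrame
    remainder_mb: pd.Series
    genome_size: pd.Series
    annot: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.mb.rename_axis("cluster").to_csv(path, sep="\t")

    def to_long_tsv(self, path) -> None:
        """Bar-chart-ready long format: species, lineage, cluster, Mb."""
        long = (
            self.mb.join(self.annot["lineage"])
            .set_index("lineage", append=True)
            .stack()
            .rename("mb")
            .rename_axis(["cluster", "lineage", "species"])
            .reset_index()[["species", "lineage", "cluster", "mb"]]
        )
        long.to_csv(path, sep="\t", index=False)


def abundance_matrix(
    table: ClusterTable,
    genome_sizes: Mapping[str, float] | pd.Series,
    totals: Mapping[str, int] | pd.Series | None = None,
) -> AbundanceMatrix:
    """Scale cluster read counts to Mb using per-species genome sizes.

    ``totals`` is the per-species total read count of the clustering run;
    it defaults to clustered + remainder reads per species.
    """
    species = list(table.counts.columns)
    gs = pd.Series({s: float(genome_sizes[s]) for s in species})
    if totals is None:
        tot = table.counts.sum(axis=0) + table.remainder
    else:
        tot = pd.Series({s: int(totals[s]) for s in species})
    if (tot <= 0).any():
        raise ValueError("total read count must be > 0 for every species")
    mb = table.counts.astype(float).div(tot, axis=1).mul(gs, axis=1)
    remainder_mb = gs - mb.sum(axis=0)
    return AbundanceMatrix(mb=mb, remainder_mb=remainder_mb, genome_size=gs, annot=table.annot.copy())


def repeat_fraction(matrix: AbundanceMatrix, species: str) -> float:
    """Percent of the 1C genome in non-small, non-plastid repeat clusters."""
    if species not in matrix.mb.columns:
        raise KeyError(f"unknown species {species!r}")
    if len(matrix.mb) == 0:
        return 0.0
    keep = (~matrix.annot["small"].astype(bool)) & (~matrix.annot["plastid"].astype(bool))
    total = float(matrix.mb.loc[keep.index[keep], species].sum())
    return 100.0 * total / float(matrix.genome_size[species])


def top_clusters(table: ClusterTable, n: int = 225, exclude_plastid: bool = True) -> ClusterTable:
    """First ``n`` clusters by total size, optionally dropping plastid rows."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = table.cluster_ids
    if exclude_plastid:
        ids = [c for c in ids if not bool(table.annot.loc[c, "plastid"])]
    ids = ids[:n]
    return ClusterTable(
        counts=table.counts.loc[ids].copy(),
        annot=table.annot.loc[ids].copy(),
        remainder=table.remainder.copy(),
        total_reads=table.total_reads,
        members={c: table.members[c] for c in ids if c in table.members},
    )


def fold_range(values: Iterable[float]) -> float:
    """max/min of positive values, rounded half-up to one decimal place."""
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("values must be non-empty")
    if min(vals) <= 0:
        raise ValueError("all values must be > 0")
    ratio = max(vals) / min(vals)
    return float(Decimal(repr(ratio)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
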