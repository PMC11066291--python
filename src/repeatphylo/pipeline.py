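"""End-to-end synthetic repeatome study: simulate → cluster → quantify →
signal → network.

This module wires the stages together for the standard synthetic study
design — a clade-structured species tree, repeat families evolving along
it with an amplification burst on one clade's stem, genome-skim read
emission, comparative clustering, genome-size-scaled quantification,
per-cluster trend classification, and the repeat-similarity consensus
network — and is what the command-line interface runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__, comparative, quantify, readgraph, repnet, simulate, trees
from .readset import ReadSet

__all__ = ["StudyConfig", "StudyResult", "default_clades", "build_families", "run_study"]


def default_clades() -> dict[str, list[str]]:
    """Ten species in four clades (A, B, C, D), D carrying the burst."""
    return {
        "A": ["a1", "a2"],
        "B": ["b1", "b2", "b3"],
        "C": ["c1", "c2"],
        "D": ["d1", "d2", "d3"],
    }


@dataclass
class StudyConfig:
    """Parameters of the synthetic study.

    Defaults follow the study design the package emulates: 10 species in 4
    clades, 8 repeat families of 300 Mb each at the root with a 2.5×
    amplification burst of one family on clade D's stem, 150 bp reads at
    20 000 per species, and repeats occupying ~85% of every genome.
    """

    clades: dict[str, list[str]] = field(default_factory=default_clades)
    n_families: int = 8
    family_mb: float = 300.0
    consensus_length: int = 25_000
    single_copy_mb: float = 425.0
    burst_family_index: int = 1
    burst_clade: str = "D"
    burst_multiplier: float = 2.5
    lam: float = 1.0
    sigma2: float = 0.0
    consensus_rate: float = 0.21
    read_length: int = 150
    n_reads_per_species: int = 20_000
    read_divergence: float = 0.005
    k: int = readgraph.DEFAULT_K
    min_shared: int = readgraph.DEFAULT_MIN_SHARED
    small_threshold: float = readgraph.SMALL_CLUSTER_THRESHOLD
    top_n: int = 225
    alpha: float = 0.05
    min_freq: float = 0.10
    outgroup: tuple[str, ...] = ()
    seed: int = 0


@dataclass
class StudyResult:
    config: StudyConfig
    tree: "object"
    truth: simulate.SimTruth
    families: list[simulate.FamilySpec]
    graph: readgraph.ReadGraph
    clusters: readgraph.ClusterTable
    abundance: quantify.AbundanceMatrix
    repeat_fractions: pd.Series  # recovered, percent
    trends: pd.DataFrame  # per cluster: lineage, trend, lambda_hat, pvalue
    nj_trees: list
    splits: repnet.SplitSet
    order_score: pd.Series

    def true_clade_splits(self) -> list[frozenset]:
        taxa = set()
        for sp in self.config.clades.values():
            taxa.update(sp)
        return [
            frozenset(sp)
            for sp in self.config.clades.values()
            if 1 < len(sp) < len(taxa) - 1
        ]


def build_families(config: StudyConfig, rng: np.random.Generator) -> list[simulate.FamilySpec]:
    burst_tips = config.clades[config.burst_clade]
    fams = []
    for i in range(config.n_families):
        bursts = ()
        if i == config.burst_family_index:
            bursts = ((trees.edge_id_for(burst_tips), config.burst_multiplier),)
        fams.append(
            simulate.random_family(
                f"fam{i}",
                config.consensus_length,
                config.family_mb,
                rng,
                lineage_label=f"fam{i}",
                burst_edges=bursts,
            )
        )
    return fams


def clade_order_score(clades: dict[str, list[str]]) -> pd.Series:
    """Clade rank per species in the clade sequence given (A=1, B=2, ...)."""
    out = {}
    for rank, (_, members) in enumerate(clades.items(), start=1):
        for sp in members:
            out[sp] = float(rank)
    return pd.Series(out)


def run_study(config: StudyConfig, subsample: int | None = None) -> StudyResult:
    """Run the full synthetic study and return every intermediate product.

    ``subsample`` optionally clusters only that many reads per species
    (drawn without replacement), as comparative clustering does with deep
    real datasets; by default every emitted read is clustered.
    """
    tree = trees.clade_tree(config.clades)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xFA411]))
    families = build_families(config, rng)
    truth = simulate.evolve_abundances(
        tree,
        families,
        lam=config.lam,
        sigma2=config.sigma2,
        seed=config.seed,
        single_copy_mb=config.single_copy_mb,
    )
    consensi = simulate.evolve_consensi(tree, families, rate=config.consensus_rate, seed=config.seed)
    reads = simulate.emit_reads(
        truth,
        families,
        read_length=config.read_length,
        n_reads=config.n_reads_per_species,
        divergence=config.read_divergence,
        seed=config.seed,
        consensi=consensi,
    )
    if subsample is not None:
        pooled = readgraph.comparative_subsample(reads, n_per_species=subsample, seed=config.seed)
        totals = {sp: subsample for sp in reads}
    else:
        pooled = ReadSet.concat([reads[sp] for sp in sorted(reads)])
        totals = {sp: config.n_reads_per_species for sp in reads}

    graph = readgraph.build_graph(pooled, k=config.k, min_shared=config.min_shared)
    clusters = readgraph.cluster_reads(
        graph, total_reads=len(pooled), small_threshold=config.small_threshold
    )
    clusters = clusters.annotate_from_families(graph)
    top = quantify.top_clusters(clusters, n=config.top_n, exclude_plastid=True)
    abundance = quantify.abundance_matrix(top, truth.genome_size, totals=totals)
    fractions = pd.Series(
        {sp: quantify.repeat_fraction(abundance, sp) for sp in truth.species}
    )

    order = clade_order_score(config.clades)
    nonsmall = [c for c in top.cluster_ids if not bool(top.annot.loc[c, "small"])]
    trend_rows = []
    for cid in nonsmall:
        mb = abundance.mb.loc[cid]
        trend = comparative.classify_trend(mb, tree, order, alpha=config.alpha)
        row = {"cluster": cid, "lineage": top.annot.loc[cid, "lineage"], "trend": trend}
        try:
            fit = comparative.fit_lambda(mb, tree)
            row["lambda_hat"] = fit.lambda_hat
            row["pvalue"] = fit.pvalue
        except ValueError:
            row["lambda_hat"] = np.nan
            row["pvalue"] = np.nan
        trend_rows.append(row)
    trends = pd.DataFrame(trend_rows).set_index("cluster")

    mats = [
        repnet.observed_expected(graph, nodes, cid)
        for cid, nodes in top.members.items()
        if cid in nonsmall
    ]
    mats = repnet.drop_edgeless(mats, outgroup=config.outgroup)
    ingroup = sorted(set(s for sp in config.clades.values() for s in sp) - set(config.outgroup))
    mats = [m for m in mats if set(m.species) == set(ingroup)]
    if not mats:
        raise ValueError(
            "no cluster spans every ingroup species; increase read depth "
            "or reduce between-species divergence"
        )
    nj_trees = [repnet.neighbor_joining(repnet.to_distance(m)) for m in mats]
    splits = repnet.consensus(nj_trees, min_freq=config.min_freq)

    return StudyResult(
        config=config,
        tree=tree,
        truth=truth,
        families=families,
        graph=graph,
        clusters=clusters,
        abundance=abundance,
        repeat_fractions=fractions,
        trends=trends,
        nj_trees=nj_trees,
        splits=splits,
        order_score=order,
    )


def write_outputs(result: StudyResult, outdir: str | Path) -> dict:
    """Write the study's artifacts under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "species_tree.nwk").write_text(trees.to_newick(result.tree) + "\n")
    result.truth.to_tsv(outdir / "truth_abundance.tsv")
    result.clusters.to_tsv(outdir / "cluster_table.tsv")
    result.abundance.to_tsv(outdir / "abundance_mb.tsv")
    result.abundance.to_long_tsv(outdir / "abundance_long.tsv")
    result.repeat_fractions.rename("repeat_pct").rename_axis("species").to_csv(
        outdir / "repeat_fractions.tsv", sep="\t"
    )
    result.trends.to_csv(outdir / "trends.tsv", sep="\t")
    with open(outdir / "nj_trees.nwk", "w") as fh:
        for t in result.nj_trees:
            fh.write(trees.to_newick(t) + "\n")
    repnet.write_splits_nexus(result.splits, outdir / "consensus_splits.nex")
    manifest = {
        "tool": "repeatphylo",
        "version": __version__,
        "seed": result.config.seed,
        "parameters": {
            k: v for k, v in vars(result.config).items() if not isinstance(v, (dict, tuple))
        },
        "clades": result.config.clades,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
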