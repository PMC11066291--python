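"""Repeat-similarity consensus network reconstruction.

For every comparative cluster, the inter-species edge counts of its read
graph are compared with a uniform random-edge-placement null, giving an
observed/expected (O/E) ratio matrix; ratios become distances by
normalizing to the off-diagonal maximum (``d = 1 − r/max r``). Each
cluster's distance matrix yields a neighbor-joining tree, and bipartitions
occurring in at least a threshold fraction of trees form the consensus
split system, exported in NEXUS for split-network viewers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import trees
from .readgraph import ReadGraph

__all__ = [
    "EdgeStatMatrix",
    "SplitSet",
    "observed_expected",
    "drop_edgeless",
    "to_distance",
    "neighbor_joining",
    "splits_of",
    "consensus",
    "write_splits_nexus",
    "read_splits_nexus",
]


@dataclass
class EdgeStatMatrix:
    """Per-cluster species × species observed/expected edge ratios."""

    ratio: pd.DataFrame
    observed: pd.DataFrame
    expected: pd.DataFrame
    n_reads: pd.Series
    e_total: int
    cluster_id: str = ""

    @property
    def species(self) -> list[str]:
        return list(self.ratio.index)

    def restrict(self, keep: Sequence[str]) -> "EdgeStatMatrix":
        keep = [s for s in self.species if s in set(keep)]
        return EdgeStatMatrix(
            ratio=self.ratio.loc[keep, keep].copy(),
            observed=self.observed.loc[keep, keep].copy(),
            expected=self.expected.loc[keep, keep].copy(),
            n_reads=self.n_reads.loc[keep].copy(),
            e_total=self.e_total,
            cluster_id=self.cluster_id,
        )


def observed_expected(
    graph: ReadGraph,
    nodes: np.ndarray | None = None,
    cluster_id: str = "",
) -> EdgeStatMatrix:
    """O/E inter-species edge ratios for one cluster.

    The null places the cluster's ``E_total`` edges uniformly over all
    ``C(N, 2)`` node pairs, so ``E[i,j] = E_total·n_i·n_j/C(N,2)`` off the
    diagonal and ``E[i,i] = E_total·C(n_i,2)/C(N,2)``; 0/0 ratios are 0.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    if nodes is None:
        nodes = np.arange(graph.n_nodes)
    nodes = np.asarray(nodes)
    if nodes.size < 2:
        sp = sorted(set(np.asarray(graph.species, dtype=object)[nodes].tolist()))
        one = pd.DataFrame(0.0, index=sp, columns=sp)
        return EdgeStatMatrix(one, one.copy(), one.copy(), pd.Series(1, index=sp), 0, cluster_id)

    in_cluster = np.zeros(graph.n_nodes, dtype=bool)
    in_cluster[nodes] = True
    species = np.asarray(graph.species, dtype=object)
    sp_levels = sorted(set(species[nodes].tolist()))
    sp_idx = {s: i for i, s in enumerate(sp_levels)}
    m = len(sp_levels)
    n_i = np.zeros(m)
    for s in species[nodes]:
        n_i[sp_idx[s]] += 1

    mask = in_cluster[graph.edges_u] & in_cluster[graph.edges_v]
    eu = graph.edges_u[mask]
    ev = graph.edges_v[mask]
    O = np.zeros((m, m))
    su = np.fromiter((sp_idx[s] for s in species[eu]), dtype=np.int64, count=eu.size)
    sv = np.fromiter((sp_idx[s] for s in species[ev]), dtype=np.int64, count=ev.size)
    np.add.at(O, (np.minimum(su, sv), np.maximum(su, sv)), 1)
    O = O + np.triu(O, 1).T

    e_total = int(eu.size)
    N = float(nodes.size)
    pairs_total = N * (N - 1) / 2.0
    E = e_total * np.outer(n_i, n_i) / pairs_total
    np.fill_diagonal(E, e_total * n_i * (n_i - 1) / 2.0 / pairs_total)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(E > 0, O / np.where(E > 0, E, 1.0), 0.0)
    idx = pd.Index(sp_levels)
    return EdgeStatMatrix(
        ratio=pd.DataFrame(R, index=idx, columns=idx),
        observed=pd.DataFrame(O, index=idx, columns=idx),
        expected=pd.DataFrame(E, index=idx, columns=idx),
        n_reads=pd.Series(n_i.astype(int), index=idx),
        e_total=e_total,
        cluster_id=cluster_id,
    )


def drop_edgeless(
    matrices: Iterable[EdgeStatMatrix],
    outgroup: Sequence[str] = (),
) -> list[EdgeStatMatrix]:
    """Drop clusters without any inter-species edges.

    ``outgroup`` species are removed from every matrix *before* the test,
    mirroring analyses that omit outgroups with few ingroup connections.
    """
    out = []
    og = set(outgroup)
    for mat in matrices:
        if og:
            mat = mat.restrict([s for s in mat.species if s not in og])
        obs = mat.observed.to_numpy()
        off = obs - np.diag(np.diag(obs))
        if off.sum() > 0:
            out.append(mat)
    return out


def to_distance(R: EdgeStatMatrix | pd.DataFrame) -> pd.DataFrame:
    """Normalize O/E ratios to [0, 1] similarities and return 1 − r/max(r)."""
    ratio = R.ratio if isinstance(R, EdgeStatMatrix) else R
    A = ratio.to_numpy(dtype=float)
    off = A - np.diag(np.diag(A))
    mx = off.max()
    if mx <= 0:
        raise ValueError("all off-diagonal ratios are zero; cluster should have been dropped")
    D = 1.0 - A / mx
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=ratio.index, columns=ratio.columns)


# ----------------------------------------------------------------- NJ


def neighbor_joining(D: pd.DataFrame) -> dendropy.Tree:
    """Canonical neighbor joining (Saitou–Nei with Studier–Keppler Q).

    Ties in Q break on the lexicographically smallest taxon-pair label (each
    partial subtree is labelled by its smallest contained taxon). Negative
    branch lengths are clamped to zero with the deficit shifted to the
    sister branch. Returns an unrooted dendropy tree.
    """
    labels = list(D.index)
    n0 = len(labels)
    if n0 < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = {(a, b): float(D.loc[a, b]) for a in labels for b in labels if a != b}

    # each active node: (sort label, newick fragment)
    active: dict[str, str] = {lab: lab for lab in labels}

    def dist(a: str, b: str) -> float:
        return d[(a, b)]

    while len(active) > 3:
        names = sorted(active)
        r = {a: sum(dist(a, b) for b in names if b != a) for a in names}
        best = None
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                q = (len(names) - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2.0 * (len(names) - 2))
        lb = dab - la
        if la < 0:
            lb -= la  # shift deficit to sister branch
            la = 0.0
        if lb < 0:
            la -= lb
            lb = 0.0
        new_label = min(a, b)
        newick = f"({active[a]}:{la:.10g},{active[b]}:{lb:.10g})"
        new_d = {c: 0.5 * (dist(a, c) + dist(b, c) - dab) for c in names if c not in (a, b)}
        for c in names:
            for x in (a, b):
                d.pop((x, c), None)
                d.pop((c, x), None)
        for c, val in new_d.items():
            d[(new_label, c)] = d[(c, new_label)] = val
        del active[a], active[b]
        active[new_label] = newick

    (a, b, c) = sorted(active)
    dab, dac, dbc = dist(a, b), dist(a, c), dist(b, c)
    xa = max(0.0, (dab + dac - dbc) / 2.0)
    xb = max(0.0, (dab + dbc - dac) / 2.0)
    xc = max(0.0, (dac + dbc - dab) / 2.0)
    newick = f"({active[a]}:{xa:.10g},{active[b]}:{xb:.10g},{active[c]}:{xc:.10g});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


# ----------------------------------------------------------------- splits


@dataclass
class SplitSet:
    """A weighted set of bipartitions over a fixed taxon set.

    Each split is stored as the side *not* containing the first taxon
    (canonical form); weights are frequencies in (0, 1]. Trivial splits
    (one taxon against the rest) are retained but flagged.
    """

    taxa: tuple[str, ...]
    splits: dict[frozenset, float]

    def nontrivial(self) -> dict[frozenset, float]:
        n = len(self.taxa)
        return {s: w for s, w in self.splits.items() if 1 < len(s) < n - 1}

    def is_trivial(self, side: frozenset) -> bool:
        return len(side) <= 1 or len(side) >= len(self.taxa) - 1

    def __contains__(self, bipartition: frozenset | set) -> bool:
        return self._canon(frozenset(bipartition)) in self.splits

    def frequency(self, bipartition: frozenset | set) -> float:
        return self.splits.get(self._canon(frozenset(bipartition)), 0.0)

    def _canon(self, side: frozenset) -> frozenset:
        anchor = sorted(self.taxa)[0]
        if anchor in side:
            return frozenset(self.taxa) - side
        return side


def splits_of(tree: dendropy.Tree) -> SplitSet:
    """One split per edge of an unrooted tree; trivial splits flagged."""
    taxa = tuple(sorted(trees.tip_labels(tree)))
    anchor = taxa[0]
    all_taxa = frozenset(taxa)
    splits: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if anchor in side:
            side = all_taxa - side
        if 0 < len(side) < len(taxa):
            splits[side] = 1.0
    return SplitSet(taxa=taxa, splits=splits)


def consensus(nj_trees: Sequence[dendropy.Tree], min_freq: float = 0.10) -> SplitSet:
    """Splits occurring in at least ``min_freq`` of the trees (inclusive)."""
    if not nj_trees:
        raise ValueError("no trees given")
    split_sets = [splits_of(t) for t in nj_trees]
    taxa = split_sets[0].taxa
    for ss in split_sets[1:]:
        if ss.taxa != taxa:
            raise ValueError("all trees must share the same taxon set")
    counts: dict[frozenset, int] = {}
    for ss in split_sets:
        for side in ss.splits:
            counts[side] = counts.get(side, 0) + 1
    n = len(split_sets)
    kept = {
        side: c / n
        for side, c in counts.items()
        if c + 1e-9 >= min_freq * n
    }
    return SplitSet(taxa=taxa, splits=kept)


# ----------------------------------------------------------------- NEXUS


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}/\\,;:=*'\"`+<>~"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_splits_nexus(splits: SplitSet, path: str | Path) -> None:
    """Write a SplitsTree-compatible NEXUS file (TAXA + ST_SPLITS blocks)."""
    taxa = list(splits.taxa)
    idx = {t: i + 1 for i, t in enumerate(taxa)}
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"DIMENSIONS NTAX={len(taxa)};", "TAXLABELS"]
    lines += [f"  {_quote(t)}" for t in taxa]
    lines += [";", "END;", "", "BEGIN ST_SPLITS;"]
    lines.append(f"DIMENSIONS NTAX={len(taxa)} NSPLITS={len(splits.splits)};")
    lines.append("FORMAT LABELS=NO WEIGHTS=YES;")
    lines.append("MATRIX")
    for side in sorted(splits.splits, key=lambda s: (len(s), sorted(s))):
        w = splits.splits[side]
        members = " ".join(str(idx[t]) for t in sorted(side, key=lambda t: idx[t]))
        lines.append(f"  {w!r}  {members},")
    lines += [";", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_splits_nexus(path: str | Path) -> SplitSet:
    """Re-parse a file written by :func:`write_splits_nexus` exactly."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines()]
    taxa: list[str] = []
    splits: dict[frozenset, float] = {}
    mode = None
    for ln in lines:
        up = ln.upper()
        if up == "TAXLABELS":
            mode = "taxa"
            continue
        if up == "MATRIX":
            mode = "splits"
            continue
        if ln == ";" or up.startswith("END;"):
            mode = None
            continue
        if mode == "taxa" and ln:
            lab = ln
            if lab.startswith("'") and lab.endswith("'"):
                lab = lab[1:-1].replace("''", "'")
            taxa.append(lab)
        elif mode == "splits" and ln:
            body = ln.rstrip(",")
            parts = body.split()
            w = float(parts[0])
            side = frozenset(taxa[int(i) - 1] for i in parts[1:])
            splits[side] = w
    return SplitSet(taxa=tuple(taxa), splits=splits)
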