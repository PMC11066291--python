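"""Newick tree helpers shared by the simulator and the comparative machinery.

Trees are dendropy :class:`~dendropy.Tree` objects throughout. Species are
addressed by taxon label; clade stems are addressed by the sorted ``+``-joined
labels of the tips they subtend (a terminal edge is addressed by its tip
label alone).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def load_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def edge_id_for(tips: Iterable[str]) -> str:
    """Canonical identifier of the stem edge above the MRCA of ``tips``."""
    return "+".join(sorted(tips))


def resolve_edge(tree: dendropy.Tree, edge_id: str) -> dendropy.Node:
    """Find the node whose subtended leaf set exactly matches ``edge_id``.

    The edge addressed is the branch immediately above the returned node.
    Raises ``KeyError`` when no branch subtends exactly that set of tips.
    """
    want = frozenset(edge_id.split("+"))
    known = set(tip_labels(tree))
    unknown = want - known
    if unknown:
        raise KeyError(f"unknown tip(s) in edge id {edge_id!r}: {sorted(unknown)}")
    for node in tree.preorder_node_iter():
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if below == want:
            return node
    raise KeyError(f"no branch subtends exactly {edge_id!r}")


def tips_below(node: dendropy.Node) -> list[str]:
    return sorted(leaf.taxon.label for leaf in node.leaf_iter())


def random_unrooted_tree(
    n_taxa: int,
    rng: "object",
    min_branch: float = 0.1,
    max_branch: float = 1.0,
) -> dendropy.Tree:
    """Random unrooted binary tree with uniform branch lengths.

    Grown by sequentially attaching taxa to a uniformly chosen existing
    edge. Path lengths between tips form an additive distance matrix, the
    standard oracle input for distance-based reconstruction.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    labels = [f"t{i}" for i in range(n_taxa)]

    def bl() -> float:
        return float(rng.uniform(min_branch, max_branch))

    nwk = f"({labels[0]}:{bl():.6f},{labels[1]}:{bl():.6f},{labels[2]}:{bl():.6f});"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    tree.is_rooted = False
    for lab in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.length is not None]
        edge = edges[int(rng.integers(len(edges)))]
        child, parent = edge.head_node, edge.tail_node
        brk = edge.length * float(rng.uniform(0.2, 0.8))
        mid = parent.new_child(edge_length=edge.length - brk)
        parent.remove_child(child)
        mid.add_child(child)
        child.edge.length = brk
        taxon = tree.taxon_namespace.new_taxon(label=lab)
        mid.new_child(taxon=taxon, edge_length=bl())
    return tree


def path_distance_matrix(tree: dendropy.Tree):
    """All-pairs tip path-length (patristic) distances as a DataFrame."""
    import pandas as pd

    pdm = tree.phylogenetic_distance_matrix()
    labs = tip_labels(tree)
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labs)}
    D = pd.DataFrame(0.0, index=labs, columns=labs)
    for i, a in enumerate(labs):
        for b in labs[i + 1 :]:
            d = pdm.patristic_distance(taxa[a], taxa[b])
            D.loc[a, b] = D.loc[b, a] = d
    return D


def clade_tree(
    clades: dict[str, Sequence[str]],
    height: float = 1.0,
    crown_depth: float = 0.15,
    backbone_start: float = 0.45,
) -> dendropy.Tree:
    """Build an ultrametric species tree with a pectinate clade backbone.

    Each clade is a pectinate subtree whose crown sits ``crown_depth`` below
    the tips; clade stems attach to a backbone whose splits are evenly spaced
    between ``backbone_start`` and the root ``height``. This is the shape the
    synthetic studies use: well-separated clades with shallow internal
    structure.
    """
    if len(clades) < 2:
        raise ValueError("need at least two clades")
    if not (0 < crown_depth < backbone_start < height):
        raise ValueError("require 0 < crown_depth < backbone_start < height")

    def pectinate(labels: Sequence[str], depth: float) -> str:
        # tips at time 0, subtree crown at `depth`
        labels = list(labels)
        if len(labels) == 1:
            return f"{labels[0]}:{depth:.10g}"
        times = [depth * (i + 1) / (len(labels) - 1) for i in range(len(labels) - 1)]
        sub = f"({labels[0]}:{times[0]:.10g},{labels[1]}:{times[0]:.10g})"
        t_prev = times[0]
        for lab, t in zip(labels[2:], times[1:]):
            sub = f"({sub}:{(t - t_prev):.10g},{lab}:{t:.10g})"
            t_prev = t
        return sub

    names = list(clades)
    sub_newicks = []
    for name in names:
        labels = list(clades[name])
        if len(labels) == 1:
            sub_newicks.append((labels[0], 0.0))
        else:
            sub_newicks.append((pectinate(labels, crown_depth), crown_depth))

    k = len(names)
    # backbone joins: the last two clades join at backbone_start, then each
    # earlier clade joins at evenly spaced older times up to `height`.
    join_times = [backbone_start + (height - backbone_start) * i / max(k - 2, 1) for i in range(k - 1)]
    nwk, depth = sub_newicks[-1]
    cur = f"{nwk}:{join_times[0] - depth:.10g}"
    nwk2, depth2 = sub_newicks[-2]
    cur = f"({nwk2}:{join_times[0] - depth2:.10g},{cur})"
    t_prev = join_times[0]
    for (nwk_i, depth_i), t in zip(reversed(sub_newicks[:-2]), join_times[1:]):
        cur = f"({nwk_i}:{t - depth_i:.10g},{cur}:{t - t_prev:.10g})"
        t_prev = t
    return tree_from_newick("[&R] " + cur + ";")
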