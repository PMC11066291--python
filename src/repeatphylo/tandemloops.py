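"""Loop structure of tandem-repeat (5S rDNA) read clusters.

Reads from a tandem array are assembled into a de-Bruijn-style graph on
canonical k-mers; unbranched paths are condensed into unitigs. The number of
independent cycles of the condensed graph — its circuit rank,
``E − V + C`` — formalizes the "loop count" of the cluster graph: a pure
satellite from a single monomer gives one loop, an array interleaving
several diverged monomer variants (the hybrid/polyploid signature of 5S
rDNA) gives one loop per variant, joined through the conserved block.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from . import _kmers
from .readset import ReadSet

__all__ = ["CondensedGraph", "build_condensed_graph", "circuit_rank", "classify_5s", "LoopClassification"]


@dataclass
class CondensedGraph:
    """Condensed assembly graph: nodes are unitigs, edges are k−1 overlaps.

    The underlying structure is an undirected multigraph (parallel edges and
    self-loops count in the circuit rank). Node attributes: ``n_kmers``
    (unitig length in k-mers) and ``coverage`` (mean k-mer multiplicity).
    """

    graph: nx.MultiGraph
    k: int

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_edge_list(self, path) -> None:
        rows = [{"node_a": u, "node_b": v} for u, v, _ in self.graph.edges(keys=True)]
        pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(path, sep="\t", index=False)


def _condense(g: nx.MultiGraph) -> nx.MultiGraph:
    """Contract every degree-2 node (no self-loop) until none remain."""
    g = g.copy()
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes):
            if g.degree(v) != 2 or g.number_of_edges(v, v) > 0:
                continue
            edges = list(g.edges(v, keys=True, data=True))
            if len(edges) != 2:
                continue  # a double edge to one neighbour counted once
            (_, a, _, da), (_, b, _, db) = edges
            attrs_v = g.nodes[v]
            g.remove_node(v)
            merged = {
                "n_kmers": da.get("n_kmers", 0) + db.get("n_kmers", 0) + attrs_v.get("n_kmers", 1),
                "cov_sum": da.get("cov_sum", 0.0) + db.get("cov_sum", 0.0) + attrs_v.get("cov_sum", 0.0),
            }
            g.add_edge(a, b, **merged)
            changed = True
    return g


def build_condensed_graph(
    reads: ReadSet | Iterable[str],
    k: int = 21,
    min_cov: int = 2,
) -> CondensedGraph:
    """De-Bruijn graph on canonical k-mers, denoised and condensed.

    K-mers seen fewer than ``min_cov`` times are dropped (sequencing-noise
    pruning); maximal unbranched paths are then contracted.
    """
    seqs = reads.seqs if isinstance(reads, ReadSet) else list(reads)
    if not seqs:
        raise ValueError("empty read set")
    if any(len(s) <= k for s in seqs):
        raise ValueError(f"k={k} must be smaller than every read length")

    kmer_counts: Counter[int] = Counter()
    edge_kmers: set[tuple[int, int, int]] = set()
    encoded = [_kmers.encode(s) for s in seqs]
    for arr in encoded:
        codes = _kmers.canonical_kmer_codes(arr, k)
        kmer_counts.update(codes.tolist())
    kept = {c for c, n in kmer_counts.items() if n >= min_cov}
    for arr in encoded:
        codes = _kmers.canonical_kmer_codes(arr, k)
        links = _kmers.canonical_kmer_codes(arr, k + 1)
        for i in range(links.size):
            u, v = int(codes[i]), int(codes[i + 1])
            if u in kept and v in kept:
                edge_kmers.add((u, v, int(links[i])))

    g = nx.MultiGraph()
    for c in kept:
        g.add_node(c, n_kmers=1, cov_sum=float(kmer_counts[c]))
    for u, v, key in edge_kmers:
        if not g.has_edge(u, v, key=key):
            g.add_edge(u, v, key=key, n_kmers=0, cov_sum=0.0)
    return CondensedGraph(graph=_condense(g), k=k)


def circuit_rank(g: CondensedGraph | nx.Graph | nx.MultiGraph) -> int:
    """Number of independent cycles, ``E − V + C``; the reported loop count."""
    graph = g.graph if isinstance(g, CondensedGraph) else g
    if graph.number_of_nodes() == 0:
        return 0
    return (
        graph.number_of_edges()
        - graph.number_of_nodes()
        + nx.number_connected_components(graph)
    )


class LoopClassification(NamedTuple):
    loop_count: int
    label: str


def classify_5s(loop_count: int) -> LoopClassification:
    """Map a loop count to the 5S rDNA hybridity label.

    One loop is the ordinary (non-hybrid) satellite pattern; two or more
    loops indicate interleaved monomer variants as expected after
    hybridization or polyploidization.
    """
    if loop_count < 0:
        raise ValueError("loop count must be >= 0")
    if loop_count == 0:
        return LoopClassification(0, "non-tandem")
    if loop_count == 1:
        return LoopClassification(1, "simple (non-hybrid pattern)")
    return LoopClassification(loop_count, "complex (hybrid/polyploid pattern)")
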