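"""Read-similarity graphs and comparative clustering.

Two reads are similar when they share at least ``min_shared`` distinct
canonical k-mers; clusters are the connected components of the resulting
graph, ordered by size. This is a desk-scale, exactly reproducible proxy for
all-to-all BLAST clustering of genome-skim reads: shared canonical k-mers
are a monotone function of local sequence identity, and components are the
units of quantification downstream.

The graph is built from an inverted k-mer index, never by an all-pairs
scan, but is score-identical to the all-pairs definition: for every k-mer,
all reads containing it are paired, and the number of index hits of a pair
equals its count of distinct shared canonical k-mers. Pair multisets are
aggregated in fixed-size numpy chunks so memory stays bounded at millions
of reads.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from . import _kmers
from .readset import ReadSet, pool

__all__ = ["ReadGraph", "ClusterTable", "shared_kmers", "build_graph", "cluster_reads", "comparative_subsample"]

DEFAULT_K = 13
DEFAULT_MIN_SHARED = 8
SMALL_CLUSTER_THRESHOLD = 0.0001  # fraction of total reads below which a cluster is "small"


def shared_kmers(a: str, b: str, k: int = DEFAULT_K) -> int:
    """Number of distinct canonical k-mers present in both reads."""
    if k > min(len(a), len(b)):
        raise ValueError(f"k={k} exceeds a read length ({min(len(a), len(b))})")
    ka = _kmers.distinct_canonical_kmers(a, k)
    kb = _kmers.distinct_canonical_kmers(b, k)
    return int(np.intersect1d(ka, kb, assume_unique=True).size)


@dataclass
class ReadGraph:
    """Undirected read-similarity graph stored as flat edge arrays."""

    ids: list[str]
    species: np.ndarray  # per-node species tag
    edges_u: np.ndarray  # int64 node indices, u < v
    edges_v: np.ndarray
    scores: np.ndarray  # shared distinct canonical k-mers per edge
    k: int
    min_shared: int
    families: list[str | None] | None = None  # simulator provenance, optional

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def n_edges(self) -> int:
        return int(self.edges_u.size)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for i, rid in enumerate(self.ids):
            g.add_node(rid, species=str(self.species[i]))
        for u, v, s in zip(self.edges_u, self.edges_v, self.scores):
            g.add_edge(self.ids[int(u)], self.ids[int(v)], score=int(s))
        return g

    def write_edge_list(self, path) -> None:
        pd.DataFrame(
            {
                "read_a": [self.ids[int(u)] for u in self.edges_u],
                "read_b": [self.ids[int(v)] for v in self.edges_v],
                "shared_kmers": self.scores,
            }
        ).to_csv(path, sep="\t", index=False)


def _read_kmer_index(seqs: Sequence[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Concatenated (code, read-index) arrays, one row per distinct k-mer per read."""
    codes_parts: list[np.ndarray] = []
    rid_parts: list[np.ndarray] = []
    for i, s in enumerate(seqs):
        if k > len(s):
            raise ValueError(f"k={k} exceeds read length {len(s)}")
        c = _kmers.distinct_canonical_kmers(s, k)
        codes_parts.append(c)
        rid_parts.append(np.full(c.size, i, dtype=np.int64))
    return np.concatenate(codes_parts), np.concatenate(rid_parts)


class _PairCounter:
    """Streaming multiset counter for int64 pair keys, chunk-compacted.

    Raw keys are deduplicated per ``chunk`` elements; the per-chunk
    (key, count) runs are merged whenever they exceed ``compact_at``
    distinct entries, keeping peak memory proportional to the number of
    distinct pairs rather than to the raw pair multiset.
    """

    def __init__(self, chunk: int = 25_000_000, compact_at: int = 80_000_000):
        self.chunk = chunk
        self.compact_at = compact_at
        self._raw: list[np.ndarray] = []
        self._raw_n = 0
        self._keys: list[np.ndarray] = []
        self._counts: list[np.ndarray] = []
        self._agg_n = 0

    def add(self, keys: np.ndarray) -> None:
        self._raw.append(keys)
        self._raw_n += keys.size
        if self._raw_n >= self.chunk:
            self._flush_raw()
        if self._agg_n > self.compact_at:
            self._compact()

    def _flush_raw(self) -> None:
        if not self._raw:
            return
        u, c = np.unique(np.concatenate(self._raw), return_counts=True)
        self._keys.append(u)
        self._counts.append(c.astype(np.int64))
        self._agg_n += u.size
        self._raw = []
        self._raw_n = 0

    def _compact(self) -> None:
        keys = np.concatenate(self._keys)
        counts = np.concatenate(self._counts)
        order = np.argsort(keys, kind="stable")
        keys, counts = keys[order], counts[order]
        starts = np.flatnonzero(np.r_[True, keys[1:] != keys[:-1]])
        self._keys = [keys[starts]]
        self._counts = [np.add.reduceat(counts, starts)]
        self._agg_n = starts.size

    def finish(self) -> tuple[np.ndarray, np.ndarray]:
        self._flush_raw()
        if not self._keys:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        self._compact()
        return self._keys[0], self._counts[0]


def build_graph(
    reads: ReadSet | Mapping[str, ReadSet] | Iterable[ReadSet],
    k: int = DEFAULT_K,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> ReadGraph:
    """Build the read-similarity graph: edge (u, v) iff shared_kmers >= min_shared."""
    rs = reads if isinstance(reads, ReadSet) else pool(reads)
    if len(rs) == 0:
        raise ValueError("empty read set")
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    n = len(rs)
    codes, rids = _read_kmer_index(rs.seqs, k)

    order = np.argsort(codes, kind="stable")
    codes_s, rids_s = codes[order], rids[order]
    starts = np.flatnonzero(np.r_[True, codes_s[1:] != codes_s[:-1]])
    sizes = np.diff(np.r_[starts, codes_s.size])

    counter = _PairCounter()
    multi = sizes >= 2
    g_starts, g_sizes = starts[multi], sizes[multi]
    # vectorize pair generation by batching groups of equal size
    for t in np.unique(g_sizes):
        t = int(t)
        sel = g_starts[g_sizes == t]
        iu, ju = np.triu_indices(t, 1)
        pairs_per_group = iu.size
        batch_groups = max(1, 8_000_000 // max(pairs_per_group, 1))
        for lo in range(0, sel.size, batch_groups):
            base = sel[lo : lo + batch_groups, None]
            members = rids_s[base + np.arange(t)]
            a = members[:, iu].ravel()
            b = members[:, ju].ravel()
            u = np.minimum(a, b)
            v = np.maximum(a, b)
            counter.add(u * n + v)
    keys, counts = counter.finish()
    keep = counts >= min_shared
    keys, counts = keys[keep], counts[keep]
    return ReadGraph(
        ids=list(rs.ids),
        species=np.asarray(rs.species, dtype=object),
        edges_u=keys // n,
        edges_v=keys % n,
        scores=counts,
        k=k,
        min_shared=min_shared,
        families=rs.families,
    )


@dataclass
class ClusterTable:
    """Clusters (connected components) × species read-count matrix.

    Rows are ordered by total cluster size, descending; ties break on the
    lexicographically smallest read id contained. ``remainder`` counts
    isolated (unclustered) reads per species.
    """

    counts: pd.DataFrame  # cluster id × species
    annot: pd.DataFrame  # per cluster: size, small, min_read_id, lineage, plastid
    remainder: pd.Series  # per species
    total_reads: int
    members: dict[str, np.ndarray] = field(default_factory=dict)  # cluster id -> node indices

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.counts.index)

    def annotate(self, table: pd.DataFrame) -> "ClusterTable":
        """Merge a (cluster-indexed) annotation table with 'lineage'/'plastid' columns."""
        annot = self.annot.copy()
        for col in ("lineage", "plastid"):
            if col in table.columns:
                annot.loc[annot.index.intersection(table.index), col] = table.loc[
                    annot.index.intersection(table.index), col
                ]
        annot["plastid"] = annot["plastid"].astype(bool)
        return ClusterTable(self.counts, annot, self.remainder, self.total_reads, self.members)

    def annotate_from_families(self, graph: ReadGraph) -> "ClusterTable":
        """Set each cluster's lineage to the majority simulator family of its reads."""
        if graph.families is None:
            raise ValueError("graph carries no family provenance")
        fam = np.asarray([f if f is not None else "" for f in graph.families], dtype=object)
        annot = self.annot.copy()
        for cid, nodes in self.members.items():
            vals, cnts = np.unique(fam[nodes], return_counts=True)
            annot.loc[cid, "lineage"] = str(vals[np.argmax(cnts)])
        return ClusterTable(self.counts, annot, self.remainder, self.total_reads, self.members)

    def to_tsv(self, path) -> None:
        out = self.counts.join(self.annot)
        out.rename_axis("cluster").to_csv(path, sep="\t")


def cluster_reads(
    graph: ReadGraph,
    total_reads: int | None = None,
    small_threshold: float = SMALL_CLUSTER_THRESHOLD,
) -> ClusterTable:
    """Partition reads into clusters = connected components of the graph.

    ``total_reads`` defaults to the number of graph nodes; clusters smaller
    than ``small_threshold`` of it are flagged small. Isolated reads form
    the remainder, not clusters.
    """
    n = graph.n_nodes
    if total_reads is None:
        total_reads = n
    if total_reads < n:
        raise ValueError("total_reads must be >= number of graph nodes")
    adj = sparse.coo_matrix(
        (np.ones(graph.n_edges, dtype=np.int8), (graph.edges_u, graph.edges_v)),
        shape=(n, n),
    )
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)

    species = np.asarray(graph.species, dtype=object)
    sp_levels = sorted(set(species.tolist()))
    comp_ids = np.flatnonzero(sizes >= 2)
    ids_arr = np.asarray(graph.ids, dtype=object)

    records = []
    for comp in comp_ids:
        nodes = np.flatnonzero(labels == comp)
        min_id = min(ids_arr[nodes])
        records.append((comp, int(sizes[comp]), min_id, nodes))
    records.sort(key=lambda r: (-r[1], r[2]))

    counts_rows, annot_rows, members = [], [], {}
    for rank, (comp, size, min_id, nodes) in enumerate(records, start=1):
        cid = f"CL{rank}"
        sp_counts = pd.Series(species[nodes]).value_counts()
        counts_rows.append(pd.Series({s: int(sp_counts.get(s, 0)) for s in sp_levels}, name=cid))
        annot_rows.append(
            pd.Series(
                {
                    "size": size,
                    "small": size / total_reads < small_threshold,
                    "min_read_id": min_id,
                    "lineage": "",
                    "plastid": False,
                },
                name=cid,
            )
        )
        members[cid] = nodes
    if counts_rows:
        counts = pd.DataFrame(counts_rows)
        annot = pd.DataFrame(annot_rows)
    else:
        counts = pd.DataFrame(columns=sp_levels)
        annot = pd.DataFrame(columns=["size", "small", "min_read_id", "lineage", "plastid"])
    iso = np.flatnonzero(sizes[labels] == 1)
    rem = pd.Series(species[iso]).value_counts() if iso.size else pd.Series(dtype=int)
    remainder = pd.Series({s: int(rem.get(s, 0)) for s in sp_levels})
    return ClusterTable(
        counts=counts, annot=annot, remainder=remainder,
        total_reads=int(total_reads), members=members,
    )


def comparative_subsample(
    readsets: Mapping[str, ReadSet],
    n_per_species: int = 1_000_000,
    seed: int = 0,
) -> ReadSet:
    """Pool an equal random subsample (without replacement) from each species."""
    parts = []
    for sp in sorted(readsets):
        rs = readsets[sp]
        if len(rs) < n_per_species:
            raise ValueError(
                f"species {sp!r} has only {len(rs)} reads, need {n_per_species}"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(("sub:" + sp).encode())])
        )
        idx = rng.choice(len(rs), size=n_per_species, replace=False)
        idx.sort()
        parts.append(rs.subset(idx.tolist()))
    return ReadSet.concat(parts)
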