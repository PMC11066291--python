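"""Synthetic repeatome evolution: abundances, reads, and tandem arrays.

The generative model: each repeat family has a genomic mass (Mb) at the root
of the species tree; log-mass evolves by Brownian motion on the λ-transformed
tree (multiplicative change, so masses stay positive), after which
hybridization/amplification *bursts* multiply the mass of every tip
descending from a designated branch. Genome-skim reads are then emitted per
species in proportion to each family's share of the genome; the single-copy
remainder emits random background sequence. A separate emitter produces reads
from a multi-variant tandem (5S rDNA-like) array whose repeating units
alternate among diverged variants sharing a conserved block.

Reproducibility: one global integer seed, forked per species or per family
by a stable CRC32 hash of the label, so output is independent of dict or
iteration order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from math import exp, log
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import _kmers, trees
from .readset import ReadSet

__all__ = [
    "FamilySpec",
    "SimTruth",
    "TandemSpec",
    "random_family",
    "evolve_abundances",
    "evolve_consensi",
    "emit_reads",
    "emit_tandem_reads",
    "simulate_trait",
]


def _fork_rng(seed: int, label: str, salt: str = "") -> np.random.Generator:
    """Child generator keyed on (seed, label); stable across runs."""
    h = zlib.crc32((salt + label).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


@dataclass(frozen=True)
class FamilySpec:
    """One repeat family: consensus sequence, root mass, and burst edges.

    ``burst_edges`` maps tree branches (addressed as in
    :func:`repeatphylo.trees.resolve_edge`) to multiplicative amplification
    factors applied to every tip below the branch.
    """

    family_id: str
    consensus: str
    base_abundance: float  # Mb at the root
    lineage_label: str = ""
    burst_edges: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.base_abundance < 0:
            raise ValueError(f"{self.family_id}: base_abundance must be >= 0")
        if not self.consensus:
            raise ValueError(f"{self.family_id}: consensus must be non-empty")
        if set(self.consensus) - set("ACGT"):
            raise ValueError(f"{self.family_id}: consensus must be over ACGT")
        for edge, mult in self.burst_edges:
            if not np.isfinite(mult) or mult < 0:
                raise ValueError(f"{self.family_id}: burst multiplier on {edge!r} must be finite and >= 0")


def random_family(
    family_id: str,
    length: int,
    base_abundance: float,
    rng: np.random.Generator,
    lineage_label: str = "",
    burst_edges: tuple[tuple[str, float], ...] = (),
) -> FamilySpec:
    """A family with a random consensus of the given length."""
    return FamilySpec(
        family_id=family_id,
        consensus=_kmers.random_dna(rng, length),
        base_abundance=base_abundance,
        lineage_label=lineage_label,
        burst_edges=burst_edges,
    )


@dataclass
class SimTruth:
    """Ground truth of one simulated repeatome.

    ``abundance`` is a family × species matrix in Mb; ``genome_size`` is the
    per-species 1C value and always equals ``single_copy`` plus the column
    sum of ``abundance``.
    """

    abundance: pd.DataFrame
    genome_size: pd.Series
    single_copy: pd.Series

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any() or (self.single_copy < 0).any():
            raise ValueError("abundances and single-copy masses must be >= 0")
        recon = self.single_copy + self.abundance.sum(axis=0)
        if not np.allclose(recon, self.genome_size, rtol=1e-12, atol=1e-9):
            raise ValueError("genome_size must equal single_copy + total repeat mass")

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    def repeat_fraction(self) -> pd.Series:
        """True percent of the genome occupied by repeats, per species."""
        return 100.0 * self.abundance.sum(axis=0) / self.genome_size

    def to_tsv(self, path) -> None:
        long = self.abundance.stack().rename("mb").rename_axis(["family", "species"]).reset_index()
        long.to_csv(path, sep="\t", index=False)


def evolve_abundances(
    tree: dendropy.Tree,
    families: Sequence[FamilySpec],
    lam: float = 1.0,
    sigma2: float = 0.0,
    seed: int = 0,
    single_copy_mb: float | Mapping[str, float] = 300.0,
) -> SimTruth:
    """Evolve per-family genomic masses along the tree.

    Log-mass follows Brownian motion with rate ``sigma2`` on the
    λ-transformed tree, starting at ``log(base_abundance)``; burst edges then
    multiply the mass of all tips below them. ``sigma2 = 0`` gives the
    deterministic limit (every tip at base abundance, times its bursts).
    """
    from . import comparative  # deferred: comparative does not import simulate

    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must be in [0, 1]")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and (edge.length is None or edge.length <= 0):
            raise ValueError("tree must have positive branch lengths")

    tips = trees.tip_labels(tree)
    rows = []
    for fam in families:
        if fam.base_abundance == 0.0:
            vals = pd.Series(0.0, index=tips)
        elif sigma2 == 0.0:
            vals = pd.Series(float(fam.base_abundance), index=tips)
        else:
            draw = simulate_trait(
                tree,
                lam=lam,
                sigma2=sigma2,
                root_state=log(fam.base_abundance),
                seed=seed,
                size=1,
                _salt="abund:" + fam.family_id,
            )
            vals = np.exp(draw.iloc[0])
        for edge_id, mult in fam.burst_edges:
            node = trees.resolve_edge(tree, edge_id)
            affected = trees.tips_below(node)
            vals.loc[affected] = vals.loc[affected] * mult
        rows.append(vals.rename(fam.family_id))
    abundance = pd.DataFrame(rows).reindex(columns=tips)

    if isinstance(single_copy_mb, Mapping):
        single_copy = pd.Series({s: float(single_copy_mb[s]) for s in tips})
    else:
        single_copy = pd.Series(float(single_copy_mb), index=tips)
    genome_size = single_copy + abundance.sum(axis=0)
    return SimTruth(abundance=abundance, genome_size=genome_size, single_copy=single_copy)


def evolve_consensi(
    tree: dendropy.Tree,
    families: Sequence[FamilySpec],
    rate: float,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Evolve species-specific consensus sequences along the tree.

    Each branch substitutes each site with probability ``1 - exp(-rate * l)``
    (new base always differs), so closely related species carry more similar
    repeat variants — the signal the repeat-similarity network reads out.
    Returns ``{family_id: {species: consensus}}``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    out: dict[str, dict[str, str]] = {}
    for fam in families:
        rng = _fork_rng(seed, fam.family_id, salt="consensi:")
        root_arr = _kmers.encode(fam.consensus)
        seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_arr}
        fam_out: dict[str, str] = {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                arr = root_arr
            else:
                p = 1.0 - exp(-rate * (node.edge.length or 0.0))
                arr = _kmers.mutate(seqs[id(node.parent_node)], p, rng)
            seqs[id(node)] = arr
            if node.is_leaf():
                fam_out[node.taxon.label] = _kmers.decode(arr)
        out[fam.family_id] = fam_out
    return out


def emit_reads(
    truth: SimTruth,
    families: Sequence[FamilySpec],
    read_length: int = 150,
    n_reads: int = 20_000,
    divergence: float = 0.005,
    seed: int = 0,
    consensi: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[str, ReadSet]:
    """Emit exactly ``n_reads`` single-end reads per species.

    Each read comes from family *f* with probability
    ``abundance[f, s] / genome_size[s]``; the single-copy remainder emits
    uniform random sequence. Consensi are treated as circular when drawing
    start positions. ``consensi`` optionally supplies species-specific
    consensus sequences (see :func:`evolve_consensi`); otherwise every
    species reads from the family's root consensus.
    """
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    fam_by_id = {f.family_id: f for f in families}
    missing = set(truth.abundance.index) - set(fam_by_id)
    if missing:
        raise KeyError(f"families missing specs: {sorted(missing)}")

    out: dict[str, ReadSet] = {}
    for sp in truth.species:
        rng = _fork_rng(seed, sp, salt="reads:")
        gs = float(truth.genome_size[sp])
        fam_ids = list(truth.abundance.index)
        probs = [float(truth.abundance.at[f, sp]) / gs for f in fam_ids]
        probs.append(max(0.0, 1.0 - sum(probs)))  # single-copy remainder
        counts = rng.multinomial(n_reads, probs)

        seq_blocks: list[np.ndarray] = []
        fam_prov: list[str | None] = []
        for fid, cnt in zip(fam_ids, counts[:-1]):
            if cnt == 0:
                continue
            cons = fam_by_id[fid].consensus
            if consensi is not None:
                cons = consensi[fid][sp]
            cons_arr = _kmers.encode(cons)
            if read_length > cons_arr.size:
                raise ValueError(
                    f"read_length {read_length} exceeds consensus length {cons_arr.size} of {fid}"
                )
            ext = np.concatenate([cons_arr, cons_arr[: read_length - 1]])
            starts = rng.integers(0, cons_arr.size, size=cnt)
            block = ext[starts[:, None] + np.arange(read_length)]
            if divergence > 0:
                hit = rng.random(block.shape) < divergence
                shift = rng.integers(1, 4, size=block.shape, dtype=np.uint8)
                block = np.where(hit, (block + shift) % 4, block).astype(np.uint8)
            seq_blocks.append(block.astype(np.uint8))
            fam_prov.extend([fid] * int(cnt))
        n_sc = int(counts[-1])
        if n_sc:
            seq_blocks.append(rng.integers(0, 4, size=(n_sc, read_length), dtype=np.uint8))
            fam_prov.extend([None] * n_sc)

        allseq = np.concatenate(seq_blocks, axis=0) if seq_blocks else np.empty((0, read_length), np.uint8)
        seqs = [_kmers.decode(allseq[i]) for i in range(allseq.shape[0])]
        ids = [f"{sp}_{i}" for i in range(len(seqs))]
        out[sp] = ReadSet(ids=ids, seqs=seqs, species=[sp] * len(seqs), families=fam_prov)
    return out


@dataclass(frozen=True)
class TandemSpec:
    """A tandem array built from ``n_variants`` monomer variants.

    Variants share the first ``conserved_fraction`` of the unit and diverge
    in the remainder at ``variant_divergence`` substitutions per site
    (relative to a common ancestral unit). Diploid-like arrays have one
    variant; hybrid/polyploid-like arrays interleave several.
    """

    n_variants: int = 1
    unit_length: int = 120
    conserved_fraction: float = 0.3
    variant_divergence: float = 0.2

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not (0.0 <= self.conserved_fraction <= 1.0):
            raise ValueError("conserved_fraction must be in [0, 1]")
        if self.unit_length < 2:
            raise ValueError("unit_length must be >= 2")
        if not (0.0 <= self.variant_divergence <= 1.0):
            raise ValueError("variant_divergence must be in [0, 1]")


def emit_tandem_reads(
    spec: TandemSpec,
    n_reads: int = 2_000,
    read_length: int = 100,
    seed: int = 0,
    species: str = "tandem",
    divergence: float = 0.0,
) -> ReadSet:
    """Sample reads from a circular tandem array alternating its variants.

    The array period is ``n_variants * unit_length``; the repeating units
    cycle v1, v2, …, vn, v1, … so every variant junction is represented.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    rng = _fork_rng(seed, species, salt="tandem:")
    unit = rng.integers(0, 4, size=spec.unit_length, dtype=np.uint8)
    n_cons = int(round(spec.conserved_fraction * spec.unit_length))
    variants = []
    for _ in range(spec.n_variants):
        var = unit.copy()
        var[n_cons:] = _kmers.mutate(unit[n_cons:], spec.variant_divergence, rng)
        variants.append(var)
    period = np.concatenate(variants)
    if read_length > period.size:
        # tile the whole period so any window fits
        reps = -(-read_length // period.size) + 1
        ext = np.tile(period, reps)
    else:
        ext = np.concatenate([period, period[: read_length - 1]])
    starts = rng.integers(0, period.size, size=n_reads)
    block = ext[starts[:, None] + np.arange(read_length)]
    if divergence > 0:
        hit = rng.random(block.shape) < divergence
        shift = rng.integers(1, 4, size=block.shape, dtype=np.uint8)
        block = np.where(hit, (block + shift) % 4, block).astype(np.uint8)
    seqs = [_kmers.decode(block[i]) for i in range(n_reads)]
    ids = [f"{species}_{i}" for i in range(n_reads)]
    return ReadSet(ids=ids, seqs=seqs, species=[species] * n_reads)


def simulate_trait(
    tree: dendropy.Tree,
    lam: float,
    sigma2: float,
    root_state: float = 0.0,
    seed: int = 0,
    size: int = 1,
    _salt: str = "trait",
) -> pd.DataFrame:
    """Draw tip values from N(root_state, sigma2 · C_λ).

    Returns a ``size`` × species DataFrame (columns sorted by label).
    """
    from . import comparative

    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must be in [0, 1]")
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    cov = comparative.phylo_vcv(tree)
    tips = cov.tips
    n = len(tips)
    rng = _fork_rng(seed, _salt, salt="trait:")
    if sigma2 == 0.0:
        vals = np.full((size, n), root_state)
        return pd.DataFrame(vals, columns=tips)
    C = comparative.lambda_transform(cov.matrix.to_numpy(), lam) * sigma2
    L = _safe_cholesky(C)
    z = rng.standard_normal((size, n))
    vals = root_state + z @ L.T
    return pd.DataFrame(vals, columns=tips)


def _safe_cholesky(C: np.ndarray) -> np.ndarray:
    jitter = 0.0
    for _ in range(6):
        try:
            return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-12 * float(np.trace(C)) / C.shape[0] or 1e-12)
    raise np.linalg.LinAlgError("covariance matrix is not positive semi-definite")
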