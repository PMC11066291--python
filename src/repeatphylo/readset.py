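"""Read collections with species tags and optional simulation provenance."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class ReadSet:
    """A collection of short reads, each tagged with the species it came from.

    ``families`` is optional provenance kept by the simulator (the repeat
    family each read was emitted from, ``None`` for single-copy background);
    it is never consulted by the clustering itself.
    """

    ids: list[str] = field(default_factory=list)
    seqs: list[str] = field(default_factory=list)
    species: list[str] = field(default_factory=list)
    families: list[str | None] | None = None

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.seqs) == len(self.species)):
            raise ValueError("ids, seqs and species must have equal length")
        if self.families is not None and len(self.families) != len(self.ids):
            raise ValueError("families must match the number of reads")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def species_set(self) -> set[str]:
        return set(self.species)

    def counts_by_species(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.species:
            out[s] = out.get(s, 0) + 1
        return out

    def subset(self, indices: Sequence[int]) -> "ReadSet":
        fam = None
        if self.families is not None:
            fam = [self.families[i] for i in indices]
        return ReadSet(
            ids=[self.ids[i] for i in indices],
            seqs=[self.seqs[i] for i in indices],
            species=[self.species[i] for i in indices],
            families=fam,
        )

    @classmethod
    def concat(cls, readsets: Iterable["ReadSet"]) -> "ReadSet":
        readsets = list(readsets)
        out = cls()
        keep_fam = all(r.families is not None for r in readsets) and readsets
        out.families = [] if keep_fam else None
        for r in readsets:
            out.ids.extend(r.ids)
            out.seqs.extend(r.seqs)
            out.species.extend(r.species)
            if keep_fam:
                out.families.extend(r.families)  # type: ignore[union-attr]
        return out

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_fasta(cls, path: str | Path, species: str | None = None) -> "ReadSet":
        """Load reads from a (optionally gzipped) FASTA/FASTQ file.

        The species tag defaults to the file's stem.
        """
        path = Path(path)
        name = path.name
        opener = gzip.open if name.endswith(".gz") else open
        stem = name
        for suff in (".gz", ".fasta", ".fastq", ".fa", ".fq"):
            if stem.endswith(suff):
                stem = stem[: -len(suff)]
        fmt = "fastq" if ".fastq" in name or ".fq" in name else "fasta"
        tag = species if species is not None else stem
        out = cls()
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, fmt):
                out.ids.append(rec.id)
                out.seqs.append(str(rec.seq).upper())
                out.species.append(tag)
        return out

    def to_fasta(self, path: str | Path) -> None:
        path = Path(path)
        opener = gzip.open if path.name.endswith(".gz") else open
        with opener(path, "wt") as fh:
            SeqIO.write(
                (SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.seqs)),
                fh,
                "fasta",
            )


def pool(readsets: Mapping[str, ReadSet] | Iterable[ReadSet]) -> ReadSet:
    """Pool per-species read sets into a single tagged collection."""
    if isinstance(readsets, Mapping):
        readsets = [readsets[k] for k in sorted(readsets)]
    return ReadSet.concat(readsets)
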