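"""Genome container and sequence/annotation I/O.

A :class:`Genome` is a named, ordered set of chromosome sequences for one
strain, stored as plain upper-case DNA strings. Coordinates are 0-based,
half-open everywhere in this package; conversion to 1-based happens only in
the GFF3 writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Named set of chromosome sequences for one strain."""

    name: str
    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chromosomes = {c: s.upper() for c, s in self.chromosomes.items()}

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes

    def __getitem__(self, chrom: str) -> str:
        return self.chromosomes[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def copy(self, name: str | None = None) -> "Genome":
        return Genome(name or self.name, dict(self.chromosomes))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end)``; bounds are validated."""
        seq = self.chromosomes[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"(length {len(seq)})"
            )
        return seq[start:end]

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_fasta(cls, path: str | Path, name: str | None = None) -> "Genome":
        path = Path(path)
        chroms = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(name or path.stem, chroms)

    def to_fasta(self, path: str | Path) -> None:
        """Write multi-FASTA, 60-column wrapped."""
        records = [
            SeqRecord(Seq(seq), id=chrom, description="")
            for chrom, seq in self.chromosomes.items()
        ]
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")


@dataclass(frozen=True)
class GeneFeature:
    """One gene interval (0-based half-open internally)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


def write_gff3(features: list[GeneFeature], path: str | Path, source: str = "comparome") -> None:
    """Write gene features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id};Name={f.gene_id}"
            fh.write(
                f"{f.chrom}\t{source}\tgene\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[GeneFeature]:
    """Read gene features from GFF3 back into 0-based half-open intervals."""
    feats: list[GeneFeature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "gene":
                continue
            gene_id = ""
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            feats.append(GeneFeature(gene_id, chrom, int(start) - 1, int(end), strand))
    return feats


def read_orf_fasta(path: str | Path) -> dict[str, str]:
    """ORF catalog: FASTA of coding sequences, id -> sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_orf_fasta(orfs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in orfs.items()]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
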