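"""Core sequence containers and FASTA ingest.

A :class:`Contig` is the unit of classification throughout the package: a
nucleotide sequence (uppercase, alphabet ``{A,C,G,T,N}``) with an identifier
and optional provenance. A :class:`Gene` is a called coding region on a
contig, stored in 0-based half-open forward-strand coordinates with the
strand recorded separately (BED-style).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


@dataclass
class Contig:
    """A nucleotide sequence with identifier and provenance metadata."""

    id: str
    sequence: str
    source_assembly: Optional[str] = None
    declared_taxon: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Gene:
    """A called coding region. ``start``/``end`` are 0-based half-open on the
    forward strand regardless of ``strand``; ``nt_seq`` reads in gene
    orientation (reverse-complemented for ``-`` genes) and includes the stop
    codon; ``aa_seq`` is its translation without the stop."""

    contig_id: str
    start: int
    end: int
    strand: str
    nt_seq: str
    aa_seq: str

    def __len__(self) -> int:
        return self.end - self.start


def validate_sequence(seq: str, name: str = "sequence") -> str:
    """Uppercase *seq* and reject characters outside the DNA alphabet."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(
            f"{name} contains characters outside {{A,C,G,T,N}}: {sorted(bad)!r}"
        )
    if not seq:
        raise ValueError(f"{name} is empty")
    return seq


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_orf(nt_seq: str) -> str:
    """Translate an ORF with bacterial (table 11) start-codon semantics: the
    initiator codon becomes M even for GTG/TTG; a trailing stop is dropped."""
    if len(nt_seq) < 3 or len(nt_seq) % 3:
        raise ValueError("ORF length must be a positive multiple of 3")
    aa = str(Seq(nt_seq).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if aa:
        aa = "M" + aa[1:]
    return aa


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a (possibly gzipped) multi-record FASTA into validated contigs.

    Raises on characters outside {A,C,G,T,N} and on duplicate record ids.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    contigs: list[Contig] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = validate_sequence(str(rec.seq), name=f"contig {rec.id!r}")
            contigs.append(Contig(id=rec.id, sequence=seq))
    return contigs


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA (e.g. marker reference) as (id, aa_seq) pairs."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs
    ]
    path = Path(path)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
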