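"""Length- and library-normalized abundances and phage:host ratios.

Input is a per-contig mapped-read count table (sample, contig, role,
mapped reads, contig length), e.g. converted from a mapper's idxstats
output. Per sample and role, reads and lengths are pooled and converted to
an RPKM-style statistic — reads per kilobase of pooled contig length per
million mapped reads in the sample — so a ratio of 1 between phage and
host means equal per-base coverage, i.e. about one phage genome per host
genome (the temperate baseline). Read fractions of the roles sum to 1 per
sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass
class CountRecord:
    sample_id: str
    contig_id: str
    role: str  # phage | host
    mapped_reads: int
    contig_length: int

    def __post_init__(self):
        if self.mapped_reads < 0:
            raise ValueError("mapped_reads must be >= 0")
        if self.contig_length <= 0:
            raise ValueError("contig_length must be positive")


@dataclass
class AbundanceRecord:
    sample_id: str
    role: str
    normalized_abundance: float  # reads / Mreads / kb (RPKM-style)
    read_fraction: float
    mapped_reads: int
    total_length: int


def normalize(records: Sequence[CountRecord]) -> list[AbundanceRecord]:
    """Pooled RPKM-style abundances for one sample.

    Library size is the sum of mapped reads over the sample's records.
    Multi-contig roles (fragmented host chromosomes) are pooled: reads and
    lengths are summed per role before normalization.
    """
    if not records:
        raise ValueError("no count records")
    samples = {r.sample_id for r in records}
    if len(samples) != 1:
        raise ValueError(f"records span multiple samples: {sorted(samples)}")
    library_size = sum(r.mapped_reads for r in records)
    if library_size == 0:
        raise ValueError("library size is zero: no mapped reads in sample")
    sample_id = records[0].sample_id
    out = []
    for role in sorted({r.role for r in records}):
        role_records = [r for r in records if r.role == role]
        reads = sum(r.mapped_reads for r in role_records)
        length = sum(r.contig_length for r in role_records)
        rpkm = reads * 1e6 / library_size / (length / 1e3)
        out.append(
            AbundanceRecord(
                sample_id=sample_id,
                role=role,
                normalized_abundance=rpkm,
                read_fraction=reads / library_size,
                mapped_reads=reads,
                total_length=length,
            )
        )
    return out


def phage_host_ratio(
    abundances: Sequence[AbundanceRecord],
) -> tuple[float, float]:
    """Phage:host abundance ratio and its log10.

    Ratio 1 means equal per-base normalized coverage — one phage genome
    per host genome. A sample without detectable host reads raises
    (reported upstream as ``host_not_detected`` rather than infinity).
    """
    by_role = {a.role: a for a in abundances}
    if "phage" not in by_role or "host" not in by_role:
        missing = sorted({"phage", "host"} - set(by_role))
        raise ValueError(f"missing role(s): {missing}")
    host = by_role["host"].normalized_abundance
    phage = by_role["phage"].normalized_abundance
    if host == 0:
        raise ValueError("host_not_detected")
    if phage == 0:
        raise ValueError("phage_not_detected")
    ratio = phage / host
    return ratio, math.log10(ratio)


def abundance_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample abundance summary from a long count table.

    Expects columns (sample_id, contig_id, role, mapped_reads,
    contig_length); returns one row per sample and role with normalized
    abundance, read fraction and — where both roles are present — the
    phage:host ratio and its log10. Samples without detectable host get
    ``host_not_detected`` in the status column.
    """
    required = {"sample_id", "contig_id", "role", "mapped_reads", "contig_length"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    rows = []
    for sample_id, group in counts.groupby("sample_id", sort=True):
        records = [
            CountRecord(
                sample_id=str(sample_id),
                contig_id=str(r.contig_id),
                role=str(r.role),
                mapped_reads=int(r.mapped_reads),
                contig_length=int(r.contig_length),
            )
            for r in group.itertuples(index=False)
        ]
        abundances = normalize(records)
        try:
            ratio, log10_ratio = phage_host_ratio(abundances)
            status = "ok"
        except ValueError as exc:
            ratio = log10_ratio = float("nan")
            status = str(exc)
        for a in abundances:
            rows.append(
                {
                    "sample_id": a.sample_id,
                    "role": a.role,
                    "normalized_abundance": a.normalized_abundance,
                    "read_fraction": a.read_fraction,
                    "mapped_reads": a.mapped_reads,
                    "total_length": a.total_length,
                    "phage_host_ratio": ratio,
                    "log10_ratio": log10_ratio,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)
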