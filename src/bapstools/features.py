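"""Gene calling and per-gene feature extraction for the triplet classifier.

A contig is turned into an ordered list of genes, each gene into a
fixed-length numeric feature vector (the schema below), and the ordered
vectors into overlapping triplets — a sliding window of three consecutive
genes with stride one. Triplets, not whole contigs, are the training and
scoring unit of the phage-likeness model: they capture local compositional
and organizational signal while keeping the input size independent of
contig length.

Feature schema (version 1), 93 values per gene:

* ``gene_length`` — nucleotides, including the stop codon.
* ``gc`` — G+C fraction of the coding sequence.
* ``gc_skew`` — (G−C)/(G+C), 0 when the gene has no G or C.
* 64 ``codon_*`` — in-frame codon frequencies (sum to 1).
* 20 ``aa_*`` — amino-acid frequencies of the translation (sum to 1).
* ``hydrophobic_frac`` — fraction of A/V/L/I/M/F/W/P residues.
* ``strand_agree_prev`` / ``strand_agree_next`` — 1 if the neighbour gene is
  on the same strand, 0 otherwise (0 at contig ends).
* ``intergenic_prev`` / ``intergenic_next`` — distance in bp to the
  neighbour gene, clipped to [0, 5000] (0 at contig ends).
* ``genes_per_10kb`` — local gene density in a ±5 kb window around the gene
  midpoint, clipped to the contig.

First/last genes take sentinel 0 for neighbour-dependent features so every
vector has the same length.
"""

from __future__ import annotations

import hashlib
from itertools import product
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import Contig, Gene, reverse_complement, translate_orf

SCHEMA_VERSION = "1"

CODONS: tuple[str, ...] = tuple("".join(c) for c in product("ACGT", repeat=3))
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = frozenset("AVLIMFWP")

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
MIN_ORF_NT = 90
INTERGENIC_CLIP = 5000
DENSITY_HALF_WINDOW = 5000

FEATURE_NAMES: tuple[str, ...] = (
    ("gene_length", "gc", "gc_skew")
    + tuple(f"codon_{c}" for c in CODONS)
    + tuple(f"aa_{a}" for a in AMINO_ACIDS)
    + (
        "hydrophobic_frac",
        "strand_agree_prev",
        "strand_agree_next",
        "intergenic_prev",
        "intergenic_next",
        "genes_per_10kb",
    )
)

N_FEATURES = len(FEATURE_NAMES)

TRIPLET_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"g{i}_{name}" for i in (1, 2, 3) for name in FEATURE_NAMES
)

_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def schema_hash() -> str:
    """Stable digest of the feature schema; models refuse mismatched data."""
    payload = (SCHEMA_VERSION + "\n" + "\n".join(FEATURE_NAMES)).encode()
    return hashlib.sha256(payload).hexdigest()


def write_schema_sidecar(path) -> None:
    """Write the schema as a TSV sidecar (name, index, description)."""
    rows = [
        {"index": i, "name": n, "schema_version": SCHEMA_VERSION}
        for i, n in enumerate(FEATURE_NAMES)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene calling
# ---------------------------------------------------------------------------

def _scan_frames(seq: str):
    """Yield (start, end) ORFs on the forward frames of *seq*.

    An ORF runs from the first start codon after the previous in-frame stop
    to the next in-frame stop (stop included). Codons containing ambiguous
    bases break any open ORF without emitting a gene. ORFs shorter than
    MIN_ORF_NT and ORFs without a terminating stop are discarded, which
    makes selection within a frame trivially non-overlapping.
    """
    n = len(seq)
    for frame in range(3):
        orf_start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon not in _CODON_INDEX:  # ambiguous base
                orf_start = None
                continue
            if codon in STOP_CODONS:
                if orf_start is not None and pos + 3 - orf_start >= MIN_ORF_NT:
                    yield orf_start, pos + 3
                orf_start = None
            elif orf_start is None and codon in START_CODONS:
                orf_start = pos


def scan_orfs(contig: Contig) -> list[Gene]:
    """Bundled six-frame naive ORF caller (the default gene-caller).

    Deterministic and dependency-free; an external Prodigal-compatible
    caller may be plugged into :func:`call_genes` behind the same contract.
    """
    seq = contig.sequence
    n = len(seq)
    genes: list[Gene] = []
    for start, end in _scan_frames(seq):
        nt = seq[start:end]
        genes.append(
            Gene(contig.id, start, end, "+", nt, translate_orf(nt))
        )
    rc = reverse_complement(seq)
    for start, end in _scan_frames(rc):
        nt = rc[start:end]
        genes.append(
            Gene(contig.id, n - end, n - start, "-", nt, translate_orf(nt))
        )
    genes.sort(key=lambda g: (g.start, g.end, g.strand))
    return genes


def call_genes(
    contig: Contig,
    caller: Optional[Callable[[Contig], list[Gene]]] = None,
) -> list[Gene]:
    """Call genes on *contig* with *caller* (default: bundled ORF scanner).

    The caller contract: takes a Contig, returns Genes sorted by start
    satisfying the Gene invariants; overlap between genes is permitted.
    """
    if not contig.sequence:
        raise ValueError(f"contig {contig.id!r} has an empty sequence")
    bad = set(contig.sequence) - frozenset("ACGTN")
    if bad:
        raise ValueError(
            f"contig {contig.id!r} contains characters outside "
            f"{{A,C,G,T,N}}: {sorted(bad)!r}"
        )
    genes = (caller or scan_orfs)(contig)
    return sorted(genes, key=lambda g: (g.start, g.end, g.strand))


# ---------------------------------------------------------------------------
# Per-gene features
# ---------------------------------------------------------------------------

def compute_gene_features(
    gene: Gene,
    prev_gene: Optional[Gene],
    next_gene: Optional[Gene],
    contig: Contig,
    local_density: Optional[float] = None,
) -> np.ndarray:
    """Feature vector for one gene given its immediate neighbours.

    ``local_density`` (genes per 10 kb around the gene midpoint) is computed
    by :func:`gene_feature_table` from the full gene list; passing None here
    stores 0.
    """
    nt = gene.nt_seq
    if len(nt) < 3:
        raise ValueError("gene shorter than one codon")
    g = nt.count("G")
    c = nt.count("C")
    gc = (g + c) / len(nt)
    skew = (g - c) / (g + c) if (g + c) else 0.0

    vec = np.zeros(N_FEATURES)
    vec[0] = len(nt)
    vec[1] = gc
    vec[2] = skew

    codon_counts = np.zeros(64)
    for i in range(0, len(nt) - 2, 3):
        idx = _CODON_INDEX.get(nt[i : i + 3])
        if idx is not None:
            codon_counts[idx] += 1
    total = codon_counts.sum()
    if total:
        vec[3:67] = codon_counts / total

    aa_counts = np.zeros(20)
    hydro = 0
    for a in gene.aa_seq:
        idx = _AA_INDEX.get(a)
        if idx is not None:
            aa_counts[idx] += 1
        if a in HYDROPHOBIC:
            hydro += 1
    n_aa = len(gene.aa_seq)
    if n_aa:
        vec[67:87] = aa_counts / n_aa
        vec[87] = hydro / n_aa

    if prev_gene is not None:
        vec[88] = 1.0 if prev_gene.strand == gene.strand else 0.0
        vec[90] = min(max(gene.start - prev_gene.end, 0), INTERGENIC_CLIP)
    if next_gene is not None:
        vec[89] = 1.0 if next_gene.strand == gene.strand else 0.0
        vec[91] = min(max(next_gene.start - gene.end, 0), INTERGENIC_CLIP)
    vec[92] = local_density if local_density is not None else 0.0
    return vec


def _local_densities(genes: Sequence[Gene], contig_len: int) -> np.ndarray:
    mids = np.array([(g.start + g.end) / 2 for g in genes])
    dens = np.zeros(len(genes))
    for i, m in enumerate(mids):
        lo = max(0.0, m - DENSITY_HALF_WINDOW)
        hi = min(float(contig_len), m + DENSITY_HALF_WINDOW)
        count = int(((mids >= lo) & (mids < hi)).sum())
        window_kb10 = (hi - lo) / 1e4
        dens[i] = count / window_kb10 if window_kb10 else 0.0
    return dens


def gene_feature_table(contig: Contig, genes: Sequence[Gene]) -> pd.DataFrame:
    """Per-gene feature rows for one contig, ordered by gene start."""
    if not genes:
        return pd.DataFrame(columns=FEATURE_NAMES)
    dens = _local_densities(genes, len(contig))
    rows = []
    for i, gene in enumerate(genes):
        prev_gene = genes[i - 1] if i > 0 else None
        next_gene = genes[i + 1] if i < len(genes) - 1 else None
        rows.append(
            compute_gene_features(gene, prev_gene, next_gene, contig, dens[i])
        )
    df = pd.DataFrame(np.vstack(rows), columns=FEATURE_NAMES)
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError(f"non-finite feature value on contig {contig.id!r}")
    return df


# ---------------------------------------------------------------------------
# Triplets
# ---------------------------------------------------------------------------

def build_triplets(rows: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Sliding window of three consecutive gene rows, stride 1.

    ``n`` gene rows yield ``max(0, n - 2)`` triplet rows; row *i*
    concatenates gene features *i*, *i+1*, *i+2* in order.
    """
    arr = np.asarray(rows, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(0, N_FEATURES) if arr.size == 0 else arr.reshape(1, -1)
    n = arr.shape[0]
    if n < 3:
        return np.empty((0, 3 * N_FEATURES))
    if arr.shape[1] != N_FEATURES:
        raise ValueError(
            f"expected {N_FEATURES} features per gene row, got {arr.shape[1]}"
        )
    return np.hstack([arr[:-2], arr[1:-1], arr[2:]])


def contig_triplets(
    contig: Contig,
    caller: Optional[Callable[[Contig], list[Gene]]] = None,
) -> tuple[np.ndarray, int]:
    """Call genes, featurize and window: returns (triplet matrix, n_genes)."""
    genes = call_genes(contig, caller)
    table = gene_feature_table(contig, genes)
    return build_triplets(table), len(genes)
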