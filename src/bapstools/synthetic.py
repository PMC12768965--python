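"""Seeded synthetic genomes with known ground truth.

Real phage discovery runs on millions of downloaded assemblies; every
other module in this package is instead exercised on synthetic genomes
whose true class, gene coordinates, markers, cluster structure and copy
numbers are constructed, so correctness can be asserted exactly.

Two compositional classes are generated: ``phage_like`` and ``host_like``
genomes differing in codon usage (Dirichlet-perturbed tables with
class-specific seeds), GC content (0.42 vs 0.52), gene density (shorter
intergenic gaps for phage-like genomes) — a learnable, documented signal
for the triplet classifier that makes no claim of biological fidelity.
Toy lifestyle-marker genes (terL, integrase, transposase, anti-repressor)
are synthetic amino-acid sequences, explicitly NOT real phage proteins;
they exist to exercise the rule machinery.

Everything is byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .cascade import AnnotationHit, MarkerProfile, screen_markers
from .core import Contig
from .features import CODONS, STOP_CODONS, call_genes
from .phager import ContigScore
from .abundance import CountRecord

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

# aa -> synonymous codon map from the bacterial code
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _tables[11].forward_table.items():
    if set(_codon) <= set("ACGT"):
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _AA_TO_CODONS:
    _AA_TO_CODONS[_aa].sort()

DEFAULT_GENOME_LENGTH = 20_000
MIN_GENOME_LENGTH = 1_000


@dataclass
class CompositionModel:
    """A compositional genome class: codon usage, GC, gene geometry."""

    name: str
    codon_probs: np.ndarray  # over SENSE_CODONS, sums to 1
    gc_target: float
    gene_len_mu: float = float(np.log(800.0))
    gene_len_sigma: float = 0.35
    gap_mean: float = 80.0

    def __post_init__(self):
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must be in (0, 1)")
        if not np.isclose(self.codon_probs.sum(), 1.0):
            raise ValueError("codon probabilities must sum to 1")


def _gc_biased_codon_probs(gc_target: float) -> np.ndarray:
    """Sense-codon distribution whose expected GC equals *gc_target*,
    obtained by exponential tilting of the uniform table."""
    gc_counts = np.array([c.count("G") + c.count("C") for c in SENSE_CODONS])

    def gap(bias: float) -> float:
        w = np.exp(bias * gc_counts)
        p = w / w.sum()
        return float((p * gc_counts).sum() / 3.0) - gc_target

    bias = brentq(gap, -8.0, 8.0)
    w = np.exp(bias * gc_counts)
    return w / w.sum()


def make_composition_model(
    name: str,
    gc_target: float,
    usage_seed: int,
    concentration: float = 60.0,
    gap_mean: float = 80.0,
    gene_len_mu: float = float(np.log(800.0)),
    gene_len_sigma: float = 0.35,
) -> CompositionModel:
    """Build a class model: GC-tilted codon table, Dirichlet-perturbed with
    a class-specific seed so all genomes of the class share the bias."""
    base = _gc_biased_codon_probs(gc_target)
    rng = np.random.default_rng(usage_seed)
    probs = rng.dirichlet(base * concentration)
    # re-tilt the perturbed table so expected GC is pinned to the target:
    # class codon bias and GC stay independent knobs
    gc_counts = np.array([c.count("G") + c.count("C") for c in SENSE_CODONS])

    def gap(bias: float) -> float:
        w = probs * np.exp(bias * gc_counts)
        p = w / w.sum()
        return float((p * gc_counts).sum() / 3.0) - gc_target

    bias = brentq(gap, -8.0, 8.0)
    probs = probs * np.exp(bias * gc_counts)
    probs /= probs.sum()
    return CompositionModel(
        name=name,
        codon_probs=probs,
        gc_target=gc_target,
        gap_mean=gap_mean,
        gene_len_mu=gene_len_mu,
        gene_len_sigma=gene_len_sigma,
    )


@lru_cache(maxsize=None)
def phage_like_model() -> CompositionModel:
    """Default phage-like class: AT-rich, densely coded."""
    return make_composition_model(
        "phage_like", gc_target=0.42, usage_seed=101, gap_mean=40.0
    )


@lru_cache(maxsize=None)
def host_like_model() -> CompositionModel:
    """Default host-like class: higher GC, sparser gene spacing."""
    return make_composition_model(
        "host_like", gc_target=0.52, usage_seed=202, gap_mean=160.0
    )


def make_model_pair(divergence: float = 1.0) -> tuple[CompositionModel, CompositionModel]:
    """Model pair with tunable inter-class divergence in [0, 1].

    At 1 the defaults are returned; toward 0 both codon tables and GC
    targets are pulled to their midpoint, shrinking the learnable signal.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    p, h = phage_like_model(), host_like_model()
    mid_probs = (p.codon_probs + h.codon_probs) / 2.0
    mid_gap = (p.gap_mean + h.gap_mean) / 2.0

    def blend(model: CompositionModel) -> CompositionModel:
        probs = divergence * model.codon_probs + (1 - divergence) * mid_probs
        realized_gc = float(
            (probs * np.array([c.count("G") + c.count("C") for c in SENSE_CODONS])).sum() / 3
        )
        return CompositionModel(
            name=model.name,
            codon_probs=probs / probs.sum(),
            gc_target=realized_gc,
            gap_mean=divergence * model.gap_mean + (1 - divergence) * mid_gap,
            gene_len_mu=model.gene_len_mu,
            gene_len_sigma=model.gene_len_sigma,
        )

    return blend(p), blend(h)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def generate_genome(
    model: CompositionModel,
    length: int,
    seed: int,
    contig_id: Optional[str] = None,
) -> Contig:
    """Generate one genome: genes drawn from the model's codon table,
    separated by sampled intergenic gaps, padded to exactly *length* bp.

    True gene coordinates (0-based half-open, all forward strand) are
    stored in ``contig.meta['true_genes']`` for feature-extraction tests.
    """
    if length < MIN_GENOME_LENGTH:
        raise ValueError(f"length must be >= {MIN_GENOME_LENGTH}")
    rng = np.random.default_rng(seed)
    codons = np.array(SENSE_CODONS)
    pieces: list[str] = []
    true_genes: list[tuple[int, int, str]] = []
    pos = 0
    while True:
        gap = int(rng.exponential(model.gap_mean))
        gene_nt = int(rng.lognormal(model.gene_len_mu, model.gene_len_sigma))
        gene_nt = max(90, min(3000, gene_nt - gene_nt % 3))
        if pos + gap + gene_nt > length:
            break
        pieces.append(_random_bases(rng, gap, model.gc_target))
        pos += gap
        n_internal = gene_nt // 3 - 2
        internal = "".join(rng.choice(codons, size=n_internal, p=model.codon_probs))
        pieces.append("ATG" + internal + "TAA")
        true_genes.append((pos, pos + gene_nt, "+"))
        pos += gene_nt
    pieces.append(_random_bases(rng, length - pos, model.gc_target))
    contig = Contig(
        id=contig_id or f"{model.name}_seed{seed}",
        sequence="".join(pieces),
        meta={"model": model.name, "true_genes": true_genes, "seed": seed},
    )
    assert len(contig) == length
    return contig


def random_genome(length: int, seed: int, contig_id: str = "random") -> Contig:
    """Uniform random DNA, no constructed genes (null background)."""
    rng = np.random.default_rng(seed)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytes(lut[rng.integers(0, 4, size=length)]).decode()
    return Contig(id=contig_id, sequence=seq, meta={"seed": seed})


def mutate_sequence(sequence: str, rate: float, seed: int) -> str:
    """Seeded per-base substitution at the given rate (always to a
    different base)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def make_training_contigs(
    model: CompositionModel,
    n: int,
    length: int = DEFAULT_GENOME_LENGTH,
    seed: int = 0,
) -> list[Contig]:
    """n genomes of one class with per-genome seeds derived from *seed*."""
    child_seeds = np.random.SeedSequence(seed).generate_state(n)
    return [
        generate_genome(
            model, length, int(s) % (2**31), contig_id=f"{model.name}_{seed}_{i}"
        )
        for i, s in enumerate(child_seeds)
    ]


def codon_usage(contig: Contig) -> np.ndarray:
    """Sense-codon frequency vector over the contig's true genes."""
    counts = np.zeros(len(SENSE_CODONS))
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    for start, end, _ in contig.meta.get("true_genes", []):
        gene = contig.sequence[start:end]
        for i in range(0, len(gene) - 2, 3):
            idx = index.get(gene[i : i + 3])
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    return counts / total if total else counts


# ---------------------------------------------------------------------------
# Toy markers
# ---------------------------------------------------------------------------

@dataclass
class ToyMarker:
    marker_class: str
    marker_id: str
    aa_seq: str
    nt_seq: str  # in-frame ORF: ATG ... TAA


_MARKER_SEEDS = {
    "terL": 9001,
    "integrase": 9002,
    "transposase": 9003,
    "anti_repressor": 9004,
}


@lru_cache(maxsize=None)
def toy_markers() -> tuple[ToyMarker, ...]:
    """Four synthetic marker genes (NOT real phage proteins), one per
    lifestyle-marker class, with deterministic sequences."""
    aa_alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    markers = []
    for marker_class, seed in _MARKER_SEEDS.items():
        rng = np.random.default_rng(seed)
        aa = "M" + "".join(rng.choice(aa_alphabet, size=179))
        nt = "".join(
            _AA_TO_CODONS[a][int(rng.integers(0, len(_AA_TO_CODONS[a])))]
            for a in aa
        ) + "TAA"
        markers.append(
            ToyMarker(marker_class, f"toy_{marker_class}", aa, nt)
        )
    return tuple(markers)


def toy_marker_ref() -> list[tuple[str, str, str]]:
    """Marker reference in the (class, id, aa_seq) form screen_markers
    expects."""
    return [(m.marker_class, m.marker_id, m.aa_seq) for m in toy_markers()]


def implant_marker(contig: Contig, marker: ToyMarker, position: int) -> Contig:
    """Insert a marker ORF at an intergenic *position* (0-based offset).

    The position must not fall strictly inside a true gene; the returned
    contig is longer by the marker length and carries updated true-gene
    coordinates including the implant.
    """
    if not 0 <= position <= len(contig):
        raise ValueError(f"position {position} out of bounds")
    true_genes = list(contig.meta.get("true_genes", []))
    for start, end, _ in true_genes:
        if start < position < end:
            raise ValueError(
                f"position {position} is inside gene ({start}, {end})"
            )
    ins = marker.nt_seq
    new_genes = []
    for start, end, strand in true_genes:
        if start >= position:
            new_genes.append((start + len(ins), end + len(ins), strand))
        else:
            new_genes.append((start, end, strand))
    new_genes.append((position, position + len(ins), "+"))
    new_genes.sort()
    meta = dict(contig.meta)
    meta["true_genes"] = new_genes
    meta.setdefault("implants", []).append((marker.marker_class, position))
    meta["implants"] = list(meta["implants"])
    return Contig(
        id=contig.id,
        sequence=contig.sequence[:position] + ins + contig.sequence[position:],
        source_assembly=contig.source_assembly,
        declared_taxon=contig.declared_taxon,
        meta=meta,
    )


def _intergenic_position(contig: Contig, after_gene: int = 1) -> int:
    """A legal implant position: the end of the given true gene."""
    genes = contig.meta.get("true_genes", [])
    if len(genes) <= after_gene:
        return len(contig)
    return genes[after_gene][1]


# ---------------------------------------------------------------------------
# Read-count simulation
# ---------------------------------------------------------------------------

def simulate_counts(
    entries: Sequence[tuple[str, str, int, float]],
    libsize: int,
    seed: int,
    sample_id: str = "sim",
) -> list[CountRecord]:
    """Multinomial read allocation proportional to copy_number × length.

    *entries* are ``(contig_id, role, length_bp, copy_number)`` tuples.
    """
    if libsize <= 0:
        raise ValueError("libsize must be positive")
    if not entries:
        raise ValueError("no entries")
    for cid, role, length, copy in entries:
        if copy <= 0:
            raise ValueError(f"copy number for {cid!r} must be > 0")
        if length <= 0:
            raise ValueError(f"length for {cid!r} must be > 0")
    rng = np.random.default_rng(seed)
    weights = np.array([length * copy for _, _, length, copy in entries], dtype=float)
    counts = rng.multinomial(libsize, weights / weights.sum())
    return [
        CountRecord(
            sample_id=sample_id,
            contig_id=cid,
            role=role,
            mapped_reads=int(c),
            contig_length=int(length),
        )
        for (cid, role, length, copy), c in zip(entries, counts)
    ]


# ---------------------------------------------------------------------------
# Mutated reference family (two-tier matching fixture)
# ---------------------------------------------------------------------------

def mutated_family(
    seed: int = 11,
    n_copies: int = 5,
    n_unrelated: int = 5,
    length: int = DEFAULT_GENOME_LENGTH,
    rate: float = 0.02,
) -> tuple[Contig, list[Contig], list[Contig]]:
    """A reference genome, *n_copies* seeded ~2%-diverged copies, and
    *n_unrelated* random genomes — the ground truth for reference-set
    matching."""
    ref = generate_genome(phage_like_model(), length, seed, contig_id="ref")
    copies = [
        Contig(
            id=f"copy_{i}",
            sequence=mutate_sequence(ref.sequence, rate, seed * 1000 + i),
        )
        for i in range(n_copies)
    ]
    unrelated = [
        random_genome(length, seed * 2000 + i, contig_id=f"unrelated_{i}")
        for i in range(n_unrelated)
    ]
    return ref, copies, unrelated


# ---------------------------------------------------------------------------
# The 12-contig cascade fixture
# ---------------------------------------------------------------------------

@dataclass
class FixtureSuite:
    """Contigs plus evidence tables and constructed expected labels,
    covering every branch of the classification cascade."""

    contigs: list[Contig]
    expected_labels: dict[str, str]
    expected_stages: dict[str, str]
    scores: dict[str, ContigScore]
    hits: dict[str, list[AnnotationHit]]
    clusters: dict[str, str]
    profiles: dict[str, MarkerProfile]
    seed: int


def _hit(query, subject, subj_len, aln_len, ident, desc, db="nucleotide_ref"):
    return AnnotationHit(
        query_id=query,
        subject_id=subject,
        subject_length=subj_len,
        alignment_length=aln_len,
        percent_identity=ident,
        subject_description=desc,
        source_db=db,
    )


def make_fixture_suite(seed: int = 7) -> FixtureSuite:
    """Twelve contigs exercising every cascade branch, with known labels.

    Branches: megabase contig (bacterial by length), short contig, score
    below the gate, bacterial reference hit, plasmid keyword, 'prophage'
    keyword trap, phage-db match with terL (lytic), terL+integrase
    (temperate), an integrase cluster-propagation pair, terL+transposase
    (undetermined), markerless (undetermined), and a contig with too few
    genes to score.
    """
    ss = np.random.SeedSequence(seed).generate_state(16)
    sub = [int(s) % (2**31) for s in ss]
    phage, host = phage_like_model(), host_like_model()
    markers = {m.marker_class: m for m in toy_markers()}
    L = DEFAULT_GENOME_LENGTH

    contigs: list[Contig] = []
    contigs.append(random_genome(1_050_000, sub[0], "c01_megabase"))
    contigs.append(random_genome(4_000, sub[1], "c02_short"))
    contigs.append(generate_genome(host, L, sub[2], "c03_lowscore"))
    contigs.append(generate_genome(host, L, sub[3], "c04_bacterial_hit"))
    contigs.append(generate_genome(host, L, sub[4], "c05_plasmid_kw"))
    contigs.append(generate_genome(phage, L, sub[5], "c06_prophage_trap"))

    c07 = generate_genome(phage, L, sub[6], "c07_lytic")
    c07 = implant_marker(c07, markers["terL"], _intergenic_position(c07, 1))
    contigs.append(c07)

    c08 = generate_genome(phage, L, sub[7], "c08_temperate")
    c08 = implant_marker(c08, markers["terL"], _intergenic_position(c08, 1))
    c08 = implant_marker(c08, markers["integrase"], _intergenic_position(c08, 3))
    contigs.append(c08)

    c09 = generate_genome(phage, L, sub[8], "c09_cluster_integrase")
    c09 = implant_marker(c09, markers["integrase"], _intergenic_position(c09, 1))
    contigs.append(c09)

    c10 = generate_genome(phage, L, sub[9], "c10_cluster_clean")
    c10 = implant_marker(c10, markers["terL"], _intergenic_position(c10, 1))
    contigs.append(c10)

    c11 = generate_genome(phage, L, sub[10], "c11_transposase")
    c11 = implant_marker(c11, markers["terL"], _intergenic_position(c11, 1))
    c11 = implant_marker(c11, markers["transposase"], _intergenic_position(c11, 3))
    contigs.append(c11)

    contigs.append(Contig(id="c12_fewgenes", sequence="TTAA" * 1500))

    # constructed evidence tables --------------------------------------------
    scores = {c.id: ContigScore(c.id, 0.9, 40, "ok") for c in contigs}
    scores["c03_lowscore"] = ContigScore("c03_lowscore", 0.3, 40, "ok")
    scores["c12_fewgenes"] = ContigScore("c12_fewgenes", 0.0, 0, "too_few_genes")

    hits = {
        "c04_bacterial_hit": [
            _hit("c04_bacterial_hit", "NZ_CHR1", 1_500_000, 3_000, 99.1,
                 "Salmonella enterica chromosome, complete genome"),
        ],
        "c05_plasmid_kw": [
            _hit("c05_plasmid_kw", "NC_PLS1", 94_000, 5_000, 98.0,
                 "Salmonella enterica plasmid pSLT"),
        ],
        "c06_prophage_trap": [
            _hit("c06_prophage_trap", "NZ_PRO1", 52_000, 1_200, 92.0,
                 "Escherichia prophage region"),
        ],
        "c07_lytic": [
            _hit("c07_lytic", "PHDB_S16", 20_500, 18_000, 97.0,
                 "Salmonella phage S16", db="phage_db"),
        ],
    }

    clusters = {
        "c09_cluster_integrase": "cloud1",
        "c10_cluster_clean": "cloud1",
    }

    marker_ref = toy_marker_ref()
    profiles = {}
    for contig in contigs:
        if contig.id in {
            "c06_prophage_trap", "c07_lytic", "c08_temperate",
            "c09_cluster_integrase", "c10_cluster_clean", "c11_transposase",
        }:
            aa_seqs = [g.aa_seq for g in call_genes(contig)]
            profiles[contig.id] = screen_markers(
                aa_seqs, marker_ref, contig_id=contig.id
            )

    expected_labels = {
        "c01_megabase": "bacterial",
        "c02_short": "non_candidate",
        "c03_lowscore": "non_candidate",
        "c04_bacterial_hit": "bacterial",
        "c05_plasmid_kw": "plasmid",
        "c06_prophage_trap": "phage_like_undetermined",
        "c07_lytic": "lytic",
        "c08_temperate": "temperate",
        "c09_cluster_integrase": "temperate",
        "c10_cluster_clean": "temperate",
        "c11_transposase": "phage_like_undetermined",
        "c12_fewgenes": "non_candidate",
    }
    expected_stages = {
        "c01_megabase": "length_gate",
        "c02_short": "length_gate",
        "c03_lowscore": "phager_gate",
        "c04_bacterial_hit": "hits",
        "c05_plasmid_kw": "hits",
        "c06_prophage_trap": "lifestyle",
        "c07_lytic": "lifestyle",
        "c08_temperate": "lifestyle",
        "c09_cluster_integrase": "lifestyle",
        "c10_cluster_clean": "lifestyle",
        "c11_transposase": "lifestyle",
        "c12_fewgenes": "phager_gate",
    }
    return FixtureSuite(
        contigs=contigs,
        expected_labels=expected_labels,
        expected_stages=expected_stages,
        scores=scores,
        hits=hits,
        clusters=clusters,
        profiles=profiles,
        seed=seed,
    )
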