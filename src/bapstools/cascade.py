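"""The BAPS classification cascade.

Every candidate contig from a bacterial assembly receives exactly one label:

* ``non_candidate`` — outside the size window or below the phage-likeness
  gate;
* ``bacterial`` — megabase-scale contigs, or contigs whose top reference hit
  is a long bacterial chromosome;
* ``plasmid`` — reference hit described as a plasmid;
* ``temperate`` — integrase evidence, either on the contig or anywhere in
  its ANI cluster (one integrase taints the whole cloud);
* ``lytic`` — terminase large subunit (terL) present and no lysogeny
  marker (integrase, transposase, anti-repressor) on the contig or in its
  cluster;
* ``phage_like_undetermined`` — phage-like but neither rule fires.

Rules are applied in a fixed order (length gate → score gate → reference
hits → lifestyle markers) and each label records the stage that fired, so
any classification can be traced to a single documented rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import Contig
from .phager import ContigScore, DEFAULT_GATE

MIN_CANDIDATE_BP = 5_000
MAX_CANDIDATE_BP = 1_000_000
BACTERIAL_SUBJECT_BP = 1_200_000
BACTERIAL_ALIGNMENT_BP = 2_100

MARKER_CLASSES = ("terL", "integrase", "transposase", "anti_repressor")

LABELS = (
    "non_candidate",
    "bacterial",
    "plasmid",
    "temperate",
    "lytic",
    "phage_like_undetermined",
)


@dataclass
class AnnotationHit:
    """One reference-database alignment for a query contig.

    ``source_db`` distinguishes the general nucleotide reference from
    dedicated phage databases, whose hits directly suggest a phage.
    Hit lists are expected sorted best-first (bit-score descending,
    supplied upstream by the search tool).
    """

    query_id: str
    subject_id: str
    subject_length: int
    alignment_length: int
    percent_identity: float
    subject_description: str = ""
    source_db: str = "nucleotide_ref"  # nucleotide_ref | phage_db


@dataclass
class MarkerProfile:
    contig_id: str
    has_terL: bool = False
    has_integrase: bool = False
    has_transposase: bool = False
    has_anti_repressor: bool = False
    evidence: list = field(default_factory=list)  # (marker, gene id, method)


@dataclass
class ClassLabel:
    contig_id: str
    label: str
    stage: str
    cluster_id: Optional[str] = None
    score: Optional[float] = None


# ---------------------------------------------------------------------------
# Individual rules
# ---------------------------------------------------------------------------

def length_gate(contig_or_length) -> str:
    """Size window for phage candidacy.

    Contigs exceeding 1 Mb are flagged as true bacterial chromosomes
    (strictly greater); contigs under 5 kb are too short to be complete
    phage genomes. Both window boundaries are inclusive candidates.
    """
    n = (
        len(contig_or_length)
        if isinstance(contig_or_length, Contig)
        else int(contig_or_length)
    )
    if n > MAX_CANDIDATE_BP:
        return "bacterial"
    if n < MIN_CANDIDATE_BP:
        return "non_candidate"
    return "candidate"


def phager_gate(score, threshold: float = DEFAULT_GATE) -> str:
    """Phage-likeness gate: scores strictly below the threshold fail."""
    value = score.score if isinstance(score, ContigScore) else float(score)
    return "pass" if value >= threshold else "fail"


def classify_by_hits(hits: Sequence[AnnotationHit]) -> str:
    """Reference-hit annotation for one contig (rules in precedence order).

    1. bacterial — the top nucleotide-reference hit is to a subject longer
       than 1.2 Mb with an alignment longer than 2,100 bp;
    2. plasmid — any hit description containing 'plasmid';
    3. phage_db_match — any hit from a phage database, or a description
       containing 'phage' but not 'prophage' ('prophage' always suppresses);
    4. no_call — no rule fired (including the empty hit list).

    Keyword matching is case-insensitive whole-string containment.
    """
    hits = list(hits)
    if hits:
        top = hits[0]
        if (
            top.source_db == "nucleotide_ref"
            and top.subject_length > BACTERIAL_SUBJECT_BP
            and top.alignment_length > BACTERIAL_ALIGNMENT_BP
        ):
            return "bacterial"
    for h in hits:
        if "plasmid" in h.subject_description.lower():
            return "plasmid"
    for h in hits:
        desc = h.subject_description.lower()
        if h.source_db == "phage_db":
            return "phage_db_match"
        if "phage" in desc and "prophage" not in desc:
            return "phage_db_match"
    return "no_call"


# ---------------------------------------------------------------------------
# Marker screening
# ---------------------------------------------------------------------------

def _aa_kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def screen_markers(
    gene_aa_seqs: Sequence[str],
    marker_ref: Sequence[tuple[str, str, str]],
    contig_id: str = "",
    k: int = 5,
    floor: float = 0.5,
) -> MarkerProfile:
    """Flag lifestyle markers among a contig's predicted proteins.

    *marker_ref* is a list of ``(marker_class, marker_id, aa_seq)`` records
    (e.g. parsed from a marker FASTA). A gene carries a marker when the
    fraction of the marker's amino-acid k-mers contained in the gene's
    k-mer set reaches *floor* — a dependency-free containment screen; a
    precomputed hit table from an HMM tool can be used instead via
    :func:`profiles_from_hit_table`. Marker classes outside the four known
    ones are treated as additional lysogeny markers and behave like
    integrase (exclusionary).
    """
    if not marker_ref:
        raise ValueError("empty marker reference")
    profile = MarkerProfile(contig_id=contig_id)
    gene_kmer_sets = [
        (i, _aa_kmers(aa, k)) for i, aa in enumerate(gene_aa_seqs)
    ]
    for marker_class, marker_id, marker_aa in marker_ref:
        mk = _aa_kmers(marker_aa, k)
        if not mk:
            continue
        for gene_idx, gk in gene_kmer_sets:
            containment = len(mk & gk) / len(mk)
            if containment >= floor:
                profile.evidence.append(
                    (marker_class, f"gene_{gene_idx}", "kmer_containment")
                )
                if marker_class == "terL":
                    profile.has_terL = True
                elif marker_class == "transposase":
                    profile.has_transposase = True
                elif marker_class == "anti_repressor":
                    profile.has_anti_repressor = True
                else:  # integrase and any extra lysogeny-marker class
                    profile.has_integrase = True
                break
    return profile


def profiles_from_hit_table(table: pd.DataFrame) -> dict[str, MarkerProfile]:
    """Build profiles from a precomputed marker hit table with columns
    (contig_id, marker, gene_id, method). One row per marker hit."""
    profiles: dict[str, MarkerProfile] = {}
    for row in table.itertuples(index=False):
        prof = profiles.setdefault(row.contig_id, MarkerProfile(row.contig_id))
        prof.evidence.append((row.marker, row.gene_id, row.method))
        if row.marker == "terL":
            prof.has_terL = True
        elif row.marker == "transposase":
            prof.has_transposase = True
        elif row.marker == "anti_repressor":
            prof.has_anti_repressor = True
        else:
            prof.has_integrase = True
    return profiles


# ---------------------------------------------------------------------------
# Lifestyle rules
# ---------------------------------------------------------------------------

def propagate_temperate(
    clusters: Mapping[str, str],
    profiles: Mapping[str, MarkerProfile],
) -> set[str]:
    """All members of every cluster with at least one integrase member.

    Contigs absent from the cluster map are singletons. A single integrase
    anywhere in a cluster labels the whole cluster temperate.
    """
    members: dict[str, list[str]] = {}
    for contig_id, profile in profiles.items():
        cluster = clusters.get(contig_id, f"__singleton__{contig_id}")
        members.setdefault(cluster, []).append(contig_id)
    tainted: set[str] = set()
    for cluster, ids in members.items():
        if any(profiles[c].has_integrase for c in ids):
            tainted.update(ids)
    return tainted


def assign_lifestyle(
    profile: MarkerProfile, is_temperate_by_cluster: bool
) -> str:
    """Lifestyle call for a phage-like contig.

    temperate: integrase on the contig or anywhere in its cluster.
    lytic: terL present, and none of integrase / transposase /
    anti-repressor, and the cluster is clean.
    Anything else: phage_like_undetermined.
    """
    if is_temperate_by_cluster or profile.has_integrase:
        return "temperate"
    if profile.has_terL and not (
        profile.has_transposase or profile.has_anti_repressor
    ):
        return "lytic"
    return "phage_like_undetermined"


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_cascade(
    contigs: Sequence[Contig],
    scores: Mapping[str, ContigScore | float],
    hits: Mapping[str, Sequence[AnnotationHit]],
    clusters: Mapping[str, str],
    profiles: Mapping[str, MarkerProfile],
    threshold: float = DEFAULT_GATE,
) -> tuple[list[ClassLabel], dict]:
    """Run the whole decision workflow over a set of contigs.

    Stage order: length gate → phage-likeness gate → reference-hit
    annotation (bacterial, plasmid removed) → cluster-wide temperate
    propagation → lifestyle assignment. Every contig receives exactly one
    label; the returned summary counts labels and records the thresholds.
    """
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids: {dupes[:5]}")

    labels: dict[str, ClassLabel] = {}
    survivors: list[Contig] = []
    for contig in contigs:
        gate = length_gate(contig)
        if gate == "bacterial":
            labels[contig.id] = ClassLabel(contig.id, "bacterial", "length_gate")
            continue
        if gate == "non_candidate":
            labels[contig.id] = ClassLabel(
                contig.id, "non_candidate", "length_gate"
            )
            continue
        raw = scores.get(contig.id, 0.0)
        value = raw.score if isinstance(raw, ContigScore) else float(raw)
        if phager_gate(value, threshold) == "fail":
            labels[contig.id] = ClassLabel(
                contig.id, "non_candidate", "phager_gate", score=value
            )
            continue
        call = classify_by_hits(hits.get(contig.id, []))
        if call == "bacterial":
            labels[contig.id] = ClassLabel(
                contig.id, "bacterial", "hits", score=value
            )
            continue
        if call == "plasmid":
            labels[contig.id] = ClassLabel(
                contig.id, "plasmid", "hits", score=value
            )
            continue
        survivors.append(contig)

    surviving_profiles = {
        c.id: profiles.get(c.id, MarkerProfile(c.id)) for c in survivors
    }
    temperate_ids = propagate_temperate(clusters, surviving_profiles)
    for contig in survivors:
        profile = surviving_profiles[contig.id]
        label = assign_lifestyle(profile, contig.id in temperate_ids)
        raw = scores.get(contig.id, 0.0)
        value = raw.score if isinstance(raw, ContigScore) else float(raw)
        labels[contig.id] = ClassLabel(
            contig.id,
            label,
            "lifestyle",
            cluster_id=clusters.get(contig.id),
            score=value,
        )

    ordered = [labels[c.id] for c in contigs]
    counts = {name: 0 for name in LABELS}
    for lab in ordered:
        counts[lab.label] += 1
    summary = {
        "n_contigs": len(contigs),
        "counts": counts,
        "phager_threshold": threshold,
        "length_window_bp": [MIN_CANDIDATE_BP, MAX_CANDIDATE_BP],
    }
    return ordered, summary


def labels_to_frame(labels: Iterable[ClassLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig_id": l.contig_id,
                "label": l.label,
                "stage": l.stage,
                "cluster_id": l.cluster_id,
                "score": l.score,
            }
            for l in labels
        ]
    )
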