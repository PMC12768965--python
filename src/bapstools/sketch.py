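"""Bottom-s MinHash sketching, Mash distances, phage networks.

Genomes are reduced to the ``s`` smallest 64-bit hashes of their canonical
k-mers (a bottom sketch). The Jaccard similarity of two genomes is
estimated from the merged bottom set of the pair, and converted to the
Mash distance ``d = -ln(2j / (1 + j)) / k``, which approximates
``1 - ANI`` for moderately diverged genomes. Thresholded distance graphs
give phage networks (components = "phage clouds"), single-linkage ANI
clusters, and two-tier matching of candidate genomes against reference
(e.g. therapeutic) phages.

Also here: the non-overlapping match-length summarizer used when screening
genomes against metagenome catalogues — the union length of filtered
alignment intervals on the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import Contig

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000
HASH_SEED = np.uint64(0x1A2B3C4D5E6F7788)  # fixed: sketches must be portable

MIN_MATCH_IDENTITY = 90.0
MIN_MATCH_LENGTH = 500

_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate(b"ACGT"):
    _CODE[base] = i


@dataclass
class Sketch:
    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted uint64, |hashes| <= s
    genome_length: int


@dataclass
class PhageNetwork:
    """Thresholded Mash-distance graph over genomes."""

    graph: nx.Graph
    threshold: float
    components: dict[str, str]  # node -> component id (smallest member)

    @property
    def n_components(self) -> int:
        return len(set(self.components.values()))


@dataclass
class MatchInterval:
    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    percent_identity: float

    def __post_init__(self):
        if self.q_start >= self.q_end:
            raise ValueError("q_start must be < q_end")


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """SplitMix64 finalizer — a well-mixed 64-bit hash, vectorized."""
    z = (x + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def canonical_kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Distinct canonical k-mers of *sequence* as 2-bit packed integers.

    Canonical = numeric (equivalently lexicographic, A<C<G<T) minimum of a
    k-mer and its reverse complement. Windows containing non-ACGT bases are
    skipped.
    """
    n = len(sequence)
    if n < k:
        raise ValueError(f"sequence length {n} shorter than k={k}")
    codes = _CODE[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    invalid = codes > 3
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    codes64 = codes.astype(np.uint64)
    rc64 = (np.uint64(3) - codes64) & np.uint64(3)
    for j in range(k):
        fwd += codes64[j : m + j] << np.uint64(2 * (k - 1 - j))
        rev += rc64[j : m + j] << np.uint64(2 * j)
    bad = np.convolve(invalid.astype(np.int32), np.ones(k, dtype=np.int32))[
        k - 1 : k - 1 + m
    ]
    keep = bad == 0
    canon = np.minimum(fwd[keep], rev[keep])
    return np.unique(canon)


def sketch(
    genome: Contig | str,
    k: int = DEFAULT_K,
    s: int = DEFAULT_SKETCH_SIZE,
    genome_id: Optional[str] = None,
) -> Sketch:
    """Bottom-s MinHash sketch of a genome's canonical k-mer set."""
    if isinstance(genome, Contig):
        seq, gid = genome.sequence, genome.id
    else:
        seq, gid = genome, genome_id or "anonymous"
    canon = canonical_kmer_codes(seq, k)
    hashes = _splitmix64(canon ^ HASH_SEED)
    hashes = np.unique(hashes)
    if len(hashes) > s:
        hashes = np.sort(np.partition(hashes, s)[:s])
    return Sketch(gid, k, s, hashes, len(seq))


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Merged bottom-s Jaccard estimator (the Mash estimator).

    Take the s smallest hashes of the union of both sketches; the estimate
    is the fraction of those also present in both. Symmetric; exactly 1 for
    identical sketches even when a genome has fewer than s distinct k-mers.
    """
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")
    if a.s != b.s:
        raise ValueError(f"sketch size mismatch: {a.s} != {b.s}")
    union = np.union1d(a.hashes, b.hashes)
    bottom = union[: a.s]
    if len(bottom) == 0:
        return 0.0
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    inter = np.isin(bottom, shared, assume_unique=True).sum()
    return float(inter) / len(bottom)


def mash_distance(j: float, k: int = DEFAULT_K) -> float:
    """Mash distance transform of a Jaccard estimate; clamped to [0, 1].

    ``d = -ln(2j/(1+j)) / k``; j = 0 is capped at distance 1 (the transform
    diverges).
    """
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"Jaccard estimate {j} outside [0, 1]")
    if j == 0.0:
        return 1.0
    d = -math.log(2.0 * j / (1.0 + j)) / k
    return min(max(d, 0.0), 1.0)


def sketch_distance(a: Sketch, b: Sketch) -> float:
    return mash_distance(jaccard_estimate(a, b), a.k)


def pairwise_distances(sketches: Sequence[Sketch]) -> pd.DataFrame:
    """All-vs-all Mash distances as a long-form table (a, b, distance)."""
    rows = []
    for i in range(len(sketches)):
        for jdx in range(i + 1, len(sketches)):
            rows.append(
                {
                    "a": sketches[i].genome_id,
                    "b": sketches[jdx].genome_id,
                    "distance": sketch_distance(sketches[i], sketches[jdx]),
                }
            )
    return pd.DataFrame(rows, columns=["a", "b", "distance"])


def build_network(
    sketches: Sequence[Sketch],
    threshold: float = 0.1,
    node_attrs: Optional[Mapping[str, Mapping]] = None,
) -> PhageNetwork:
    """Genome graph with edges at Mash distance ≤ threshold.

    Connected components are the phage clouds; component ids are the
    lexicographically smallest member, so they are order-independent.
    ``node_attrs`` maps genome id → attribute dict (genome size, origin,
    host genus, ...).
    """
    if len(sketches) == 0:
        raise ValueError("need at least one sketch")
    g = nx.Graph()
    for sk in sketches:
        attrs = dict(node_attrs.get(sk.genome_id, {})) if node_attrs else {}
        attrs.setdefault("size", sk.genome_length)
        g.add_node(sk.genome_id, **attrs)
    for i in range(len(sketches)):
        for jdx in range(i + 1, len(sketches)):
            d = sketch_distance(sketches[i], sketches[jdx])
            if d <= threshold:
                g.add_edge(
                    sketches[i].genome_id, sketches[jdx].genome_id, distance=d
                )
    components = {}
    for comp in nx.connected_components(g):
        cid = min(comp)
        for node in comp:
            components[node] = cid
    return PhageNetwork(graph=g, threshold=threshold, components=components)


def ani_cluster(
    sketches: Sequence[Sketch], ani_threshold: float = 0.95
) -> dict[str, str]:
    """Single-linkage clusters of the graph with edges at sketch-ANI
    (1 − Mash distance) ≥ threshold; cluster id = smallest member id."""
    network = build_network(sketches, threshold=1.0 - ani_threshold)
    return dict(network.components)


def match_reference_set(
    references: Sequence[Sketch],
    candidates: Sequence[Sketch],
    loose: float = 0.2,
    strict: float = 0.05,
) -> pd.DataFrame:
    """Two-tier matching of candidates against each reference genome.

    A candidate is a loose (closely associated) match at distance ≤
    *loose* and a strict (strongly associated) match at ≤ *strict*; the
    strict tier is by construction nested in the loose tier.
    """
    if not 0.0 <= strict <= loose <= 1.0:
        raise ValueError("need 0 <= strict <= loose <= 1")
    rows = []
    for ref in references:
        loose_ids, strict_ids = [], []
        for cand in candidates:
            d = sketch_distance(ref, cand)
            if d <= loose:
                loose_ids.append(cand.genome_id)
            if d <= strict:
                strict_ids.append(cand.genome_id)
        rows.append(
            {
                "reference_id": ref.genome_id,
                "n_loose": len(loose_ids),
                "n_strict": len(strict_ids),
                "loose_ids": sorted(loose_ids),
                "strict_ids": sorted(strict_ids),
            }
        )
    return pd.DataFrame(rows)


def nonoverlapping_match_length(
    intervals: Iterable[MatchInterval],
    min_identity: float = MIN_MATCH_IDENTITY,
    min_length: int = MIN_MATCH_LENGTH,
) -> int:
    """Union length of filtered alignment intervals on one query.

    Intervals below the identity floor (default 90%) or shorter than the
    length floor (default 500 bp) are dropped before the union, so repeated
    matches of the same region count once.
    """
    kept = sorted(
        (iv.q_start, iv.q_end)
        for iv in intervals
        if iv.percent_identity >= min_identity
        and (iv.q_end - iv.q_start) >= min_length
    )
    total = 0
    cur_start = cur_end = None
    for a, b in kept:
        if cur_end is None or a > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = a, b
        else:
            cur_end = max(cur_end, b)
    if cur_end is not None:
        total += cur_end - cur_start
    return total
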