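"""Phage-likeness scoring: corpus construction, training, scoring.

The classifier is a gradient-boosted tree ensemble (LightGBM) over
overlapping gene-triplet feature rows. Positives are phage genomes;
negatives are bacterial genome fragments sampled so that their length
distribution matches the positive set (whole chromosomes would let the
model learn length alone), after prophage regions have been masked out.
A contig's phage-likeness score is the arithmetic mean of its per-triplet
phage probabilities; contigs with fewer than three called genes cannot
form a triplet and are assigned score 0 with an explicit flag.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import Contig
from .features import (
    TRIPLET_FEATURE_NAMES,
    contig_triplets,
    schema_hash,
)

MODEL_FORMAT_VERSION = "1"
DEFAULT_GATE = 0.8


@dataclass
class ContigScore:
    contig_id: str
    score: float
    n_triplets: int
    flag: str = "ok"  # ok | too_few_genes


@dataclass
class Hyperparams:
    """Training defaults, recorded verbatim in the model file."""

    n_estimators: int = 500
    learning_rate: float = 0.05
    max_depth: int = 8
    num_leaves: int = 63
    early_stopping_rounds: int = 50
    validation_fraction: float = 0.1
    max_neg_ratio: float = 3.0  # negatives downsampled to <= 3x positives


@dataclass
class TrainingCorpus:
    """Triplet rows with labels and per-row source-genome provenance."""

    X: np.ndarray
    y: np.ndarray  # 1 = phage, 0 = bacterial
    provenance: list[str]

    @property
    def n_positive(self) -> int:
        return int(self.y.sum())

    @property
    def n_negative(self) -> int:
        return int((1 - self.y).sum())


# ---------------------------------------------------------------------------
# Negative-set preparation
# ---------------------------------------------------------------------------

def mask_regions(
    genome: Contig, regions: Sequence[tuple[int, int]]
) -> tuple[Contig, list[tuple[int, int, int]]]:
    """Excise the union of half-open *regions* (e.g. predicted prophages).

    Returns the masked contig plus a coordinate map of kept segments as
    ``(new_start, new_end, old_start)`` triples. Regions may overlap; the
    union is removed. Out-of-bounds regions raise.
    """
    n = len(genome)
    for a, b in regions:
        if not (0 <= a < b <= n):
            raise ValueError(f"region ({a}, {b}) out of bounds for length {n}")
    merged: list[list[int]] = []
    for a, b in sorted(regions):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    segments: list[tuple[int, int]] = []
    cursor = 0
    for a, b in merged:
        if a > cursor:
            segments.append((cursor, a))
        cursor = b
    if cursor < n:
        segments.append((cursor, n))
    parts = [genome.sequence[a:b] for a, b in segments]
    coord_map = []
    pos = 0
    for (a, b) in segments:
        coord_map.append((pos, pos + (b - a), a))
        pos += b - a
    masked = Contig(
        id=genome.id,
        sequence="".join(parts),
        source_assembly=genome.source_assembly,
        declared_taxon=genome.declared_taxon,
        meta={**genome.meta, "masked_bp": n - pos},
    )
    if not masked.sequence:
        warnings.warn(
            f"mask_regions removed the entire sequence of {genome.id!r}"
        )
    return masked, coord_map


def sample_negative_fragments(
    genome: Contig,
    positive_lengths: Sequence[int],
    n: int,
    seed: int,
) -> list[Contig]:
    """Sample *n* fragments whose lengths follow the positive (phage) genome
    length distribution, with uniform start positions. Fragments longer than
    the genome are clipped to the full genome and flagged in ``meta``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not positive_lengths:
        raise ValueError("empty positive length distribution")
    rng = np.random.default_rng(seed)
    lengths = rng.choice(np.asarray(positive_lengths), size=n, replace=True)
    frags = []
    for i, want in enumerate(lengths):
        want = int(want)
        clipped = want > len(genome)
        length = min(want, len(genome))
        start = int(rng.integers(0, len(genome) - length + 1))
        frags.append(
            Contig(
                id=f"{genome.id}|frag{i}",
                sequence=genome.sequence[start : start + length],
                source_assembly=genome.source_assembly,
                meta={"origin": genome.id, "start": start, "clipped": clipped},
            )
        )
    return frags


# ---------------------------------------------------------------------------
# Corpus and training
# ---------------------------------------------------------------------------

def build_corpus(
    positives: Iterable[Contig],
    negatives: Iterable[Contig],
    caller: Optional[Callable] = None,
) -> TrainingCorpus:
    """Extract triplet rows from labelled contigs.

    A contig id appearing in both classes is a labelling error and raises.
    """
    pos_list, neg_list = list(positives), list(negatives)
    overlap = {c.id for c in pos_list} & {c.id for c in neg_list}
    if overlap:
        raise ValueError(f"contig ids in both classes: {sorted(overlap)[:5]}")
    blocks, labels, prov = [], [], []
    for label, contigs in ((1, pos_list), (0, neg_list)):
        for contig in contigs:
            trip, _ = contig_triplets(contig, caller)
            if len(trip):
                blocks.append(trip)
                labels.append(np.full(len(trip), label))
                prov.extend([contig.id] * len(trip))
    if not blocks:
        raise ValueError("no triplet rows extracted from corpus")
    return TrainingCorpus(
        X=np.vstack(blocks), y=np.concatenate(labels), provenance=prov
    )


class PhagerModel:
    """Trained triplet classifier plus the metadata needed to trust it."""

    def __init__(
        self,
        booster: lgb.Booster,
        hyperparams: Hyperparams,
        seed: int,
        feature_schema_hash: str | None = None,
    ):
        self.booster = booster
        self.hyperparams = hyperparams
        self.seed = seed
        self.schema_hash = feature_schema_hash or schema_hash()
        self.version = MODEL_FORMAT_VERSION

    # -- prediction ---------------------------------------------------------
    def predict_triplets(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(
            self.booster.predict(X, num_threads=1), dtype=float
        )

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": self.version,
            "schema_hash": self.schema_hash,
            "seed": self.seed,
            "hyperparams": asdict(self.hyperparams),
            "feature_names": list(TRIPLET_FEATURE_NAMES),
            "booster": self.booster.model_to_string(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PhagerModel":
        payload = json.loads(Path(path).read_text())
        booster = lgb.Booster(model_str=payload["booster"])
        model = cls(
            booster,
            Hyperparams(**payload["hyperparams"]),
            payload["seed"],
            payload["schema_hash"],
        )
        model.version = payload["format_version"]
        return model

    def fingerprint(self) -> str:
        import hashlib

        return hashlib.sha256(self.booster.model_to_string().encode()).hexdigest()


def train_phager(
    corpus: TrainingCorpus,
    hyperparams: Optional[Hyperparams] = None,
    seed: int = 0,
) -> PhagerModel:
    """Train the gradient-boosted triplet classifier.

    Single-threaded and deterministic for a fixed seed: two runs on the same
    corpus produce byte-identical model files. Negatives are downsampled
    (seeded) to at most ``max_neg_ratio`` times the positives, and 10% of
    rows are held out (seeded) for early stopping on binary log-loss.
    """
    hp = hyperparams or Hyperparams()
    n_pos, n_neg = corpus.n_positive, corpus.n_negative
    if n_pos == 0 or n_neg == 0:
        missing = "phage (positive)" if n_pos == 0 else "bacterial (negative)"
        raise ValueError(f"corpus has no {missing} rows")

    rng = np.random.default_rng(seed)
    X, y = corpus.X, corpus.y
    max_neg = int(hp.max_neg_ratio * n_pos)
    if n_neg > max_neg:
        neg_idx = np.flatnonzero(y == 0)
        keep_neg = rng.choice(neg_idx, size=max_neg, replace=False)
        keep = np.sort(np.concatenate([np.flatnonzero(y == 1), keep_neg]))
        X, y = X[keep], y[keep]

    n = len(y)
    order = rng.permutation(n)
    n_val = max(1, int(round(hp.validation_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0 or len(np.unique(y[train_idx])) < 2:
        train_idx, val_idx = order, order  # tiny corpora: validate in-sample

    params = {
        "objective": "binary",
        "metric": "binary_logloss",
        "learning_rate": hp.learning_rate,
        "max_depth": hp.max_depth,
        "num_leaves": hp.num_leaves,
        "seed": seed,
        "deterministic": True,
        "force_row_wise": True,
        "num_threads": 1,
        "verbosity": -1,
    }
    dtrain = lgb.Dataset(
        X[train_idx], label=y[train_idx], feature_name=list(TRIPLET_FEATURE_NAMES)
    )
    dval = lgb.Dataset(X[val_idx], label=y[val_idx], reference=dtrain)
    booster = lgb.train(
        params,
        dtrain,
        num_boost_round=hp.n_estimators,
        valid_sets=[dval],
        callbacks=[
            lgb.early_stopping(hp.early_stopping_rounds, verbose=False),
            lgb.log_evaluation(period=0),
        ],
    )
    return PhagerModel(booster, hp, seed)


# ---------------------------------------------------------------------------
# Scoring and evaluation
# ---------------------------------------------------------------------------

def score_contig(
    model: PhagerModel,
    contig: Contig,
    caller: Optional[Callable] = None,
) -> ContigScore:
    """Mean per-triplet phage probability; 0 with a flag below 3 genes."""
    if model.schema_hash != schema_hash():
        raise ValueError(
            "model was trained under a different feature schema "
            f"({model.schema_hash[:12]} != {schema_hash()[:12]})"
        )
    triplets, n_genes = contig_triplets(contig, caller)
    if len(triplets) == 0:
        return ContigScore(contig.id, 0.0, 0, "too_few_genes")
    probs = model.predict_triplets(triplets)
    return ContigScore(contig.id, float(np.mean(probs)), len(triplets), "ok")


def score_contigs(
    model: PhagerModel,
    contigs: Iterable[Contig],
    caller: Optional[Callable] = None,
) -> list[ContigScore]:
    return [score_contig(model, c, caller) for c in contigs]


def metrics_from_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    thresholds: Sequence[float] = (0.5, DEFAULT_GATE),
) -> dict:
    """AUC plus precision/recall/confusion counts at the given thresholds.

    Ties receive the standard mid-rank treatment (all-equal scores → 0.5).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) == 0:
        raise ValueError("no scores to evaluate")
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes to evaluate")
    rows = []
    for t in thresholds:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        rows.append(
            {
                "threshold": t,
                "precision": tp / (tp + fp) if tp + fp else float("nan"),
                "recall": tp / (tp + fn) if tp + fn else float("nan"),
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "tn": tn,
            }
        )
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "by_threshold": pd.DataFrame(rows),
    }


def evaluate_model(
    model: PhagerModel,
    contigs: Sequence[Contig],
    labels: Sequence[str],
    thresholds: Sequence[float] = (0.5, DEFAULT_GATE),
    caller: Optional[Callable] = None,
) -> dict:
    """Contig-level evaluation: score, then AUC and threshold metrics.

    *labels* are 'phage' / 'bacterial' per contig.
    """
    if len(contigs) == 0:
        raise ValueError("no contigs to evaluate")
    bad = set(labels) - {"phage", "bacterial"}
    if bad:
        raise ValueError(f"labels must be phage/bacterial, got {sorted(bad)}")
    contig_scores = score_contigs(model, contigs, caller)
    numeric = [s.score for s in contig_scores]
    binary = [1 if l == "phage" else 0 for l in labels]
    out = metrics_from_scores(numeric, binary, thresholds)
    out["scores"] = contig_scores
    return out
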