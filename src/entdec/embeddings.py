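"""Static entity-vector aggregation, similarity benchmarks, clustering.

Contextualized language models give one vector per mention and layer rather
than one static vector per entity.  The aggregation protocol averages the
selected final layers within each mention and then averages across up to
the first ``max_mentions`` mentions (the two means commute).  Vector sets
are validated against human similarity/relatedness judgments (Spearman
between pairwise cosines and scores) and by unsupervised K-means clustering
scored with the chance-corrected adjusted Rand index against category
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from scipy.stats import spearmanr

from .simulate import VectorSet

DEFAULT_MAX_MENTIONS = 32


class InsufficientDataError(ValueError):
    """Too few resolvable items for the requested evaluation."""


@dataclass
class MentionVectors:
    """Per-mention (layers x dim) blocks for one entity, capped at
    ``max_mentions`` mentions in original (sentence) order."""

    entity_id: str
    mentions: list  # each (n_layers, dim)
    max_mentions: int = DEFAULT_MAX_MENTIONS

    def __post_init__(self):
        if not self.mentions:
            raise ValueError(f"{self.entity_id}: at least one mention required")
        dims = {np.asarray(m).shape[-1] for m in self.mentions}
        if len(dims) != 1:
            raise ValueError(f"{self.entity_id}: inconsistent dimensions {dims}")
        self.mentions = [np.atleast_2d(np.asarray(m, dtype=float))
                         for m in self.mentions[: self.max_mentions]]


@dataclass(frozen=True)
class SimilarityBenchmark:
    """Human similarity/relatedness judgments for entity pairs."""

    pairs: tuple  # of (id1, id2, score)

    @classmethod
    def from_tsv(cls, path) -> "SimilarityBenchmark":
        df = pd.read_csv(path, sep="\t", names=["id1", "id2", "score"],
                         header=0)
        return cls(pairs=tuple(
            (str(r.id1), str(r.id2), float(r.score)) for r in df.itertuples()))


@dataclass(frozen=True)
class ClusteringEvaluation:
    ari: float  # adjusted Rand index, <= 1, 0 expected under independence
    k: int
    n_items: int
    inertia: float
    scheme: str = ""


def aggregate_contextual_vectors(mv: MentionVectors, layers) -> np.ndarray:
    """Mean over the selected layers within each mention, then over mentions."""
    layers = list(layers)
    if not layers:
        raise ValueError("layer index set must be non-empty")
    per_mention = [m[layers].mean(axis=0) for m in mv.mentions]
    return np.mean(per_mention, axis=0)


def aggregate_vector_set(
    mention_vectors: dict[str, "MentionVectors | np.ndarray"], layers
) -> VectorSet:
    """Aggregate a whole collection (id -> MentionVectors or a raw
    (n_mentions, n_layers, dim) array) into one static VectorSet."""
    names, rows = [], []
    for name, mv in mention_vectors.items():
        if not isinstance(mv, MentionVectors):
            mv = MentionVectors(entity_id=name, mentions=list(np.asarray(mv)))
        names.append(name)
        rows.append(aggregate_contextual_vectors(mv, layers))
    return VectorSet(names=tuple(names), vectors=np.asarray(rows))


def similarity_benchmark_correlation(
    vectors: VectorSet, bench: SimilarityBenchmark
) -> float:
    """Spearman between pairwise cosine similarities and human scores.

    Pairs with an unresolvable id are dropped; fewer than 3 resolvable
    pairs is an error.
    """
    known = set(vectors.names)
    resolvable = [(a, b, s) for a, b, s in bench.pairs
                  if a in known and b in known]
    if len(resolvable) < 3:
        raise InsufficientDataError(
            f"only {len(resolvable)} of {len(bench.pairs)} pairs resolvable")
    norms = {n: vectors.get(n) / np.linalg.norm(vectors.get(n))
             for n in {i for a, b, _ in resolvable for i in (a, b)}}
    cos = [float(norms[a] @ norms[b]) for a, b, _ in resolvable]
    human = [s for _, _, s in resolvable]
    return float(spearmanr(cos, human).statistic)


def cluster_and_score(
    vectors: VectorSet,
    labels: dict[str, str],
    k: int | None = None,
    seed: int = 0,
    n_restarts: int = 10,
    scheme: str = "",
) -> ClusteringEvaluation:
    """K-means partition (best inertia over ``n_restarts`` seeded runs)
    scored by the adjusted Rand index against the reference labels."""
    ids = [n for n in vectors.names if n in labels]
    if len(ids) < len(vectors.names):
        missing = set(vectors.names) - set(ids)
        raise ValueError(f"labels missing for: {sorted(missing)}")
    y = [labels[n] for n in ids]
    if k is None:
        k = len(set(y))
    if k != len(set(y)):
        raise ValueError(f"k={k} != {len(set(y))} distinct labels")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} vectors")
    X = vectors.subset(ids).vectors
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
    return ClusteringEvaluation(
        ari=float(adjusted_rand_score(y, km.labels_)),
        k=k, n_items=len(ids), inertia=float(km.inertia_), scheme=scheme)
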