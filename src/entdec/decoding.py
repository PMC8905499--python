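"""Zero-shot decoding from whole-epoch EEG features to entity vectors.

A ridge regression maps the flattened 100-1200 ms epoch (channels x
in-window samples, channel-major) of each stimulus to its word vector.
Evaluation is leave-two-out pairwise: for every unordered stimulus pair the
map is fitted on all remaining stimuli (the held-out pair never contributes
training rows - a zero-shot contract that is asserted on every fold) and
the two predictions are scored by the Spearman sum rule::

    accuracy = 1  iff  rho(e1, e1_hat) + rho(e2, e2_hat)
                       > rho(e1, e2_hat) + rho(e2, e1_hat)

with 0.5 on an exact tie.  Chance level is 0.50.  Outcomes carry pair-type
tags (entity/category x people/places) for the breakdown analysis, and a
word-length control checks that vector similarity does not track character
length.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.linear_model import Ridge

from .design import StimulusDesign
from .preprocessing import EvokedSet
from .simulate import VectorSet, window_indices


class DegenerateVectorError(ValueError):
    """A constant vector has undefined ranks."""


@dataclass(frozen=True)
class DecoderSpec:
    alpha: float = 1.0  # ridge regularization
    feature_window: tuple[float, float] = (100.0, 1200.0)  # ms

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass(frozen=True)
class PairwiseOutcome:
    pair: tuple[str, str]
    rho_matched: tuple[float, float]
    rho_mismatched: tuple[float, float]
    accuracy: float  # 1, 0, or 0.5 on an exact tie
    ontology_bin: str = ""  # entity-entity | category-category | mixed
    coarse_bin: str = ""  # people | places | mixed


@dataclass(frozen=True)
class DecodingResult:
    subject_id: str
    outcomes: tuple[PairwiseOutcome, ...]

    @property
    def accuracy(self) -> float:
        return float(np.mean([o.accuracy for o in self.outcomes]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.subject_id, o.pair[0], o.pair[1], o.ontology_bin,
              o.coarse_bin, o.accuracy) for o in self.outcomes],
            columns=["subject", "id1", "id2", "ontology_bin", "coarse_bin",
                     "accuracy"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def features_from_evoked(
    evoked: EvokedSet, spec: DecoderSpec = DecoderSpec()
) -> np.ndarray:
    """Flatten each evoked response's in-window block to one feature row.

    Channel-major order: row = [ch0 samples..., ch1 samples...].  With the
    default 128 channels and 100-1200 ms window at 256 Hz this gives
    36,096 features per stimulus.
    """
    i0, i1 = window_indices(evoked.times, evoked.rate, spec.feature_window)
    if i1 < i0:
        raise ValueError("empty feature window")
    block = evoked.evoked[:, :, i0:i1 + 1]
    return block.reshape(block.shape[0], -1)


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    return float(spearmanr(a, b).statistic)


def pairwise_score(e1, e2, ehat1, ehat2,
                   pair: tuple[str, str] = ("a", "b")) -> PairwiseOutcome:
    """Score one held-out pair by the Spearman sum rule."""
    vecs = [np.asarray(v, dtype=float) for v in (e1, e2, ehat1, ehat2)]
    if len({v.size for v in vecs}) != 1 or vecs[0].size < 3:
        raise ValueError("all four vectors must share a dimension >= 3")
    for v in vecs:
        if np.ptp(v) == 0:
            raise DegenerateVectorError("constant vector has undefined ranks")
    e1, e2, ehat1, ehat2 = vecs
    matched = (_spearman(e1, ehat1), _spearman(e2, ehat2))
    mismatched = (_spearman(e1, ehat2), _spearman(e2, ehat1))
    diff = sum(matched) - sum(mismatched)
    accuracy = 0.5 if diff == 0 else float(diff > 0)
    return PairwiseOutcome(pair=pair, rho_matched=matched,
                           rho_mismatched=mismatched, accuracy=accuracy)


def pair_tags(design: StimulusDesign, id1: str, id2: str) -> tuple[str, str]:
    """(ontology, coarse) bin tags, symmetric in pair order."""
    s1, s2 = design.by_id(id1), design.by_id(id2)
    if s1.is_entity and s2.is_entity:
        ontology = "entity-entity"
    elif not s1.is_entity and not s2.is_entity:
        ontology = "category-category"
    else:
        ontology = "mixed"
    if s1.coarse == s2.coarse:
        coarse = "people" if s1.coarse == "person" else "places"
    else:
        coarse = "mixed"
    return ontology, coarse


def leave_two_out_decoding(
    evoked: EvokedSet,
    vectors: VectorSet,
    design: StimulusDesign,
    scope: str = "entities_only",
    spec: DecoderSpec = DecoderSpec(),
) -> DecodingResult:
    """Leave-two-out ridge decoding over all unordered stimulus pairs.

    ``scope`` is ``"entities_only"`` (the 32 proper names, 496 pairs) or
    ``"all"`` (all 40 stimuli, 780 pairs).
    """
    if scope == "entities_only":
        ids = [s.id for s in design.entities]
    elif scope == "all":
        ids = design.stimulus_ids
    else:
        raise ValueError(f"unknown scope {scope!r}")
    missing = [i for i in ids if i not in vectors.names]
    if missing:
        raise ValueError(f"vectors missing stimuli: {missing}")
    if len(ids) < 4:
        raise ValueError("need at least 4 stimuli in scope")
    sub = evoked.subset(ids)
    X = features_from_evoked(sub, spec)
    Y = vectors.subset(ids).vectors
    outcomes = []
    for i, j in combinations(range(len(ids)), 2):
        train = [k for k in range(len(ids)) if k not in (i, j)]
        assert i not in train and j not in train  # zero-shot audit
        model = Ridge(alpha=spec.alpha).fit(X[train], Y[train])
        ehat1, ehat2 = model.predict(X[[i, j]])
        out = pairwise_score(Y[i], Y[j], ehat1, ehat2, pair=(ids[i], ids[j]))
        ontology, coarse = pair_tags(design, ids[i], ids[j])
        outcomes.append(PairwiseOutcome(
            pair=out.pair, rho_matched=out.rho_matched,
            rho_mismatched=out.rho_mismatched, accuracy=out.accuracy,
            ontology_bin=ontology, coarse_bin=coarse))
    return DecodingResult(subject_id=evoked.subject_id,
                          outcomes=tuple(outcomes))


def breakdown_by_pair_type(results) -> pd.DataFrame:
    """Mean accuracy per (ontology, coarse) bin, per subject.

    ``results`` is one DecodingResult or a list of them; empty bins are
    simply absent from the table.
    """
    if isinstance(results, DecodingResult):
        results = [results]
    df = pd.concat([r.to_frame() for r in results], ignore_index=True)
    table = (df.groupby(["ontology_bin", "coarse_bin", "subject"])
             .agg(accuracy=("accuracy", "mean"), n_pairs=("accuracy", "size"))
             .reset_index())
    return table


def length_similarity_correlation(
    vectors: VectorSet, design: StimulusDesign
) -> float:
    """Spearman between pairwise cosine similarity and |length difference|.

    Near zero when the vectors carry no orthographic information; defined
    as 0 when either side is constant (e.g., all lengths equal).
    """
    ids = [i for i in vectors.names if i in set(design.stimulus_ids)]
    if len(ids) < 3:
        raise ValueError("need at least 3 stimuli")
    V = vectors.subset(ids).vectors
    norms = np.linalg.norm(V, axis=1)
    if np.any(norms == 0):
        raise DegenerateVectorError("zero vector has undefined cosine")
    U = V / norms[:, None]
    lengths = np.array([design.by_id(i).word_length for i in ids], dtype=float)
    cos, gaps = [], []
    for i, j in combinations(range(len(ids)), 2):
        cos.append(U[i] @ U[j])
        gaps.append(abs(lengths[i] - lengths[j]))
    cos, gaps = np.array(cos), np.array(gaps)
    if np.ptp(cos) == 0 or np.ptp(gaps) == 0:
        return 0.0
    return float(spearmanr(cos, gaps).statistic)
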