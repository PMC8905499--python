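"""Balanced held-out test sets and word-length confound control.

Because mean word length differs between categories (people's names run
longer than places'), a classifier could exploit orthographic length rather
than semantics.  Following the confound-control-by-split-selection idea,
every balanced candidate test set is scored by the Spearman correlation
between its stimuli encoded as character lengths and its labels encoded as
the mean length of the label's entities; only the candidates with the
lowest |rho| are retained as final test sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
from scipy.stats import spearmanr

from .design import StimulusDesign, validate_design


@dataclass(frozen=True)
class CandidateTestSet:
    stimulus_ids: tuple[str, ...]
    rho: float | None = None  # word-length confound correlation


@dataclass(frozen=True)
class SplitPlan:
    scheme: str  # "leave4_balanced" | "leave2_within_coarse"
    splits: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, test)
    rhos: tuple[float, ...] = ()

    def __len__(self) -> int:
        return len(self.splits)

    @property
    def max_abs_rho(self) -> float:
        return max(abs(r) for r in self.rhos) if self.rhos else 0.0


def enumerate_balanced_test_sets(design: StimulusDesign) -> list[CandidateTestSet]:
    """All 4-entity test sets with 2 people, 2 places, distinct fine categories.

    Deterministic lexicographic order over (fine-category pair, entity
    choice) within each coarse category.  For the default design this yields
    96 x 96 = 9,216 candidates.
    """
    validate_design(design)
    per_coarse = {}
    for coarse in design.coarse_categories:
        fines = design.fine_categories[coarse]
        combos = []
        for f1, f2 in combinations(fines, 2):
            for e1 in design.entities_of(f1):
                for e2 in design.entities_of(f2):
                    combos.append((e1.id, e2.id))
        per_coarse[coarse] = combos
    people, places = (per_coarse[c] for c in design.coarse_categories)
    return [CandidateTestSet(stimulus_ids=p + q) for p in people for q in places]


def enumerate_within_coarse_test_sets(
    design: StimulusDesign, coarse: str
) -> list[CandidateTestSet]:
    """All 2-entity test sets within one coarse category, distinct fine categories."""
    validate_design(design)
    if coarse not in design.coarse_categories:
        raise ValueError(f"unknown coarse category {coarse!r}")
    combos = []
    for f1, f2 in combinations(design.fine_categories[coarse], 2):
        for e1 in design.entities_of(f1):
            for e2 in design.entities_of(f2):
                combos.append(CandidateTestSet(stimulus_ids=(e1.id, e2.id)))
    return combos


def _length_rho(candidate: CandidateTestSet, design: StimulusDesign,
                label_lengths: dict[str, float], level: str) -> float:
    """Spearman between stimulus lengths and label mean-length encodings.

    Average ranks for ties; defined as 0 when either encoding is constant.
    """
    stims = [design.by_id(i) for i in candidate.stimulus_ids]
    x = np.array([s.word_length for s in stims], dtype=float)
    key = (lambda s: s.coarse) if level == "coarse" else (lambda s: s.fine)
    y = np.array([label_lengths[key(s)] for s in stims])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(spearmanr(x, y).statistic)


def label_mean_lengths(design: StimulusDesign, level: str = "fine") -> dict[str, float]:
    """Mean entity word length per category label (the label encodings)."""
    out: dict[str, list[int]] = {}
    for s in design.entities:
        label = s.coarse if level == "coarse" else s.fine
        out.setdefault(label, []).append(s.word_length)
    return {k: float(np.mean(v)) for k, v in out.items()}


def select_confound_controlled(
    candidates: list[CandidateTestSet],
    design: StimulusDesign,
    n_select: int = 50,
    level: str = "fine",
) -> SplitPlan:
    """Retain the ``n_select`` candidates with the lowest |rho|.

    ``level`` chooses the label encoding (coarse or fine category mean
    lengths) matching the analysis the plan will serve.  Ties in |rho| are
    broken by canonical candidate order (stable sort).  Train sets are the
    remaining eligible entities, so each split keeps the 87.5%/12.5%
    train/test proportion of the generating scheme.
    """
    if n_select > len(candidates):
        raise ValueError(
            f"n_select={n_select} exceeds {len(candidates)} candidates")
    if level not in ("coarse", "fine"):
        raise ValueError(f"level must be 'coarse' or 'fine', got {level!r}")
    enc = label_mean_lengths(design, level)
    scored = [replace(c, rho=_length_rho(c, design, enc, level))
              for c in candidates]
    order = sorted(range(len(scored)), key=lambda i: abs(scored[i].rho))
    chosen = [scored[i] for i in order[:n_select]]
    eligible = sorted({i for c in candidates for i in c.stimulus_ids},
                      key=design.stimulus_ids.index)
    k = len(candidates[0].stimulus_ids)
    scheme = "leave4_balanced" if k == 4 else "leave2_within_coarse"
    splits = tuple(
        (tuple(i for i in eligible if i not in c.stimulus_ids), c.stimulus_ids)
        for c in chosen)
    return SplitPlan(scheme=scheme, splits=splits,
                     rhos=tuple(c.rho for c in chosen))


def within_coarse_plan(design: StimulusDesign, coarse: str) -> SplitPlan:
    """All 96 leave-2-out splits over one coarse category's 16 entities."""
    candidates = enumerate_within_coarse_test_sets(design, coarse)
    eligible = sorted({i for c in candidates for i in c.stimulus_ids},
                      key=design.stimulus_ids.index)
    splits = tuple(
        (tuple(i for i in eligible if i not in c.stimulus_ids), c.stimulus_ids)
        for c in candidates)
    return SplitPlan(scheme="leave2_within_coarse", splits=splits)


# ---------------------------------------------------------------- JSON i/o

def plan_to_json(plan: SplitPlan, path) -> None:
    payload = {
        "scheme": plan.scheme,
        "splits": [{"train": list(tr), "test": list(te)} for tr, te in plan.splits],
        "rhos": list(plan.rhos),
    }
    with open(path, "w") as f:
        json.dump(payload, f, indent=1)


def plan_from_json(path) -> SplitPlan:
    with open(path) as f:
        payload = json.load(f)
    return SplitPlan(
        scheme=payload["scheme"],
        splits=tuple((tuple(s["train"]), tuple(s["test"]))
                     for s in payload["splits"]),
        rhos=tuple(payload["rhos"]),
    )
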