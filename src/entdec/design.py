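"""Hierarchical stimulus design and session schedule.

The stimulus set is organized as 2 coarse categories (people, places), each
split into 4 fine-grained categories (occupations for people, place kinds for
places), with 4 named individual entities per fine category plus the 8
category nouns themselves: 40 stimuli in total, 32 of them proper names.

A session consists of short runs in which every stimulus appears exactly
once in randomized order; after each trial the participant answers either a
coarse-level question ("person or place?") or a fine-level verification
question ("the name referred to a musician" -> correct/wrong). Per run the
question multiset is fixed: 16 coarse questions and 24 fine questions, 12 of
which expect the answer "correct".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COARSE_CATEGORIES = ("person", "place")
FINE_CATEGORIES = {
    "person": ("musician", "politician", "actor", "writer"),
    "place": ("body_of_water", "monument", "city", "country"),
}
N_ENTITIES_PER_FINE = 4

# per-run question quotas
N_COARSE_QUESTIONS = 16
N_FINE_QUESTIONS = 24
N_FINE_CORRECT = 12

# mean surface-form length (characters) by coarse category: people carry
# name + surname and run longer than place names
DEFAULT_MEAN_LENGTH = {"person": 12, "place": 9}
LENGTH_SD = 2.0
MIN_LENGTH = 3

_VOWELS = "aeiou"
_CONSONANTS = "bcdfghklmnprstvz"


class DesignError(ValueError):
    """A structural constraint of the stimulus design is violated."""


class ScheduleError(ValueError):
    """The requested schedule configuration is infeasible."""


@dataclass(frozen=True)
class Stimulus:
    id: str
    surface_form: str
    coarse: str
    fine: str
    is_entity: bool
    word_length: int
    familiarity: float | None = None


@dataclass(frozen=True)
class StimulusDesign:
    stimuli: tuple[Stimulus, ...]
    coarse_categories: tuple[str, str] = COARSE_CATEGORIES
    fine_categories: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(FINE_CATEGORIES)
    )

    @property
    def stimulus_ids(self) -> list[str]:
        return [s.id for s in self.stimuli]

    @property
    def entities(self) -> list[Stimulus]:
        return [s for s in self.stimuli if s.is_entity]

    @property
    def category_nouns(self) -> list[Stimulus]:
        return [s for s in self.stimuli if not s.is_entity]

    def by_id(self, stimulus_id: str) -> Stimulus:
        for s in self.stimuli:
            if s.id == stimulus_id:
                return s
        raise KeyError(stimulus_id)

    def entities_of(self, fine: str) -> list[Stimulus]:
        return [s for s in self.entities if s.fine == fine]

    @property
    def all_fine(self) -> list[str]:
        return [f for c in self.coarse_categories for f in self.fine_categories[c]]


@dataclass(frozen=True)
class Trial:
    stimulus_id: str
    question_kind: str  # "coarse" | "fine"
    probed_category: str | None  # fine category named in a fine question
    expected_answer: str | None  # "correct" | "wrong" for fine questions


@dataclass(frozen=True)
class TrialSchedule:
    runs: tuple[tuple[Trial, ...], ...]

    @property
    def n_trials(self) -> int:
        return sum(len(r) for r in self.runs)


def _pronounceable(rng: np.random.Generator, length: int) -> str:
    """Random CV-alternating string of the requested length."""
    chars = []
    for i in range(length):
        pool = _CONSONANTS if i % 2 == 0 else _VOWELS
        chars.append(pool[rng.integers(len(pool))])
    return "".join(chars)


def build_design(
    entity_names: dict[str, list[str]] | None = None,
    lengths: dict[str, int] | None = None,
    seed: int = 0,
) -> StimulusDesign:
    """Construct the 2 x 4 x 4 stimulus design.

    Parameters
    ----------
    entity_names
        Optional mapping fine category -> list of 4 entity surface forms.
        When omitted, pronounceable placeholder names are synthesized with
        lengths drawn per coarse category (normal, mean 12 characters for
        people and 9 for places, sd 2, truncated at 3).
    lengths
        Optional mapping surface form -> character count overriding
        ``len(surface_form)`` (useful when forms contain spaces that should
        not count as letters).
    seed
        Seed for placeholder synthesis and familiarity metadata.
    """
    rng = np.random.default_rng(seed)
    if entity_names is not None:
        missing = [f for c in COARSE_CATEGORIES for f in FINE_CATEGORIES[c]
                   if f not in entity_names]
        if missing:
            raise DesignError(f"entity_names missing fine categories: {missing}")
        for fine, names in entity_names.items():
            if len(names) != N_ENTITIES_PER_FINE or len(set(names)) != N_ENTITIES_PER_FINE:
                raise DesignError(
                    f"fine category {fine!r} needs exactly "
                    f"{N_ENTITIES_PER_FINE} distinct entities, got {names!r}"
                )

    stimuli: list[Stimulus] = []
    for coarse in COARSE_CATEGORIES:
        for fine in FINE_CATEGORIES[coarse]:
            for k in range(N_ENTITIES_PER_FINE):
                if entity_names is None:
                    length = int(round(rng.normal(DEFAULT_MEAN_LENGTH[coarse], LENGTH_SD)))
                    length = max(length, MIN_LENGTH)
                    form = _pronounceable(rng, length)
                else:
                    form = entity_names[fine][k]
                    length = lengths.get(form, len(form)) if lengths else len(form)
                if length < 1:
                    raise DesignError(f"word_length must be >= 1 for {form!r}")
                stimuli.append(Stimulus(
                    id=f"{fine}_{k}",
                    surface_form=form,
                    coarse=coarse,
                    fine=fine,
                    is_entity=True,
                    word_length=length,
                    familiarity=float(np.round(rng.uniform(3.0, 5.0), 2)),
                ))
            noun_len = lengths.get(fine, len(fine)) if lengths else len(fine)
            stimuli.append(Stimulus(
                id=f"{fine}_noun",
                surface_form=fine,
                coarse=coarse,
                fine=fine,
                is_entity=False,
                word_length=noun_len,
                familiarity=float(np.round(rng.uniform(3.0, 5.0), 2)),
            ))
    design = StimulusDesign(stimuli=tuple(stimuli))
    validate_design(design)
    return design


def validate_design(design: StimulusDesign) -> None:
    """Check every structural invariant, raising DesignError on violation."""
    if len(design.stimuli) != 40:
        raise DesignError(f"expected 40 stimuli, got {len(design.stimuli)}")
    if len(set(design.stimulus_ids)) != 40:
        raise DesignError("stimulus ids are not unique")
    if len(design.entities) != 32:
        raise DesignError(f"expected 32 entities, got {len(design.entities)}")
    for coarse in design.coarse_categories:
        if len(design.fine_categories[coarse]) != 4:
            raise DesignError(f"coarse category {coarse!r} needs 4 fine categories")
        for fine in design.fine_categories[coarse]:
            ents = design.entities_of(fine)
            if len(ents) != N_ENTITIES_PER_FINE:
                raise DesignError(
                    f"fine category {fine!r} has {len(ents)} entities, "
                    f"expected {N_ENTITIES_PER_FINE}"
                )
            nouns = [s for s in design.category_nouns if s.fine == fine]
            if len(nouns) != 1:
                raise DesignError(f"fine category {fine!r} needs exactly 1 noun stimulus")
            if nouns[0].surface_form != fine:
                raise DesignError(
                    f"noun stimulus for {fine!r} must have the category name "
                    f"as surface form, got {nouns[0].surface_form!r}"
                )
    for s in design.stimuli:
        if s.word_length < 1:
            raise DesignError(f"stimulus {s.id!r} has word_length < 1")


def generate_schedule(
    design: StimulusDesign, n_runs: int = 24, seed: int = 0
) -> TrialSchedule:
    """Randomized session schedule: each run presents every stimulus once.

    Question assignment per run is a uniform shuffle of the fixed multiset of
    question tokens (16 coarse, 12 fine/correct, 12 fine/wrong); for a
    fine/correct question the probed category is the stimulus's own fine
    category, for fine/wrong a uniformly drawn different one.
    """
    validate_design(design)
    if n_runs < 1:
        raise ScheduleError("n_runs must be >= 1")
    n_stim = len(design.stimuli)
    if N_COARSE_QUESTIONS + N_FINE_QUESTIONS != n_stim:
        raise ScheduleError(
            f"question quotas ({N_COARSE_QUESTIONS} coarse + {N_FINE_QUESTIONS} fine) "
            f"do not cover a run of {n_stim} trials"
        )
    rng = np.random.default_rng(seed)
    all_fine = design.all_fine
    tokens = (["coarse"] * N_COARSE_QUESTIONS
              + ["fine_correct"] * N_FINE_CORRECT
              + ["fine_wrong"] * (N_FINE_QUESTIONS - N_FINE_CORRECT))
    runs = []
    for _ in range(n_runs):
        order = rng.permutation(n_stim)
        run_tokens = [tokens[i] for i in rng.permutation(len(tokens))]
        trials = []
        for idx, token in zip(order, run_tokens):
            stim = design.stimuli[idx]
            if token == "coarse":
                trials.append(Trial(stim.id, "coarse", None, None))
            elif token == "fine_correct":
                trials.append(Trial(stim.id, "fine", stim.fine, "correct"))
            else:
                others = [f for f in all_fine if f != stim.fine]
                probed = others[rng.integers(len(others))]
                trials.append(Trial(stim.id, "fine", probed, "wrong"))
        runs.append(tuple(trials))
    schedule = TrialSchedule(runs=tuple(runs))
    validate_schedule(design, schedule)
    return schedule


def validate_schedule(design: StimulusDesign, schedule: TrialSchedule) -> None:
    """Re-count all per-run quotas, raising ScheduleError on violation."""
    ids = set(design.stimulus_ids)
    for i, run in enumerate(schedule.runs):
        seen = [t.stimulus_id for t in run]
        if sorted(seen) != sorted(ids):
            raise ScheduleError(f"run {i}: each stimulus must appear exactly once")
        n_coarse = sum(t.question_kind == "coarse" for t in run)
        n_fine = sum(t.question_kind == "fine" for t in run)
        n_correct = sum(t.expected_answer == "correct" for t in run)
        if n_coarse != N_COARSE_QUESTIONS:
            raise ScheduleError(f"run {i}: {n_coarse} coarse questions, "
                                f"expected {N_COARSE_QUESTIONS}")
        if n_fine != N_FINE_QUESTIONS or n_correct != N_FINE_CORRECT:
            raise ScheduleError(
                f"run {i}: {n_fine} fine questions ({n_correct} 'correct'), "
                f"expected {N_FINE_QUESTIONS} ({N_FINE_CORRECT})"
            )
        for t in run:
            if t.question_kind == "fine":
                is_match = t.probed_category == design.by_id(t.stimulus_id).fine
                if (t.expected_answer == "correct") != is_match:
                    raise ScheduleError(f"run {i}: inconsistent fine question {t}")


# ---------------------------------------------------------------- TSV i/o

def design_to_frame(design: StimulusDesign) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.id, s.surface_form, s.coarse, s.fine, s.is_entity,
          s.word_length, s.familiarity) for s in design.stimuli],
        columns=["id", "surface_form", "coarse", "fine", "is_entity",
                 "word_length", "familiarity"],
    )


def design_to_tsv(design: StimulusDesign, path) -> None:
    design_to_frame(design).to_csv(path, sep="\t", index=False)


def design_from_tsv(path) -> StimulusDesign:
    df = pd.read_csv(path, sep="\t")
    stimuli = tuple(
        Stimulus(
            id=str(r.id), surface_form=str(r.surface_form), coarse=str(r.coarse),
            fine=str(r.fine), is_entity=bool(r.is_entity),
            word_length=int(r.word_length),
            familiarity=None if pd.isna(r.familiarity) else float(r.familiarity),
        )
        for r in df.itertuples()
    )
    design = StimulusDesign(stimuli=stimuli)
    validate_design(design)
    return design


def schedule_to_tsv(schedule: TrialSchedule, path) -> None:
    rows = [
        (run_i, trial_i, t.stimulus_id, t.question_kind,
         t.probed_category or "", t.expected_answer or "")
        for run_i, run in enumerate(schedule.runs)
        for trial_i, t in enumerate(run)
    ]
    pd.DataFrame(rows, columns=[
        "run", "trial_index", "stimulus_id", "question_kind",
        "probed_category", "expected_answer",
    ]).to_csv(path, sep="\t", index=False)
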