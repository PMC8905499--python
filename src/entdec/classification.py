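"""Time-resolved category classification of evoked responses.

At each timepoint the n_channels potential vector is the feature and a
linear max-margin classifier (l2-penalized, C = 1.0, one-vs-rest for more
than two classes) is trained and tested separately, yielding an accuracy
time course per subject.  Tasks: coarse (person vs place, chance 0.5), fine
(8 categories, chance 0.125), within-coarse (4 categories, chance 0.25),
and entity-to-category transfer (train on the 32 proper-name responses,
test on the 8 category-noun responses, no split plan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .design import StimulusDesign
from .preprocessing import EvokedSet
from .splits import SplitPlan

TASK_CHANCE = {"coarse": 0.5, "fine": 0.125,
               "within_people": 0.25, "within_places": 0.25}
_TASK_SCHEME = {"coarse": "leave4_balanced", "fine": "leave4_balanced",
                "within_people": "leave2_within_coarse",
                "within_places": "leave2_within_coarse"}


class DegenerateLabelError(ValueError):
    """Training labels contain a single class."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Linear max-margin classifier: l2 penalty, one-vs-rest multiclass."""

    C: float = 1.0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be > 0")

    def make(self) -> LinearSVC:
        # fixed random_state: the dual coordinate-descent solver is
        # otherwise not bit-reproducible
        return LinearSVC(C=self.C, penalty="l2", random_state=0)


@dataclass(frozen=True)
class AccuracyTimecourse:
    subject_ids: tuple[str, ...]
    times: np.ndarray  # ms
    accuracies: np.ndarray  # (n_subjects, n_timepoints) in [0, 1]
    chance: float
    task: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (sid, float(t), float(self.accuracies[i, j]), self.task, self.chance)
            for i, sid in enumerate(self.subject_ids)
            for j, t in enumerate(self.times)
        ]
        return pd.DataFrame(
            rows, columns=["subject", "time_ms", "accuracy", "task", "chance"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def task_labels(design: StimulusDesign, task: str) -> dict[str, str]:
    """Per-stimulus category label for a classification task."""
    if task == "coarse":
        return {s.id: s.coarse for s in design.stimuli}
    if task == "fine":
        return {s.id: s.fine for s in design.stimuli}
    if task in ("within_people", "within_places"):
        coarse = "person" if task == "within_people" else "place"
        return {s.id: s.fine for s in design.stimuli if s.coarse == coarse}
    raise ValueError(f"unknown task {task!r}")


def train_eval_at_timepoint(
    evoked: EvokedSet,
    labels: dict[str, str],
    split: tuple,
    t_index: int,
    spec: ClassifierSpec = ClassifierSpec(),
) -> float:
    """Fit on the train stimuli's channel vectors at one timepoint; return
    the fraction of test stimuli classified correctly."""
    train_ids, test_ids = split
    y_train = [labels[i] for i in train_ids]
    if len(set(y_train)) < 2:
        raise DegenerateLabelError("training labels contain a single class")
    x_train = np.stack([evoked.get(i)[:, t_index] for i in train_ids])
    x_test = np.stack([evoked.get(i)[:, t_index] for i in test_ids])
    clf = spec.make().fit(x_train, y_train)
    pred = clf.predict(x_test)
    return float(np.mean(pred == np.array([labels[i] for i in test_ids])))


def time_resolved_classification(
    cohort: list[EvokedSet],
    task: str,
    plan: SplitPlan,
    spec: ClassifierSpec = ClassifierSpec(),
    design: StimulusDesign | None = None,
    labels: dict[str, str] | None = None,
    t_indices=None,
) -> AccuracyTimecourse:
    """Per-subject, per-timepoint accuracy averaged over the plan's splits.

    ``labels`` (or ``design``, from which the task's labels are derived)
    maps stimulus ids to category names.  ``t_indices`` restricts evaluation
    to a subset of sample indices (default: every timepoint).
    """
    if labels is None:
        if design is None:
            raise ValueError("provide either design or labels")
        labels = task_labels(design, task)
    if task not in TASK_CHANCE:
        raise ValueError(f"unknown task {task!r}")
    if plan.scheme != _TASK_SCHEME[task]:
        raise ValueError(
            f"plan scheme {plan.scheme!r} incompatible with task {task!r}")
    needed = {i for tr, te in plan.splits for i in tr + te}
    for ev in cohort:
        missing = needed - set(ev.stimulus_ids)
        if missing:
            raise ValueError(
                f"subject {ev.subject_id}: stimuli missing from evoked set: "
                f"{sorted(missing)}")
    times = cohort[0].times
    if t_indices is None:
        t_indices = np.arange(len(times))
    t_indices = np.asarray(t_indices)
    acc = np.empty((len(cohort), len(t_indices)))
    for si, ev in enumerate(cohort):
        for tj, t in enumerate(t_indices):
            acc[si, tj] = np.mean([
                train_eval_at_timepoint(ev, labels, split, int(t), spec)
                for split in plan.splits])
    return AccuracyTimecourse(
        subject_ids=tuple(ev.subject_id for ev in cohort),
        times=times[t_indices], accuracies=acc,
        chance=TASK_CHANCE[task], task=task)


def transfer_classification(
    cohort: list[EvokedSet],
    task: str,
    design: StimulusDesign,
    spec: ClassifierSpec = ClassifierSpec(),
    t_indices=None,
) -> AccuracyTimecourse:
    """Entity-to-category transfer: train on all 32 proper-name responses,
    test on the 8 category-noun responses, separately at each timepoint."""
    if task not in ("coarse", "fine"):
        raise ValueError(f"transfer task must be 'coarse' or 'fine', got {task!r}")
    labels = task_labels(design, task)
    train_ids = tuple(s.id for s in design.entities)
    test_ids = tuple(s.id for s in design.category_nouns)
    for ev in cohort:
        missing = set(train_ids + test_ids) - set(ev.stimulus_ids)
        if missing:
            raise ValueError(
                f"subject {ev.subject_id}: stimuli missing from evoked set: "
                f"{sorted(missing)}")
    times = cohort[0].times
    if t_indices is None:
        t_indices = np.arange(len(times))
    t_indices = np.asarray(t_indices)
    acc = np.empty((len(cohort), len(t_indices)))
    for si, ev in enumerate(cohort):
        for tj, t in enumerate(t_indices):
            acc[si, tj] = train_eval_at_timepoint(
                ev, labels, (train_ids, test_ids), int(t), spec)
    chance = 0.5 if task == "coarse" else 0.125
    return AccuracyTimecourse(
        subject_ids=tuple(ev.subject_id for ev in cohort),
        times=times[t_indices], accuracies=acc, chance=chance,
        task=f"transfer_{task}")
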