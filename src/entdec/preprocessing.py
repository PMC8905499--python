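"""Baseline correction, repetition averaging, channel standardization.

Canonical order: ``baseline_correct`` on single trials, then
``average_repetitions`` to one evoked response per stimulus, then
``standardize_channels`` on the per-subject evoked set entering
classification and decoding.  Standardization is idempotent, so re-running
the last step changes nothing beyond floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np

from .design import StimulusDesign
from .simulate import EpochDataset, window_indices


class MissingDataError(ValueError):
    """A design stimulus has no trials in the dataset."""


class DegenerateChannelError(ValueError):
    """A channel has zero variance and cannot be standardized."""


@dataclass(frozen=True)
class EvokedSet:
    """Per-stimulus averaged responses: one n_channels x n_samples array each."""

    subject_id: str
    evoked: np.ndarray  # (n_stimuli, n_channels, n_samples)
    stimulus_ids: tuple[str, ...]
    times: np.ndarray
    rate: float

    def get(self, stimulus_id: str) -> np.ndarray:
        return self.evoked[self.stimulus_ids.index(stimulus_id)]

    def subset(self, ids) -> "EvokedSet":
        idx = [self.stimulus_ids.index(i) for i in ids]
        return replace(self, evoked=self.evoked[idx], stimulus_ids=tuple(ids))


def baseline_correct(
    dataset: EpochDataset, window: tuple[float, float] = (-100.0, 0.0)
) -> EpochDataset:
    """Subtract the mean pre-stimulus potential per trial and channel.

    Removes slow voltage drifts: for each trial and channel the average over
    ``window`` (default the -100..0 ms pre-stimulus interval) is subtracted
    from the whole epoch.
    """
    i0, i1 = window_indices(dataset.times, dataset.rate, window)
    base = dataset.trials[:, :, i0:i1 + 1].mean(axis=2, keepdims=True)
    return replace(dataset, trials=dataset.trials - base)


def average_repetitions(
    dataset: EpochDataset, design: StimulusDesign | None = None
) -> EvokedSet:
    """Arithmetic mean over the repetitions of each stimulus.

    Output order follows ``design`` when given (raising MissingDataError for
    design stimuli without trials), else first appearance in the dataset.
    """
    labels = np.asarray(dataset.stimulus_ids)
    if design is not None:
        order = design.stimulus_ids
        missing = sorted(set(order) - set(labels))
        if missing:
            raise MissingDataError(f"stimuli without trials: {missing}")
    else:
        order = list(dict.fromkeys(dataset.stimulus_ids))
    evoked = np.stack([dataset.trials[labels == sid].mean(axis=0) for sid in order])
    return EvokedSet(subject_id=dataset.subject_id, evoked=evoked,
                     stimulus_ids=tuple(order), times=dataset.times,
                     rate=dataset.rate)


def standardize_channels(evoked: EvokedSet) -> EvokedSet:
    """Z-score each channel using its grand mean/sd over all stimuli and samples.

    The sd uses the population (divide-by-N) convention.  A zero-variance
    channel raises DegenerateChannelError naming its index.
    """
    mean = evoked.evoked.mean(axis=(0, 2), keepdims=True)
    sd = evoked.evoked.std(axis=(0, 2), keepdims=True)
    dead = np.flatnonzero(sd.ravel() == 0)
    if dead.size:
        raise DegenerateChannelError(
            f"zero-variance channel(s): {dead.tolist()}")
    return replace(evoked, evoked=(evoked.evoked - mean) / sd)


def preprocess(
    dataset: EpochDataset,
    design: StimulusDesign | None = None,
    baseline_window: tuple[float, float] = (-100.0, 0.0),
) -> EvokedSet:
    """Full pipeline: baseline-correct, average repetitions, standardize."""
    return standardize_channels(
        average_repetitions(baseline_correct(dataset, baseline_window), design))


# ---------------------------------------------------------------- HDF5 i/o

def save_evoked(evoked: EvokedSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("evoked", data=evoked.evoked.astype(np.float32))
        f.create_dataset("times", data=evoked.times)
        f.create_dataset("stimulus_ids",
                         data=np.array(evoked.stimulus_ids, dtype="S"))
        f.attrs["rate"] = evoked.rate
        f.attrs["subject_id"] = evoked.subject_id


def load_evoked(path) -> EvokedSet:
    with h5py.File(path, "r") as f:
        return EvokedSet(
            subject_id=str(f.attrs["subject_id"]),
            evoked=f["evoked"][()].astype(np.float64),
            stimulus_ids=tuple(x.decode() for x in f["stimulus_ids"][()]),
            times=f["times"][()],
            rate=float(f.attrs["rate"]),
        )
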