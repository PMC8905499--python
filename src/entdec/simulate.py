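"""Synthetic entity vectors and synthetic evoked EEG epochs.

The generator plants exactly the statistical structure the downstream
analyses test for:

* entity vectors are hierarchical draws ``v(s) = mu_coarse + mu_fine + eps``
  so that K-means clustering and similarity analyses see coarse > fine >
  entity structure when the scale parameters are ordered that way;
* each epoch is a sum of boxcar-windowed components: a per-coarse-category
  channel template, a per-fine-category channel template, and a linear
  forward image ``A @ v(s)`` of the stimulus's entity vector, plus i.i.d.
  Gaussian sensor noise.  The forward map makes the linear-decodability
  assumption of ridge decoding literally true at zero noise.

Category-noun epochs share the category templates of their entities through
a mixing weight: at 1.0 (default) nouns and entities carry identical
category signal, at 0.0 nouns get independent templates, which emulates the
regime where nothing transfers from entities to category nouns.

All randomness flows through explicit integer seeds; cohort-level objects
(the channel templates and the forward map) derive from ``config.seed``
alone so that every subject of a cohort shares them, up to an optional
between-subject jitter.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd

from .design import StimulusDesign, validate_design


class DimensionError(ValueError):
    """Vector dimensionality incompatible with the forward map or request."""


@dataclass(frozen=True)
class VectorSet:
    """Named real vectors, one per stimulus (entities and category nouns)."""

    names: tuple[str, ...]
    vectors: np.ndarray  # (n_stimuli, dim)

    def __post_init__(self):
        if len(self.names) != self.vectors.shape[0]:
            raise DimensionError("one vector per name required")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.vectors[self.names.index(name)]

    def subset(self, names) -> "VectorSet":
        idx = [self.names.index(n) for n in names]
        return VectorSet(names=tuple(names), vectors=self.vectors[idx])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.vectors, columns=[f"d{i}" for i in range(self.dim)])
        df.insert(0, "id", list(self.names))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "VectorSet":
        df = pd.read_csv(path, sep="\t")
        return cls(names=tuple(df["id"].astype(str)),
                   vectors=df.drop(columns="id").to_numpy(float))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the epoch generator.

    Windows are in ms relative to stimulus onset and must lie inside
    ``epoch_window``.  ``sigma_coarse``/``sigma_fine``/``sigma_entity`` scale
    the three signal components (channel-template standard deviations for
    the category components, forward-map gain for the entity component);
    ``noise_sd`` is the per-sample sensor-noise standard deviation.
    """

    n_channels: int = 128
    rate: float = 256.0  # Hz
    epoch_window: tuple[float, float] = (-100.0, 1200.0)
    coarse_window: tuple[float, float] = (150.0, 800.0)
    fine_window: tuple[float, float] = (300.0, 450.0)
    entity_window: tuple[float, float] = (300.0, 1100.0)
    sigma_coarse: float = 1.0
    sigma_fine: float = 1.0
    sigma_entity: float = 1.0
    noise_sd: float = 5.0
    n_repetitions: int = 24
    noun_mixing: float = 1.0  # 1.0: nouns share category templates; 0.0: independent
    subject_jitter_sd: float = 0.0  # between-subject template jitter, relative scale
    seed: int = 0

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")
        t0, t1 = self.epoch_window
        for name in ("coarse_window", "fine_window", "entity_window"):
            a, b = getattr(self, name)
            if not (t0 <= a <= b <= t1):
                raise ValueError(f"{name} {(a, b)} outside epoch_window {(t0, t1)}")


@dataclass(frozen=True)
class EpochDataset:
    """One subject's epochs: trials x channels x samples."""

    subject_id: str
    trials: np.ndarray  # (n_trials, n_channels, n_samples)
    times: np.ndarray  # ms per sample
    stimulus_ids: tuple[str, ...]
    rate: float

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]


def sample_times(epoch_window: tuple[float, float], rate: float) -> np.ndarray:
    """Sample grid in ms: t_k = start + k/rate for k = 0..floor((end-start)*rate/1000).

    Endpoints inclusive at the start; for -100..1200 ms at 256 Hz this yields
    333 samples.
    """
    t0, t1 = epoch_window
    n = int(np.floor((t1 - t0) * rate / 1000.0)) + 1
    return t0 + np.arange(n) * 1000.0 / rate


def window_indices(times: np.ndarray, rate: float,
                   window: tuple[float, float]) -> tuple[int, int]:
    """Inclusive index pair (i0, i1) covering ``window`` on the sample grid.

    i0 is the sample at or immediately before the window start, i1 the
    sample at or immediately before the window end; both clipped to the
    grid.  Raises on a window outside the time axis.
    """
    a, b = window
    t0, t1 = times[0], times[-1]
    if a > b or a < t0 - 1000.0 / rate or b > t1 + 1000.0 / rate or b < t0 or a > t1:
        raise ValueError(f"window {(a, b)} outside time axis [{t0}, {t1}]")
    i0 = max(int(np.floor((a - t0) * rate / 1000.0)), 0)
    i1 = min(int(np.floor((b - t0) * rate / 1000.0)), len(times) - 1)
    return i0, i1


def generate_entity_vectors(
    design: StimulusDesign,
    dim: int = 50,
    sigma_coarse: float = 1.0,
    sigma_fine: float = 0.5,
    sigma_entity: float = 0.2,
    seed: int = 0,
    noun_scale: float = 1.0,
) -> VectorSet:
    """Hierarchically structured synthetic entity vectors.

    ``v(s) = mu_coarse(s) + mu_fine(s) + eps(s)`` with the category means
    drawn once per category (isotropic normal, scales ``sigma_coarse`` and
    ``sigma_fine``) and ``eps`` per entity at scale ``sigma_entity``.
    Category-noun vectors sit at their fine-category mean plus an
    independent entity-scale deviation multiplied by ``noun_scale``.
    """
    if dim < 2:
        raise DimensionError("dim must be >= 2")
    validate_design(design)
    rng = np.random.default_rng(seed)
    mu_coarse = {c: sigma_coarse * rng.standard_normal(dim)
                 for c in design.coarse_categories}
    mu_fine = {f: sigma_fine * rng.standard_normal(dim) for f in design.all_fine}
    names, rows = [], []
    for s in design.stimuli:
        eps = sigma_entity * rng.standard_normal(dim)
        if not s.is_entity:
            eps = noun_scale * eps
        rows.append(mu_coarse[s.coarse] + mu_fine[s.fine] + eps)
        names.append(s.id)
    return VectorSet(names=tuple(names), vectors=np.asarray(rows))


def _cohort_params(design: StimulusDesign, dim: int, config: GeneratorConfig):
    """Cohort-level templates and forward map, drawn from config.seed only."""
    rng = np.random.default_rng([config.seed, 101])
    t_coarse = {c: config.sigma_coarse * rng.standard_normal(config.n_channels)
                for c in design.coarse_categories}
    t_fine = {f: config.sigma_fine * rng.standard_normal(config.n_channels)
              for f in design.all_fine}
    # independent noun templates for the decoupled (noun_mixing < 1) regime
    noun_coarse = {f: config.sigma_coarse * rng.standard_normal(config.n_channels)
                   for f in design.all_fine}
    noun_fine = {f: config.sigma_fine * rng.standard_normal(config.n_channels)
                 for f in design.all_fine}
    forward = config.sigma_entity * rng.standard_normal(
        (config.n_channels, dim)) / np.sqrt(dim)
    return t_coarse, t_fine, noun_coarse, noun_fine, forward


def generate_epoch_dataset(
    design: StimulusDesign,
    vectors: VectorSet,
    config: GeneratorConfig,
    subject_id: str = "s00",
) -> EpochDataset:
    """Simulate one subject's epochs under the forward model.

    Each trial for stimulus ``s`` is ``T_coarse(s)*1[coarse_window] +
    T_fine(s)*1[fine_window] + (A @ v(s))*1[entity_window] + noise`` with
    boxcar window indicators.  Subject-specific randomness (noise and
    optional template jitter) is keyed on ``(config.seed, subject_id)``;
    the templates and ``A`` are cohort-level.
    """
    validate_design(design)
    missing = [i for i in design.stimulus_ids if i not in vectors.names]
    if missing:
        raise DimensionError(f"vectors missing stimuli: {missing}")
    t_coarse, t_fine, noun_coarse, noun_fine, forward = _cohort_params(
        design, vectors.dim, config)
    if forward.shape[1] != vectors.dim:
        raise DimensionError("forward map / vector dimension mismatch")

    subj_rng = np.random.default_rng(
        [config.seed, 202, zlib.crc32(subject_id.encode())])
    if config.subject_jitter_sd > 0:
        j = config.subject_jitter_sd
        t_coarse = {k: v + j * config.sigma_coarse
                    * subj_rng.standard_normal(v.shape) for k, v in t_coarse.items()}
        t_fine = {k: v + j * config.sigma_fine
                  * subj_rng.standard_normal(v.shape) for k, v in t_fine.items()}

    times = sample_times(config.epoch_window, config.rate)
    n_samp = len(times)
    cw = window_indices(times, config.rate, config.coarse_window)
    fw = window_indices(times, config.rate, config.fine_window)
    ew = window_indices(times, config.rate, config.entity_window)

    w = config.noun_mixing
    trials = np.empty(
        (len(design.stimuli) * config.n_repetitions, config.n_channels, n_samp),
        dtype=np.float64)
    stim_ids = []
    row = 0
    for s in design.stimuli:
        template = np.zeros((config.n_channels, n_samp))
        if s.is_entity:
            tc, tf = t_coarse[s.coarse], t_fine[s.fine]
        else:
            tc = w * t_coarse[s.coarse] + (1.0 - w) * noun_coarse[s.fine]
            tf = w * t_fine[s.fine] + (1.0 - w) * noun_fine[s.fine]
        template[:, cw[0]:cw[1] + 1] += tc[:, None]
        template[:, fw[0]:fw[1] + 1] += tf[:, None]
        template[:, ew[0]:ew[1] + 1] += (forward @ vectors.get(s.id))[:, None]
        for _ in range(config.n_repetitions):
            noise = config.noise_sd * subj_rng.standard_normal(template.shape) \
                if config.noise_sd > 0 else 0.0
            trials[row] = template + noise
            stim_ids.append(s.id)
            row += 1
    return EpochDataset(subject_id=subject_id, trials=trials, times=times,
                        stimulus_ids=tuple(stim_ids), rate=config.rate)


def make_cohort(
    design: StimulusDesign,
    vectors: VectorSet,
    config: GeneratorConfig,
    n_subjects: int,
) -> list[EpochDataset]:
    """Subject datasets sharing cohort templates, ids s00, s01, ..."""
    return [generate_epoch_dataset(design, vectors, config, subject_id=f"s{i:02d}")
            for i in range(n_subjects)]


def generate_mention_vectors(
    vectors: VectorSet,
    n_mentions: int = 8,
    n_layers: int = 4,
    mention_noise_sd: float = 0.1,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-mention, per-layer vectors around each stimulus vector.

    Emulates contextualized-model extraction: each mention is the stimulus
    vector plus mention-level noise, replicated over layers with additional
    layer-level noise.  Returns ``{id: array (n_mentions, n_layers, dim)}``.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for name in vectors.names:
        v = vectors.get(name)
        mention = v + mention_noise_sd * rng.standard_normal((n_mentions, 1, len(v)))
        layer = mention_noise_sd * rng.standard_normal((n_mentions, n_layers, len(v)))
        out[name] = mention + layer
    return out


# ---------------------------------------------------------------- HDF5 i/o

def save_epochs(dataset: EpochDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=dataset.trials.astype(np.float32))
        f.create_dataset("times", data=dataset.times)
        f.create_dataset("stimulus_ids",
                         data=np.array(dataset.stimulus_ids, dtype="S"))
        f.attrs["rate"] = dataset.rate
        f.attrs["subject_id"] = dataset.subject_id


def load_epochs(path) -> EpochDataset:
    with h5py.File(path, "r") as f:
        return EpochDataset(
            subject_id=str(f.attrs["subject_id"]),
            trials=f["trials"][()].astype(np.float64),
            times=f["times"][()],
            stimulus_ids=tuple(x.decode() for x in f["stimulus_ids"][()]),
            rate=float(f.attrs["rate"]),
        )
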