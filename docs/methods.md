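# Methods

## Stimulus design and session schedule

The design is 2 coarse categories (person, place) × 4 fine categories each
(musician, politician, actor, writer; body_of_water, monument, city,
country) × 4 entities, plus one noun stimulus per fine category: 40
stimuli, 32 of them proper names. Placeholder surface forms are
pronounceable consonant–vowel strings whose lengths are drawn per coarse
category (normal with mean 12 characters for people and 9 for places, sd 2,
truncated at 3). This preserves the only orthographic property the pipeline
consumes — the length-by-category confound structure — while real stimulus
lists can be supplied as TSV. Familiarity is synthesized uniformly on
[3, 5] (stimuli of this kind are selected for high familiarity) and is
pass-through metadata.

A session is 24 runs × 40 trials, each stimulus once per run. The question
multiset per run is fixed — 16 coarse questions, 24 fine questions of which
12 expect "correct" — and assigned to the shuffled stimulus order by a
uniform shuffle of question tokens. Quotas are enforced exactly per run (the
natural reading of a balanced design); `validate_schedule` re-counts them.
For a "wrong" fine question the probed category is drawn uniformly from the
seven other fine categories.

## Synthetic data generator

**Entity vectors.** `v(s) = μ_coarse(s) + μ_fine(s) + ε(s)` with isotropic
normal draws at scales `σ_coarse`, `σ_fine` (one draw per category) and
`σ_entity` (per stimulus). Category-noun vectors sit at their fine-category
mean plus an entity-scale deviation multiplied by `noun_scale` (default 1).
Defaults `σ_coarse=1, σ_fine=0.5, σ_entity=0.2, dim=50` give the
coarse-dominant hierarchical similarity structure that clustering analyses
of real entity embeddings show.

**Epochs.** The sample grid is `t_k = start + k/rate` for
`k = 0 … floor((end−start)·rate/1000)`, endpoints inclusive at the start:
for −100…1200 ms at 256 Hz, 333 samples at 3.90625 ms resolution. A window
[a, b] maps to the inclusive index range
`floor((a−t₀)·rate/1000) … floor((b−t₀)·rate/1000)` — the sample at or
immediately before the window start is included — so the 100–1200 ms
decoding window covers 282 samples (128 × 282 = 36,096 features).

Each trial is

```
x(s) = T_coarse(s)·1[150–800 ms] + T_fine(s)·1[300–450 ms]
     + (A · v(s))·1[300–1100 ms] + η,   η ~ N(0, noise_sd²) i.i.d.
```

with boxcar indicators (no ramp — the simplest testable choice). The
channel templates `T` (per category, scales `σ_coarse`, `σ_fine`) and the
forward map `A` (entries `σ_entity/√dim`) are cohort-level, drawn from
`config.seed` with fixed offsets, so all subjects of a cohort share them;
subject-level randomness (noise, optional template jitter at relative scale
`subject_jitter_sd`) is keyed on `(config.seed, crc32(subject_id))`. The
signal windows default to the latency ranges where category information is
typically found in evoked responses (semantic processing from ~150 ms, the
N400 range, and a late imagery-related interval).

Category nouns receive `w·T_cat + (1−w)·T_independent` with mixing weight
`w = noun_mixing`: at 1 (default) entity→category transfer succeeds
perfectly at zero noise, at 0 nothing transfers — both regimes are needed
to exercise the transfer analysis.

Default `noise_sd = 5` with 24 repetitions leaves per-evoked noise of
roughly the template scale (5/√24 ≈ 1), i.e. single-trial SNR well below 1,
qualitatively matching the low signal-to-noise regime of real EEG. What the
generator does **not** emulate: 1/f spectra, volume conduction, channel
covariance, artifacts, latency jitter. Passing tests therefore demonstrate
correctness of the analysis machinery under the linear forward model and
white noise, not performance on real recordings.

The generator follows the one-evoked-per-stimulus reading of the
preprocessing pipeline (24 repetitions averaged to a single evoked response
per stimulus and subject).

## Preprocessing

Baseline correction subtracts the −100…0 ms mean per trial and channel;
repetitions are averaged per stimulus (design order); channels are z-scored
using grand mean/sd pooled over all stimuli and timepoints of the
subject's evoked set, population (divide-by-N) convention for bit
reproducibility. Standardization operates on the averaged evoked set — the
object entering classification and decoding — and is idempotent. Whether
the original scaling preceded or followed averaging is not documented
anywhere we rely on; this package's convention is recorded here, not
claimed as anyone's intent. Filtering, artifact rejection and ICA are out
of scope: synthetic data are generated clean at the target rate.

## Splits and confound control

All balanced 4-entity test sets (2 people + 2 places, no fine category
repeated: 9,216) or within-coarse 2-entity sets (distinct fine categories:
96) are enumerated exhaustively in lexicographic order. For confound
control each candidate's stimuli are encoded as character lengths and its
labels as the mean entity length of the label (`level` chooses coarse or
fine encodings to match the analysis); Spearman ρ uses average ranks, and a
constant encoding defines ρ = 0 to keep the ordering total. Candidates are
stably sorted by |ρ| and the first 50 retained, which is optimal: no other
50-subset has a smaller maximum |ρ|. The within-coarse "balanced"
constraint (distinct fine categories) extends the leave-4-out rule by
analogy.

## Classification

`LinearSVC` (squared hinge, l2, C = 1.0, one-vs-rest, fixed random_state
for reproducibility) on the per-timepoint channel vectors. No scaling
beyond the preprocessing standardization. Transfer uses the whole dataset
(no splits): train on 32 entities, test on 8 nouns.

## Inference

TFCE with E = 0.5, H = 2 (the conventional defaults of the standard
implementations), threshold grid of 50 steps from 0 to the maximum of the
*observed* statistic — the grid is fixed before permutation so observed and
null enhancements integrate over identical thresholds. Adjacency: two
samples are adjacent iff their time difference ≤ 10 ms, so at 256 Hz a
cluster survives one sub-threshold sample between suprathreshold neighbors.
The group statistic is a one-sample t across subjects (consistent with the
sign-flip null; a mean-based variant is available); where the
between-subject sd is exactly 0 with nonzero mean the t is set to a large
cap (10⁶) rather than infinity. The null flips the sign of whole subject
rows; the identity permutation is always included, so the smallest
attainable p is 1/n_perm; family-wise correction is by the permutation
distribution of the maximum enhanced statistic.

Wilcoxon signed-rank tests drop zero differences, use exact enumeration for
n ≤ 12 without ties and the tie-corrected normal approximation otherwise;
an empty difference set returns p = 1 by convention. BH-FDR is the standard
step-up procedure.

## Decoding

Features: the 100–1200 ms block flattened channel-major. Ridge regression
with α = 1.0 (the common library default, configurable). For every
unordered pair the map is refitted without the pair — an assertion audits
the zero-shot contract on every fold — and scored by the Spearman sum rule,
with an exact tie scoring 0.5 (unbiased under symmetry). Per-subject
accuracy is the plain mean over all pairs. Pair-type tags (entity-entity /
category-category / mixed × people / places / mixed) drive the breakdown
table; empty bins are absent, not errors. The word-length control
correlates pairwise cosine similarity with absolute length difference over
all pairs.

## Embedding evaluation

Mention blocks (layers × dim) are truncated to the first 32 mentions in
sentence order (each mention counts once); the selected final layers are
averaged within mention, then across mentions (the means commute, which is
tested). Similarity benchmarks correlate pairwise cosines with human
scores, dropping unresolvable pairs and requiring ≥ 3. Clustering uses
K-means with seeded initialization, best inertia over 10 restarts, scored
by the adjusted Rand index.

## Problem sizes and numerical choices

The test suite exercises the pipeline at reduced scale (16–32 channels,
64–128 Hz, 4–8 repetitions) — the generative model is scale-free in
channels and rate, so nothing about the analyses changes — while
`scripts/acceptance.py` runs the chance-calibration analyses on one
full-scale subject (128 channels, 256 Hz, 24 repetitions) over the 50
confound-controlled splits at 20 evenly spaced timepoints, and the pairwise
chance statistic over all 496 entity pairs × 20 replicates. Floating-point
tolerances in tests are 1e−8–1e−10 for algebraic identities; stochastic
checks use fixed seeds and 3-standard-error bands computed from independent
per-timepoint means.

## Known limitations

* The synthetic noise is white; real EEG noise is strongly colored and
  spatially correlated, so absolute accuracies here do not predict real
  performance.
* TFCE is temporal-only (no channel adjacency), matching the time-resolved
  design; spatio-temporal TFCE is out of scope.
* The maximum |ρ| of retained fine-grained splits depends on the actual
  stimulus lengths; with synthesized lengths it is typically 0 and is not
  comparable to values obtained with any particular real stimulus list.
* Leave-two-out pairwise outcomes are mutually correlated (shared training
  sets), so the per-run mean accuracy has higher variance than a binomial
  count of independent pairs would suggest; the same holds for accuracy
  means over overlapping splits.
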