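"""Permutation significance with threshold-free cluster enhancement, plus
Wilcoxon signed-rank tests and Benjamini-Hochberg FDR control.

TFCE integrates, over an ascending grid of thresholds h, the quantity
``extent(h, p)^E * h^H * dh`` at every timepoint p, where extent is the size
of the suprathreshold cluster containing p.  Clusters are runs of timepoints
adjacent within a configurable window (default 10 ms, wider than one sample
step at 256 Hz, reflecting the minimum duration of post-synaptic
potentials).  Group-level significance uses a sign-flip permutation null on
subject accuracy-minus-chance curves with max-statistic family-wise
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon as _scipy_wilcoxon
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TfceParams:
    """E: extent exponent; H: height exponent; dh: threshold step (None ->
    one fiftieth of the maximum observed statistic); start: lowest
    threshold; adjacency_ms: temporal adjacency radius."""

    E: float = 0.5
    H: float = 2.0
    dh: float | None = None
    start: float = 0.0
    adjacency_ms: float = 10.0

    def __post_init__(self):
        if self.E < 0 or self.H < 0:
            raise ValueError("E and H must be >= 0")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be > 0")


@dataclass(frozen=True)
class SignificanceResult:
    times: np.ndarray
    pvalues: np.ndarray  # in (0, 1]
    alpha: float
    observed: np.ndarray  # TFCE-enhanced observed statistic

    @property
    def significant_mask(self) -> np.ndarray:
        return self.pvalues < self.alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.times, "pvalue": self.pvalues,
            "significant": self.significant_mask})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _clusters(mask: np.ndarray, times: np.ndarray, adjacency_ms: float):
    """Connected components of suprathreshold points under temporal adjacency.

    Two suprathreshold points belong to the same cluster when they are
    linked by a chain of suprathreshold points with consecutive time gaps
    <= adjacency_ms; sub-threshold samples inside such a gap do not break
    the cluster.
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    gaps = np.diff(times[idx])
    breaks = np.flatnonzero(gaps > adjacency_ms + 1e-9)
    return np.split(idx, breaks + 1)


def tfce_enhance(stat, params: TfceParams = TfceParams(), times=None) -> np.ndarray:
    """TFCE-enhanced statistic, one-sided (only values above ``start`` count).

    ``enhanced(p) = sum over h in (start+dh, start+2dh, ... <= stat(p)) of
    extent(h, p)^E * h^H * dh``.
    """
    stat = np.asarray(stat, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("statistic must be finite")
    if times is None:
        times = np.arange(stat.size, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.shape != stat.shape or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be strictly increasing and match stat")
    top = stat.max(initial=-np.inf)
    if top <= params.start:
        return np.zeros_like(stat)
    dh = params.dh if params.dh is not None else (top - params.start) / 50.0
    enhanced = np.zeros_like(stat)
    h = params.start + dh
    while h <= top + 1e-12:
        for cluster in _clusters(stat >= h, times, params.adjacency_ms):
            enhanced[cluster] += cluster.size ** params.E * h ** params.H * dh
        h += dh
    return enhanced


_T_CAP = 1e6  # stand-in t where the between-subject sd vanishes but the mean does not


def _t_stat(curves: np.ndarray) -> np.ndarray:
    """One-sample t across subjects per timepoint; degenerate (zero-sd)
    timepoints map to 0 when the mean is also 0, else to a large cap."""
    n = curves.shape[0]
    mean = curves.mean(axis=0)
    sd = curves.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * _T_CAP), t)


def permutation_significance(
    curves: np.ndarray,
    params: TfceParams = TfceParams(),
    n_perm: int = 1024,
    alpha: float = 0.05,
    seed: int = 0,
    times=None,
    statistic: str = "t",
) -> SignificanceResult:
    """Sign-flip permutation test on subject curves with TFCE + max-statistic.

    ``curves`` holds accuracy-minus-chance per subject and timepoint.  The
    observed per-timepoint statistic (one-sample t by default, subject mean
    with ``statistic="mean"``) is TFCE-enhanced; the null is built by
    randomly flipping the sign of whole subject rows, and each timepoint's
    p-value is the fraction of permutations (the identity included) whose
    maximum enhanced statistic reaches its observed enhanced value.
    """
    curves = np.asarray(curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("curves must be (n_subjects >= 2) x n_timepoints")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100 gives a coarse p-value grid",
                      stacklevel=2)
    if times is None:
        times = np.arange(curves.shape[1], dtype=float)
    times = np.asarray(times, dtype=float)
    stat_fn = _t_stat if statistic == "t" else (lambda c: c.mean(axis=0))
    if statistic not in ("t", "mean"):
        raise ValueError(f"statistic must be 't' or 'mean', got {statistic!r}")

    observed_stat = stat_fn(curves)
    finite_obs = np.where(np.isfinite(observed_stat), observed_stat, 0.0)
    top = finite_obs.max(initial=0.0)
    if top <= params.start:
        return SignificanceResult(times=times,
                                  pvalues=np.ones(curves.shape[1]),
                                  alpha=alpha,
                                  observed=np.zeros(curves.shape[1]))
    # fix the threshold grid from the observed statistic so that observed
    # and permuted enhancements are integrated over identical thresholds
    if params.dh is None:
        params = TfceParams(E=params.E, H=params.H,
                            dh=(top - params.start) / 50.0,
                            start=params.start,
                            adjacency_ms=params.adjacency_ms)
    observed = tfce_enhance(finite_obs, params, times)

    rng = np.random.default_rng(seed)
    n_subj = curves.shape[0]
    signs = rng.choice([-1.0, 1.0], size=(n_perm - 1, n_subj))
    null_max = np.empty(n_perm)
    null_max[0] = observed.max()  # identity permutation
    for i, s in enumerate(signs):
        stat_p = stat_fn(curves * s[:, None])
        stat_p = np.where(np.isfinite(stat_p), stat_p, 0.0)
        null_max[i + 1] = tfce_enhance(stat_p, params, times).max()
    pvalues = (null_max[None, :] >= observed[:, None] - 1e-12).mean(axis=1)
    return SignificanceResult(times=times, pvalues=pvalues, alpha=alpha,
                              observed=observed)


def wilcoxon_test(x, mu0: float = 0.0, mode: str = "one_sample_greater",
                  y=None) -> float:
    """Signed-rank p-value: exact enumeration for n <= 12 (tie-free),
    normal approximation with tie correction otherwise.

    ``one_sample_greater`` tests the median of ``x - mu0`` against zero,
    one-tailed; ``paired_two_sided`` tests ``x - y``, two-tailed.  Zero
    differences are discarded; an empty difference set returns p = 1 by
    convention, and fewer than 3 nonzero differences is an error.
    """
    x = np.asarray(x, dtype=float)
    if mode == "one_sample_greater":
        d = x - mu0
        alternative = "greater"
    elif mode == "paired_two_sided":
        if y is None:
            raise ValueError("paired mode requires y")
        d = x - np.asarray(y, dtype=float)
        alternative = "two-sided"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    if d.size < 3:
        raise ValueError("need >= 3 nonzero differences")
    ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 12 and not ties) else "approx"
    return float(_scipy_wilcoxon(d, alternative=alternative, method=method).pvalue)


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at FDR level ``q``."""
    pvalues = np.asarray(pvalues, dtype=float)
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must be in [0, 1]")
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(pvalues, alpha=q, method="fdr_bh")[0]
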