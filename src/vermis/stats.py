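"""Resampling and hypothesis-test utilities shared by all analysis stages.

Means and standard errors across units are estimated by leave-one-unit-out
jackknife; goodness-of-fit scores over time points use a 500-repetition
bootstrap.  Hypothesis tests wrap :mod:`scipy.stats` with the conventions
used throughout the pipeline (one-sided Student's t between jackknife
distributions, two-sided Wilcoxon signed-rank for paired early/late
behavior, zero-difference samples reported as p = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

log = logging.getLogger("vermis")

__all__ = [
    "ResampleReport",
    "jackknife_mean_sem",
    "bootstrap_gof",
    "one_sided_t",
    "two_sided_t",
    "wilcoxon_signed_rank",
]


@dataclass
class ResampleReport:
    """Point estimate plus resampled mean and SEM."""

    estimate: float | np.ndarray
    mean: float | np.ndarray
    sem: float | np.ndarray
    n_replicates: int
    scheme: str
    replicates: np.ndarray | None = None


def jackknife_mean_sem(
    statistic: Callable, units: Sequence, return_replicates: bool = False
) -> ResampleReport:
    """Leave-one-unit-out jackknife mean and SEM of ``statistic(units)``.

    The bias-corrected jackknife mean is ``n*theta - (n-1)*mean(theta_i)``
    and the SEM is ``sqrt((n-1)/n * sum((theta_i - mean)^2))``.  For a
    linear statistic (the sample mean) the SEM equals ``s/sqrt(n)`` exactly.
    """
    n = len(units)
    if n < 2:
        raise ValueError("jackknife requires at least 2 units")
    units = list(units)
    theta_full = np.asarray(statistic(units), dtype=float)
    reps = np.array(
        [statistic(units[:i] + units[i + 1 :]) for i in range(n)], dtype=float
    )
    rep_mean = reps.mean(axis=0)
    jack_mean = n * theta_full - (n - 1) * rep_mean
    sem = np.sqrt((n - 1) / n * ((reps - rep_mean) ** 2).sum(axis=0))
    return ResampleReport(
        estimate=theta_full,
        mean=jack_mean,
        sem=sem,
        n_replicates=n,
        scheme="leave-one-unit-out jackknife",
        replicates=reps if return_replicates else None,
    )


def bootstrap_gof(
    scores: np.ndarray, reps: int = 500, seed: int | np.random.Generator = 0
) -> ResampleReport:
    """Bootstrap mean +- SEM of per-timepoint scores (resampled over time)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, scores.size, size=(reps, scores.size))
    means = scores[idx].mean(axis=1)
    return ResampleReport(
        estimate=float(scores.mean()),
        mean=float(means.mean()),
        sem=float(means.std(ddof=1)) if reps > 1 else 0.0,
        n_replicates=reps,
        scheme=f"bootstrap-{reps}",
        replicates=means,
    )


def one_sided_t(a, b, alternative: str = "greater") -> tuple[float, float]:
    """One-sided two-sample Student's t test (equal variances)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                        equal_var=True, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def two_sided_t(a, b=None) -> tuple[float, float]:
    """Two-sided Student's t test; one-sample against 0 if ``b`` is None."""
    a = np.asarray(a, float)
    if b is None:
        res = sps.ttest_1samp(a, 0.0)
    else:
        res = sps.ttest_ind(a, np.asarray(b, float), equal_var=True)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x, y=None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon convention); an all-zero
    difference vector returns p = 1.  The exact null distribution is used
    for n <= 25 untied pairs, the tie-corrected normal approximation above.
    """
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    d = d[d != 0.0]
    if d.size == 0:
        log.info("wilcoxon_signed_rank: all differences zero; p = 1")
        return 0.0, 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
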