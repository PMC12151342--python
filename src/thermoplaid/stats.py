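"""Fish-level statistics.

Bout-derived quantities cluster by fish: most variability arises between
fish, not between individual swim bouts, so evaluating a two-sample KS test
against the number of bouts would wildly overstate significance.  The
bootstrapped KS test here resamples *entire fish* (each fish's values move
as one block): all fish are pooled, null variates are drawn by sampling fish
with replacement into two groups of the original sizes, and the p-value is
the fraction of null KS statistics at least as large as the observed one.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats as sps

GroupedSample = Sequence[np.ndarray]  # one 1-D value array per fish


def _validate(groups: GroupedSample, min_groups: int = 1) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(out) < min_groups or any(g.size == 0 for g in out):
        raise ValueError(f"need at least {min_groups} non-empty fish groups")
    return out


def ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic (max ECDF distance)."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def bootstrap_ks(
    a: GroupedSample,
    b: GroupedSample,
    n_boot: int = 10_000,
    seed: int | None = 0,
    resample_within_fish: bool = False,
) -> tuple[float, float]:
    """Fish-level bootstrapped two-sample KS test.

    The observed statistic is the ordinary KS distance between the pooled
    values of ``a`` and ``b``.  Null variates resample fish (with
    replacement) from the combined pool into two groups with the original
    fish counts; ``resample_within_fish`` additionally resamples values
    within each drawn fish.  Returns ``(ks_statistic, p_value)`` with the
    p-value floored at ``1 / n_boot`` (never reported as exactly 0).
    """
    a = _validate(a, min_groups=2)
    b = _validate(b, min_groups=2)
    observed = ks_statistic(np.concatenate(a), np.concatenate(b))
    pool = a + b
    n_a, n_b = len(a), len(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(pool), n_a + n_b)
        if resample_within_fish:
            va = np.concatenate(
                [rng.choice(pool[i], size=pool[i].size, replace=True) for i in idx[:n_a]]
            )
            vb = np.concatenate(
                [rng.choice(pool[i], size=pool[i].size, replace=True) for i in idx[n_a:]]
            )
        else:
            va = np.concatenate([pool[i] for i in idx[:n_a]])
            vb = np.concatenate([pool[i] for i in idx[n_a:]])
        if ks_statistic(va, vb) >= observed:
            count += 1
    p = max(count / n_boot, 1.0 / n_boot)
    return observed, p


def binned_density_with_se(
    values: GroupedSample,
    bin_edges: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram density with fish-level bootstrap standard errors.

    Every bootstrap replicate resamples fish with replacement and renormalizes,
    so each replicate's density integrates to one; the per-bin SE is the SD
    across replicates.
    """
    values = _validate(values, min_groups=2)
    bin_edges = np.asarray(bin_edges, dtype=float)
    rng = np.random.default_rng(seed)
    density, _ = np.histogram(np.concatenate(values), bins=bin_edges, density=True)
    boots = np.empty((n_boot, bin_edges.size - 1))
    for i in range(n_boot):
        idx = rng.integers(0, len(values), len(values))
        sample = np.concatenate([values[j] for j in idx])
        boots[i], _ = np.histogram(sample, bins=bin_edges, density=True)
    return density, boots.std(axis=0)


def ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney z form), as (statistic, p)."""
    res = sps.ranksums(a, b)
    return float(res.statistic), float(res.pvalue)


def signed_rank(paired_diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Uses the smaller-rank-sum convention, so fully one-sided differences give
    statistic 0.  All-zero differences are rejected (the test is undefined).
    """
    paired_diffs = np.asarray(paired_diffs, dtype=float)
    if np.all(paired_diffs == 0):
        raise ValueError("all paired differences are zero")
    res = sps.wilcoxon(paired_diffs)
    return float(res.statistic), float(res.pvalue)
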