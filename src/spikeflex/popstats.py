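"""Resampling statistics: per-animal bootstrap, permutation tests,
Benjamini-Hochberg correction, and a paired/unpaired test dispatcher.

Population statistics (e.g. percent non-classically responsive) are
bootstrapped by resampling each animal's units with replacement at the
animal's original yield, recomputing the statistic on the pooled
resample; group differences use a label-permutation test whose p-value
floor is 1/N (4e-6 at the default N = 250,000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class BootstrapStat:
    name: str
    estimate: float
    bootstrap_mean: float
    bootstrap_sem: float
    b: int
    n_excluded: int


def bootstrap_population_stat(
    animal_records: dict[str, np.ndarray],
    statistic: Callable[[np.ndarray], float],
    b: int = 2000,
    seed: int = 0,
    name: str = "statistic",
) -> BootstrapStat:
    """Per-animal bootstrap of a pooled population statistic."""
    groups = {a: np.asarray(v) for a, v in animal_records.items()}
    if not groups or any(v.size == 0 for v in groups.values()):
        raise ValueError("every animal needs >= 1 unit")
    pooled = np.concatenate(list(groups.values()))
    estimate = float(statistic(pooled))
    rng = np.random.default_rng(seed)
    reps = []
    excluded = 0
    for _ in range(b):
        draw = np.concatenate(
            [rng.choice(v, size=v.size, replace=True) for v in groups.values()]
        )
        val = statistic(draw)
        if np.isfinite(val):
            reps.append(float(val))
        else:
            excluded += 1
    reps = np.asarray(reps)
    mean = float(reps.mean()) if reps.size else float("nan")
    # the SD of the bootstrap distribution estimates the standard error
    sem = float(reps.std(ddof=1)) if reps.size > 1 else 0.0
    return BootstrapStat(name, estimate, mean, sem, b, excluded)


@dataclass
class PermutationResult:
    observed: float
    p_value: float
    n_resamples: int
    direction: str  # sign of the observed difference


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    statistic: Callable[[np.ndarray], float] = np.mean,
    n_resamples: int = 250_000,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided label-permutation test of statistic(A) - statistic(B).

    p = max(#{|perm diff| >= |observed|}, 1) / N, so the minimum
    reportable p equals 1/N.
    """
    a = np.asarray(group_a, dtype=float)
    bb = np.asarray(group_b, dtype=float)
    if a.size == 0 or bb.size == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(statistic(a) - statistic(bb))
    pooled = np.concatenate([a, bb])
    na, n = a.size, a.size + bb.size
    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(20_000, n_resamples))
    is_mean = statistic is np.mean
    done = 0
    while done < n_resamples:
        m = min(chunk, n_resamples - done)
        idx = np.argsort(rng.random((m, n)), axis=1)
        perm = pooled[idx]
        if is_mean:
            diffs = perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1)
        else:
            diffs = np.array(
                [statistic(row[:na]) - statistic(row[na:]) for row in perm]
            )
        count += int((np.abs(diffs) >= abs(observed) - 1e-12).sum())
        done += m
    p = max(count, 1) / n_resamples
    direction = "A>B" if observed > 0 else ("A<B" if observed < 0 else "A=B")
    return PermutationResult(observed, float(p), n_resamples, direction)


def benjamini_hochberg(
    p_values: Sequence[float], q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-up BH correction: adjusted p-values and the rejection set
    (adjusted <= q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def choose_test(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    alpha_normality: float = 0.05,
) -> tuple[str, float]:
    """Parametric-vs-rank test dispatcher following the normality rule
    (D'Agostino-Pearson): t-tests when both samples look normal, else
    Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired).

    Provided for completeness; the analyses default to the resampling
    tests above.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    try:
        normal = (
            stats.normaltest(a).pvalue > alpha_normality
            and stats.normaltest(b).pvalue > alpha_normality
        )
    except ValueError:
        warnings.warn("samples too small for normality test; using rank test")
        normal = False
    if paired:
        if normal:
            return "paired_t", float(stats.ttest_rel(a, b).pvalue)
        return "wilcoxon", float(stats.wilcoxon(a, b).pvalue)
    if normal:
        return "independent_t", float(stats.ttest_ind(a, b).pvalue)
    return "mann_whitney_u", float(
        stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    )
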