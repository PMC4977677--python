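"""Shared statistics: chi-squared homogeneity, Marascuilo post-hoc contrasts,
normal-approximation confidence intervals and Benjamini-Hochberg adjustment."""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class Chi2Result(NamedTuple):
    statistic: float
    df: int
    p_value: float


def _as_counts(table) -> np.ndarray:
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table needs >=2 rows and >=2 columns")
    if not np.isfinite(counts).all() or (counts < 0).any():
        raise ValueError("contingency table must hold finite non-negative counts")
    return counts


def chi2_homogeneity(table) -> Chi2Result:
    """Pearson chi-squared test of homogeneity on an r x c contingency table.

    statistic = sum (O-E)^2/E with E = row_total * col_total / grand_total,
    df = (r-1)(c-1). No continuity correction.
    """
    counts = _as_counts(table)
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("degenerate margins: a row or column total is zero")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return Chi2Result(float(stat), int(df), float(p))


def permutation_chi2_p(table, n_perm: int = 10_000, seed: int = 0,
                       mid_p: bool = False) -> float:
    """Monte-Carlo homogeneity p-value: permute individual observations
    across rows with row sizes fixed (conditions on both margins).

    Serves as an independent check of the asymptotic chi-squared p-value on
    small tables. The permutation null is discrete; ``mid_p=True`` counts
    ties at the observed statistic half, which removes the discreteness
    bias relative to the continuous chi-squared reference.
    """
    counts = _as_counts(table).astype(int)
    stat_obs = chi2_homogeneity(counts).statistic
    rng = np.random.default_rng(seed)
    r, c = counts.shape
    row_sizes = counts.sum(axis=1)
    pooled = np.repeat(np.arange(c), counts.sum(axis=0))
    greater = ties = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        perm = np.zeros((r, c), dtype=int)
        offset = 0
        for i, n_i in enumerate(row_sizes):
            perm[i] = np.bincount(pooled[offset:offset + n_i], minlength=c)
            offset += n_i
        stat = ((perm - _expected(perm)) ** 2 / _expected(perm)).sum()
        if stat > stat_obs + 1e-9:
            greater += 1
        elif abs(stat - stat_obs) <= 1e-9:
            ties += 1
    if mid_p:
        return (greater + 0.5 * ties) / n_perm
    return (greater + ties + 1) / (n_perm + 1)


def _expected(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    return np.outer(counts.sum(axis=1), counts.sum(axis=0)) / counts.sum()


class ProportionContrast(NamedTuple):
    row_a: int
    row_b: int
    column: int
    difference: float
    critical: float


def pairwise_proportions(table, alpha: float = 0.001,
                         method: str = "marascuilo") -> list[ProportionContrast]:
    """Simultaneous pairwise proportion contrasts after a chi-squared
    homogeneity test, valid for unequal group sizes.

    For each column (outcome bin) and each pair of rows (groups), the
    Marascuilo procedure flags |p_i - p_j| exceeding
    sqrt(chi2_crit(alpha, df=r-1)) * sqrt(p_i(1-p_i)/n_i + p_j(1-p_j)/n_j).

    ``method="bonferroni"`` instead runs pairwise two-proportion z-tests with
    a Bonferroni-corrected alpha.
    """
    counts = _as_counts(table)
    r, c = counts.shape
    n = counts.sum(axis=1)
    if (n == 0).any():
        raise ValueError("every row needs a positive total")
    props = counts / n[:, None]
    out: list[ProportionContrast] = []
    n_pairs = r * (r - 1) // 2
    for col in range(c):
        for i in range(r):
            for j in range(i + 1, r):
                diff = abs(props[i, col] - props[j, col])
                se2 = (props[i, col] * (1 - props[i, col]) / n[i]
                       + props[j, col] * (1 - props[j, col]) / n[j])
                if method == "marascuilo":
                    crit = float(np.sqrt(sps.chi2.ppf(1 - alpha, df=r - 1) * se2))
                    if diff > crit:
                        out.append(ProportionContrast(i, j, col, diff, crit))
                elif method == "bonferroni":
                    if se2 == 0:
                        continue
                    z = diff / np.sqrt(se2)
                    p = 2 * sps.norm.sf(z)
                    if p < alpha / (n_pairs * c):
                        out.append(ProportionContrast(i, j, col, diff, float(np.sqrt(se2))))
                else:
                    raise ValueError(f"unknown method {method!r}")
    return out


def mean_ci95(values) -> tuple[float, float, float]:
    """Mean with a 95 % normal-approximation confidence interval.

    Returns (mean, low, high) where low/high = mean -/+ 1.96 sd/sqrt(n).
    A single value yields a degenerate interval at that value.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("mean_ci95 needs at least one value")
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, mean, mean
    half = 1.96 * float(arr.std(ddof=1)) / np.sqrt(arr.size)
    return mean, mean - half, mean + half


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
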