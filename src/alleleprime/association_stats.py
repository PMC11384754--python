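"""Non-model statistics for allele-by-dose and repertoire comparisons.

Fisher exact tests on allele-by-dose 2x2 tables, exact/asymptotic Wilcoxon
rank-sum comparisons, t-distribution confidence intervals and tests for
heterozygote *02:*04 ratios, a bootstrap ratio-of-means for homozygote
group comparisons, Spearman/Pearson correlations (with small-sample
permutation p-values), the favourability ranking of IGHV1-2 genotypes, and
an optional Holm adjustment for the genotype-pair comparison family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "RatioCI",
    "ratio_t_ci",
    "bootstrap_ratio_of_means",
    "correlation",
    "genotype_rank",
    "holm_adjust",
]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table.

    The two-sided p sums the probabilities of all tables (under the
    hypergeometric null with fixed margins) no more probable than the
    observed one — the conventional definition, not the doubling rule.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    return float(stats.fisher_exact(table, alternative="two-sided").pvalue)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact: bool | None = None
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by full enumeration of rank assignments when there are no ties
    and the combined sample size is at most 20 (the default policy);
    otherwise the normal approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < combined.size
    if exact is None:
        exact = (not has_ties) and combined.size <= 20
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass(frozen=True)
class RatioCI:
    """Mean of per-participant ratios with a t-distribution CI and test."""

    mean: float
    ci_low: float
    ci_high: float
    p_value: float | None
    n: int
    df: int
    degenerate_variance: bool = False


def ratio_t_ci(ratios: Sequence[float], null: float = 1.0, level: float = 0.95) -> RatioCI:
    """t-distribution CI for a mean ratio and two-sided t-test against ``null``.

    Inputs with no variance (all ratios equal) are returned flagged with a
    zero-width CI and no p-value, rather than a spurious p of zero.
    """
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        raise ValueError("no ratios supplied")
    n = r.size
    mean = float(r.mean())
    if n < 2 or np.allclose(r, mean):
        return RatioCI(mean, mean, mean, None, n, max(n - 1, 0), True)
    se = r.std(ddof=1) / np.sqrt(n)
    tq = stats.t.ppf(0.5 + level / 2, df=n - 1)
    tstat = (mean - null) / se
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 1)
    return RatioCI(mean, mean - tq * se, mean + tq * se, float(p), n, n - 1)


def bootstrap_ratio_of_means(
    x_02: Sequence[float],
    x_04: Sequence[float],
    B: int = 10_000,
    seed: int | np.random.Generator | None = None,
    level: float = 0.95,
    null: float = 1.0,
) -> dict:
    """Bootstrap ratio of group means mean(x_02)/mean(x_04) with percentile CI.

    Participants are resampled with replacement within each group; the
    two-sided p-value inverts the percentile interval,
    ``p = 2 * min(P(r* <= null), P(r* >= null))`` (capped at 1), a
    documented convention since only the CI construction is standard.
    Fully reproducible for a fixed seed.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    x = np.asarray(x_02, dtype=float)
    y = np.asarray(x_04, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    idx_x = rng.integers(0, x.size, size=(B, x.size))
    idx_y = rng.integers(0, y.size, size=(B, y.size))
    means_x = x[idx_x].mean(axis=1)
    means_y = y[idx_y].mean(axis=1)
    with np.errstate(divide="ignore"):
        ratios = np.where(means_y > 0, means_x / means_y, np.inf)
    alpha = 1.0 - level
    lo, hi = np.quantile(ratios, [alpha / 2, 1 - alpha / 2])
    p = 2.0 * min((ratios <= null).mean(), (ratios >= null).mean())
    return {
        "ratio": float(x.mean() / y.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p_value": float(min(p, 1.0)),
        "B": B,
    }


def _perm_pvalue_exact(x: np.ndarray, y: np.ndarray, stat) -> float:
    """Two-sided permutation p by full enumeration of pairings of y to x."""
    observed = abs(stat(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(range(y.size)):
        total += 1
        if abs(stat(x, y[list(perm)])) >= observed - 1e-12:
            count += 1
    return count / total


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "spearman",
    p_method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Correlation coefficient and p-value.

    ``method`` is ``"spearman"`` (rank-based, average ranks for ties) or
    ``"pearson"`` (linear). The p-value uses the t approximation by
    default; ``p_method="permutation"`` enumerates all pairings exactly for
    n <= 8 and otherwise uses ``n_permutations`` seeded Monte-Carlo draws.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
        stat = lambda a, b: stats.spearmanr(a, b).statistic
    elif method == "pearson":
        res = stats.pearsonr(x, y)
        r, p = res.statistic, res.pvalue
        stat = lambda a, b: stats.pearsonr(a, b).statistic
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    if p_method == "permutation":
        if x.size <= 8:
            p = _perm_pvalue_exact(x, y, stat)
        else:
            rng = np.random.default_rng(seed)
            observed = abs(r)
            hits = sum(
                abs(stat(x, rng.permutation(y))) >= observed - 1e-12
                for _ in range(n_permutations)
            )
            p = (hits + 1) / (n_permutations + 1)
    elif p_method != "asymptotic":
        raise ValueError("p_method must be 'asymptotic' or 'permutation'")
    return float(r), float(p)


#: Most-to-least favourable genotypes for inducing a VRC01-class response,
#: ranked by expected precursor frequency (*02 precursors ~4x more common
#: than *04; *05/*06 lack the binding motif).
_GENOTYPE_RANKS = {
    ("*02", "*02"): 1,
    ("*02", "*04"): 2,
    ("*02", "*05"): 3,
    ("*02", "*06"): 3,
    ("*04", "*04"): 4,
    ("*04", "*05"): 5,
    ("*04", "*06"): 5,
}


def genotype_rank(allele_1: str, allele_2: str) -> int | None:
    """Favourability rank 1-5 of an IGHV1-2 genotype, or None if unranked.

    The *05/*06 genotype carries no VRC01-class-capable allele and is
    unranked. The non-coding *02_S4953 variant counts as *02.
    """
    a = "*02" if allele_1 == "*02_S4953" else allele_1
    b = "*02" if allele_2 == "*02_S4953" else allele_2
    return _GENOTYPE_RANKS.get(tuple(sorted((a, b))))


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    m = p.size
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted
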