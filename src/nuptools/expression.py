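"""Expression layer: expressed flags, Tau tissue-specificity, and the
group comparisons (Fisher expressed-fraction tests, Wilcoxon rank tests,
Bonferroni-corrected functional-term enrichment).

The Tau index summarises how narrowly a gene is expressed across N
tissues:

    tau = sum_i (1 - x_i / max_j x_j) / (N - 1)

on raw (untransformed) TPM values. tau = 0 for perfectly uniform positive
expression, tau = 1 when expression is confined to a single tissue; it is
undefined (flagged) for an all-zero gene. All tests are two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: exact-permutation Wilcoxon up to this combined sample size
_EXACT_WILCOXON_MAX_N = 12


def flag_expressed(matrix: pd.DataFrame, threshold: float = 0.0) -> pd.Series:
    """Per-gene expressed flag: TPM > threshold in at least one tissue.

    ``matrix`` has genes as rows and tissues as columns. Monotone in the
    threshold: raising it never adds expressed genes.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("TPM values must be non-negative")
    return (matrix > threshold).any(axis=1)


@dataclass(frozen=True)
class TauResult:
    gene_id: str | None
    tau: float
    n_tissues: int
    defined: bool


def tau(values: Sequence[float], gene_id: str | None = None) -> TauResult:
    """Tau tissue-specificity index of one gene's expression profile.

    Requires >= 2 tissues and non-negative values. A gene with zero
    maximum expression has no defined specificity (``defined=False``,
    tau reported as NaN).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("Tau requires at least 2 tissues")
    if (x < 0).any():
        raise ValueError("expression values must be non-negative")
    m = x.max()
    if m == 0:
        return TauResult(gene_id, float("nan"), x.size, False)
    t = float(np.sum(1.0 - x / m) / (x.size - 1))
    return TauResult(gene_id, t, x.size, True)


def tau_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Tau for every gene in a genes x tissues TPM matrix."""
    rows = [tau(matrix.loc[g].to_numpy(), gene_id=g) for g in matrix.index]
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in rows],
            "tau": [r.tau for r in rows],
            "n_tissues": [r.n_tissues for r in rows],
            "defined": [r.defined for r in rows],
        }
    )


def fisher_fraction_test(
    group_expressed: int, group_total: int, bg_expressed: int, bg_total: int
) -> float:
    """Two-sided Fisher exact test of a group's expressed fraction against
    the rest of the background.

    The group must be a subset of the background; the 2x2 table contrasts
    (expressed, unexpressed) in the group vs in the background minus the
    group.
    """
    if group_total <= 0:
        raise ValueError("group_total must be positive")
    if group_expressed > group_total or group_expressed < 0:
        raise ValueError("group_expressed must lie in [0, group_total]")
    if group_total > bg_total or group_expressed > bg_expressed:
        raise ValueError("group must be a subset of the background")
    rest_expressed = bg_expressed - group_expressed
    rest_unexpressed = (bg_total - group_total) - rest_expressed
    if rest_unexpressed < 0:
        raise ValueError("inconsistent background counts")
    table = [
        [group_expressed, group_total - group_expressed],
        [rest_expressed, rest_unexpressed],
    ]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _rank_sum_u(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of sample a, from midranks of the pooled data."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return r_a - a.size * (a.size + 1) / 2.0


def wilcoxon_rank_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic of sample a, two-sided p). For combined sample
    sizes up to 12 the p-value is computed by full enumeration of the
    C(n_a+n_b, n_a) group relabelings of the pooled midranks (exact even
    under ties); larger samples use the normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    u = _rank_sum_u(a, b)
    n, m = a.size, b.size
    mu = n * m / 2.0
    if n + m <= _EXACT_WILCOXON_MAX_N:
        ranks = stats.rankdata(np.concatenate([a, b]))
        offset = n * (n + 1) / 2.0
        obs_dev = abs(u - mu)
        count = total = 0
        for combo in itertools.combinations(range(n + m), n):
            u_perm = ranks[list(combo)].sum() - offset
            total += 1
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                count += 1
        return u, count / total
    _, p = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u, float(p)


@dataclass(frozen=True)
class GroupTest:
    """One group-vs-background comparison with its (adjusted) p-value."""

    label: str
    statistic: float
    p: float
    p_adjusted: float
    n_group: int
    n_background: int
    direction: str = ""


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def term_enrichment(
    gene_set: Sequence[str],
    background: Sequence[str],
    term_table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher exact over/under-representation of functional terms in a
    gene set against a background, Bonferroni-corrected.

    ``term_table`` needs columns ``gene_id`` and ``term_id``. Every term
    annotating at least one background gene is tested (two-sided), and m =
    number of terms tested enters the correction. A term is significant at
    adjusted p < alpha.
    """
    if term_table.empty:
        raise ValueError("empty term table")
    bg = set(background)
    gs = set(gene_set)
    if not gs <= bg:
        raise ValueError("gene_set must be a subset of background")
    ann = term_table[term_table["gene_id"].isin(bg)]
    terms = sorted(ann["term_id"].unique())
    m = len(terms)
    if m == 0:
        raise ValueError("no terms annotate the background")
    N, K = len(bg), len(gs)
    rows = []
    genes_by_term = ann.groupby("term_id")["gene_id"].apply(set)
    for term in terms:
        with_term = genes_by_term[term]
        k = len(with_term & gs)
        n_term = len(with_term)
        table = [[k, K - k], [n_term - k, (N - K) - (n_term - k)]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        p_adj = bonferroni(p, m)
        expected = K * n_term / N
        rows.append(
            {
                "term_id": term,
                "k_in_set": k,
                "n_set": K,
                "k_in_background": n_term,
                "n_background": N,
                "odds_ratio": odds,
                "p": p,
                "p_adjusted": p_adj,
                "direction": "over" if k > expected else ("under" if k < expected else "none"),
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)
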