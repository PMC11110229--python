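"""Expression statistics against enumeration oracles and closed forms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom, rankdata

from nuptools.expression import (
    bonferroni,
    fisher_fraction_test,
    flag_expressed,
    tau,
    term_enrichment,
    wilcoxon_rank_test,
)


class TestFlags:
    def test_all_zero_unexpressed(self):
        m = pd.DataFrame({"t1": [0.0], "t2": [0.0]}, index=["g"])
        assert not flag_expressed(m).iloc[0]

    def test_threshold_monotone(self):
        m = pd.DataFrame({"t1": [0.3], "t2": [0.0]}, index=["g"])
        assert flag_expressed(m, 0.0).iloc[0]
        assert not flag_expressed(m, 1.0).iloc[0]

    def test_matches_brute_force(self, rng):
        m = pd.DataFrame(rng.exponential(1.0, size=(50, 5)))
        for t in (0.0, 0.5, 2.0):
            oracle = [(row > t).any() for _, row in m.iterrows()]
            assert flag_expressed(m, t).tolist() == oracle


class TestTau:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((5, 5, 5, 5, 5), 0.0),
            ((0, 0, 7, 0, 0), 1.0),
            ((1, 2, 4, 8, 16), 0.765625),
        ],
    )
    def test_closed_forms(self, values, expected):
        assert tau(values).tau == pytest.approx(expected, abs=1e-12)

    def test_undefined_for_silent_gene(self):
        r = tau((0.0, 0.0, 0.0))
        assert not r.defined and np.isnan(r.tau)

    def test_too_few_tissues(self):
        with pytest.raises(ValueError):
            tau((1.0,))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tau((1.0, -0.1))

    @given(
        st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=10),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_and_scale_invariance(self, values, c):
        x = np.asarray(values)
        if x.max() == 0:
            return
        t = tau(x).tau
        assert 0.0 <= t <= 1.0 + 1e-12
        assert tau(c * x).tau == pytest.approx(t, abs=1e-9)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by enumeration of all tables with fixed margins:
    sum the hypergeometric probabilities no larger than the observed one."""
    n1, N, K = a + b, a + b + c + d, a + c
    p_obs = hypergeom.pmf(a, N, K, n1)
    total = 0.0
    for k in range(max(0, n1 + K - N), min(n1, K) + 1):
        p = hypergeom.pmf(k, N, K, n1)
        if p <= p_obs * (1 + 1e-7):  # tolerance for float-equal tables
            total += p
    return min(total, 1.0)


class TestFisher:
    def test_matches_enumeration_example(self):
        # group 8/10 expressed vs rest-of-background 42/90
        p = fisher_fraction_test(8, 10, 50, 100)
        assert p == pytest.approx(fisher_oracle(8, 2, 42, 48), rel=1e-9)

    def test_modal_table_p_one(self):
        # group proportion identical to background at the modal table
        p = fisher_fraction_test(5, 10, 50, 100)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_random_tables_match_oracle(self, rng):
        """Exact agreement with full enumeration for margins <= 30."""
        for _ in range(100):
            n_g = int(rng.integers(1, 16))
            n_rest = int(rng.integers(1, 16))
            a = int(rng.integers(0, n_g + 1))
            c = int(rng.integers(0, n_rest + 1))
            p = fisher_fraction_test(a, n_g, a + c, n_g + n_rest)
            assert p == pytest.approx(
                fisher_oracle(a, n_g - a, c, n_rest - c), rel=1e-7
            )

    def test_inconsistent_input_rejected(self):
        with pytest.raises(ValueError):
            fisher_fraction_test(11, 10, 50, 100)
        with pytest.raises(ValueError):
            fisher_fraction_test(0, 0, 50, 100)


def wilcoxon_oracle(a, b):
    """Full-permutation two-sided rank-sum p on midranks."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = a.size, b.size
    ranks = rankdata(np.concatenate([a, b]))
    mu = n * m / 2.0
    offset = n * (n + 1) / 2.0
    obs = abs(ranks[:n].sum() - offset - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n + m), n):
        dev = abs(ranks[list(combo)].sum() - offset - mu)
        total += 1
        if dev >= obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_identical_multisets(self):
        u, p = wilcoxon_rank_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.99

    def test_complete_separation_exact(self):
        """a=(1,2,3) vs b=(10,11,12): 2 of the C(6,3)=20 splits are as
        extreme, so the exact two-sided p is 0.1."""
        _, p = wilcoxon_rank_test([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_matches_permutation_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 6))
            a = rng.integers(0, 8, size=n).astype(float)  # ties likely
            b = rng.integers(0, 8, size=m).astype(float)
            _, p = wilcoxon_rank_test(a, b)
            assert p == pytest.approx(wilcoxon_oracle(a, b), abs=1e-12)

    def test_normal_approximation_close_to_exact(self, rng):
        """Large-sample p within 0.01 of the exact enumeration at n=6 vs 6."""
        from nuptools import expression

        a = rng.normal(0, 1, size=6)
        b = rng.normal(0.5, 1, size=6)
        _, p_exact = wilcoxon_rank_test(a, b)
        old = expression._EXACT_WILCOXON_MAX_N
        try:
            expression._EXACT_WILCOXON_MAX_N = 0  # force the approximation
            _, p_approx = wilcoxon_rank_test(a, b)
        finally:
            expression._EXACT_WILCOXON_MAX_N = old
        assert abs(p_exact - p_approx) < 0.01

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_test([], [1.0])


class TestTermEnrichment:
    def build_tables(self, rng, factor=5.0):
        background = [f"g{i:03d}" for i in range(200)]
        gene_set = background[:40]
        rows = []
        for g in background:
            p_planted = 0.08 * factor if g in gene_set else 0.08
            if rng.random() < p_planted:
                rows.append({"gene_id": g, "term_id": "PLANTED", "namespace": "GO"})
            for t in range(8):
                if rng.random() < 0.10:
                    rows.append({"gene_id": g, "term_id": f"T{t}", "namespace": "GO"})
        return gene_set, background, pd.DataFrame(rows)

    def test_planted_term_recovered(self, rng):
        gene_set, background, table = self.build_tables(rng)
        res = term_enrichment(gene_set, background, table).set_index("term_id")
        assert res.loc["PLANTED", "significant"]
        assert res.loc["PLANTED", "direction"] == "over"
        # terms without planted signal stay non-significant
        assert not res.drop(index="PLANTED")["significant"].any()

    def test_single_term_unadjusted(self):
        table = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "term_id": ["T", "T"], "namespace": ["GO"] * 2}
        )
        res = term_enrichment(["g1"], ["g1", "g2", "g3"], table)
        assert res["p"].iloc[0] == res["p_adjusted"].iloc[0]  # m = 1

    def test_universal_term_uninformative(self):
        genes = [f"g{i}" for i in range(10)]
        table = pd.DataFrame(
            {"gene_id": genes, "term_id": ["T"] * 10, "namespace": ["GO"] * 10}
        )
        res = term_enrichment(genes[:4], genes, table)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment(["g1"], ["g1"], pd.DataFrame())

    def test_bonferroni_never_decreases(self):
        assert bonferroni(0.01, 7) == pytest.approx(0.07)
        assert bonferroni(0.3, 10) == 1.0
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)
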