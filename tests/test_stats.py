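import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from episcan import stats
from episcan.core_data import PhenotypeVector
from episcan.stats import (
    ContingencyTable,
    anova_f,
    brute_force_scan,
    chi_square,
    contingency_table,
    g_statistic,
    joint_group_labels,
    mutual_information,
    pair_stats_for_phenotypes,
)
from episcan.synth import null_binary_dataset, null_quantitative_dataset

from conftest import make_genotypes, make_phenotype


class TestAnova:
    @pytest.mark.parametrize(
        "values, labels, ssb, ssw, f",
        [
            # zero within-group variance -> perfect separation, F = +inf
            ([1, 1, 3, 3], [0, 0, 1, 1], 4.0, 0.0, float("inf")),
            # hand-computed one-way ANOVA
            ([0, 2, 1, 3], [0, 0, 1, 1], 1.0, 4.0, 0.5),
            # equal group means -> F = 0
            ([0, 2, 2, 0], [0, 0, 1, 1], 0.0, 4.0, 0.0),
        ],
    )
    def test_examples(self, values, labels, ssb, ssw, f):
        r = anova_f(np.array(values, float), np.array(labels))
        assert r.ss_between == pytest.approx(ssb, abs=1e-12)
        assert r.ss_within == pytest.approx(ssw, abs=1e-12)
        assert r.f == f

    def test_scipy_oracle(self, rng):
        from scipy.stats import f_oneway

        for _ in range(20):
            labels = rng.integers(0, 3, size=30)
            values = rng.normal(size=30)
            groups = [values[labels == g] for g in np.unique(labels)]
            expected = f_oneway(*groups).statistic
            assert anova_f(values, labels).f == pytest.approx(expected, rel=1e-9)

    def test_monomorphic_split_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            anova_f(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))

    def test_no_residual_df_error(self):
        with pytest.raises(ValueError, match="residual"):
            anova_f(np.array([1.0, 2.0]), np.array([0, 1]))

    @given(st.integers(0, 2**32 - 1))
    def test_ss_decomposition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        values = rng.normal(size=n)
        labels = rng.integers(0, 4, size=n)
        if np.unique(labels).size < 2:
            labels[0] = (labels[0] + 1) % 4
        r = anova_f(values, labels)
        assert r.ss_between + r.ss_within == pytest.approx(
            r.ss_total, rel=1e-9, abs=1e-9 * max(1.0, r.ss_total)
        )


class TestJointGroups:
    @pytest.mark.parametrize(
        "xi, xj, k",
        [
            ((0, 0, 1, 1), (0, 1, 0, 1), 4),  # all four cells occupied
            ((0, 0, 1, 1), (0, 0, 1, 1), 2),  # identical SNPs collapse
            ((0, 0, 0, 0), (0, 1, 0, 1), 2),  # monomorphic anchor
        ],
    )
    def test_examples(self, xi, xj, k):
        labels, got_k = joint_group_labels(np.array(xi), np.array(xj), 2)
        assert got_k == k

    def test_label_formula(self):
        labels, _ = joint_group_labels(
            np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]), 2
        )
        assert list(labels) == [0, 1, 2, 3]


class TestContingency:
    def test_direct_count(self):
        t = contingency_table(
            np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1]),
            np.array([1, 1, 0, 0]), 2,
        )
        assert list(t.col_margins) == [1, 1, 1, 1]
        assert t.n == 4

    def test_joint_permutation_invariance(self, rng):
        xi = rng.integers(0, 2, 20)
        xj = rng.integers(0, 2, 20)
        y = rng.integers(0, 2, 20)
        perm = rng.permutation(20)
        t1 = contingency_table(xi, xj, y, 2)
        t2 = contingency_table(xi[perm], xj[perm], y[perm], 2)
        assert np.array_equal(t1.counts, t2.counts)

    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[10, 10], [10, 10]], 0.0),  # exact independence
            ([[3, 1], [1, 3]], 2.0),  # all E = 2
            ([[30, 10], [10, 30]], 20.0),  # 10x cells -> 10x chi-square
        ],
    )
    def test_chi_square_examples(self, table, expected):
        t = ContingencyTable(np.array(table), np.arange(2))
        assert chi_square(t) == pytest.approx(expected, rel=1e-12)

    def test_chi_square_scipy_oracle(self, rng):
        from scipy.stats import chi2_contingency

        for _ in range(20):
            counts = rng.integers(1, 20, size=(2, 4))
            t = ContingencyTable(counts, np.arange(4))
            ref = chi2_contingency(counts, correction=False)
            assert chi_square(t) == pytest.approx(ref.statistic, rel=1e-9)
            assert g_statistic(t) == pytest.approx(
                chi2_contingency(counts, correction=False,
                                 lambda_="log-likelihood").statistic,
                rel=1e-9,
            )

    def test_g_hand_formula(self):
        t = ContingencyTable(np.array([[3, 1], [1, 3]]), np.arange(2))
        assert g_statistic(t) == pytest.approx(12 * math.log(1.5) - 4 * math.log(2),
                                               rel=1e-12)

    def test_g_zero_cell_finite(self):
        t = ContingencyTable(np.array([[2, 0], [0, 2]]), np.arange(2))
        g = g_statistic(t)
        assert math.isfinite(g) and g > 0

    def test_mi_identity_example(self):
        t = ContingencyTable(np.array([[3, 1], [1, 3]]), np.arange(2))
        assert mutual_information(t) == pytest.approx(
            g_statistic(t) / (2 * 8), rel=1e-12
        )

    def test_independence_zero_for_all(self):
        t = ContingencyTable(np.array([[6, 2], [3, 1]]), np.arange(2))
        assert chi_square(t) == pytest.approx(0.0, abs=1e-12)
        assert g_statistic(t) == pytest.approx(0.0, abs=1e-12)
        assert mutual_information(t) == pytest.approx(0.0, abs=1e-12)

    def test_single_class_error(self):
        t = ContingencyTable(np.array([[2, 3], [0, 0]]), np.arange(2))
        for func in (chi_square, g_statistic, mutual_information):
            with pytest.raises(ValueError, match="single-class"):
                func(t)

    @given(st.integers(0, 2**32 - 1))
    def test_g_equals_2n_mi_and_entropy_bound(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 6))
        counts = rng.integers(0, 15, size=(2, k))
        counts[:, counts.sum(axis=0) == 0] += 1
        if counts[0].sum() == 0:
            counts[0, 0] += 1
        if counts[1].sum() == 0:
            counts[1, 0] += 1
        t = ContingencyTable(counts, np.arange(counts.shape[1]))
        g = g_statistic(t)
        mi = mutual_information(t)
        assert g == pytest.approx(2 * t.n * mi, rel=1e-9, abs=1e-12)
        assert mi <= min(math.log(2), math.log(t.k)) + 1e-12

    def test_column_reorder_invariance(self, rng):
        counts = rng.integers(1, 10, size=(2, 4))
        t1 = ContingencyTable(counts, np.arange(4))
        perm = rng.permutation(4)
        t2 = ContingencyTable(counts[:, perm], np.arange(4))
        for func in (chi_square, g_statistic, mutual_information):
            assert func(t1) == pytest.approx(func(t2), rel=1e-12)


class TestBruteForce:
    def test_pair_count(self):
        G, y = null_quantitative_dataset(1, m=5, n=20)
        assert len(brute_force_scan(G, y, "anova")) == 10

    def test_duplicate_snp_matches_single_locus(self):
        # pair (i, duplicate of i) adds no extra split
        xi = np.array([0, 0, 1, 1, 0, 1])
        G = make_genotypes(np.vstack([xi, xi]))
        y = make_phenotype([0.5, 1.2, 3.0, 2.8, 0.1, 3.3])
        res = brute_force_scan(G, y, "anova")
        single = anova_f(y.values, xi)
        assert res.rows[0].statistic == pytest.approx(single.f, rel=1e-12)
        assert res.rows[0].k == single.k

    def test_incompatible_test_rejected(self):
        G, y = null_quantitative_dataset(2, m=4, n=20)
        with pytest.raises(ValueError):
            brute_force_scan(G, y, "chi2")
        Gb, yb = null_binary_dataset(2, m=4, n=20)
        with pytest.raises(ValueError):
            brute_force_scan(Gb, yb, "anova")

    def test_snp_reordering_invariance(self, rng):
        G, y = null_binary_dataset(3, m=8, n=30)
        res1 = {(r.snp_a, r.snp_b): r.statistic for r in
                brute_force_scan(G, y, "chi2").rows}
        perm = rng.permutation(G.m)
        G2 = make_genotypes(G.codes[perm])
        G2.snp_ids = [G.snp_ids[p] for p in perm]
        res2 = {tuple(sorted((r.snp_a, r.snp_b))): r.statistic for r in
                brute_force_scan(G2, y, "chi2").rows}
        for pair, stat in res1.items():
            assert res2[pair] == pytest.approx(stat, rel=1e-12)


class TestVectorizedPhenotypeBatch:
    @pytest.mark.parametrize("alphabet", ["binary", "triallelic"])
    @pytest.mark.parametrize("test", ["chi2", "gtest", "mi"])
    def test_matches_brute_force_per_column(self, alphabet, test, rng):
        G, y = null_binary_dataset(5, m=7, n=40, alphabet=alphabet)
        perms = np.stack([rng.permutation(40) for _ in range(6)])
        Y = y.values[perms].T
        got = pair_stats_for_phenotypes(G, Y, test)
        for k in range(6):
            yk = PhenotypeVector(y.values[perms[k]], "binary", y.individual_ids)
            ref = {(r.snp_a, r.snp_b): r.statistic
                   for r in brute_force_scan(G, yk, test).rows}
            p = 0
            for i in range(G.m - 1):
                for j in range(i + 1, G.m):
                    key = (G.snp_ids[i], G.snp_ids[j])
                    assert got[p, k] == pytest.approx(ref[key], rel=1e-9, abs=1e-12)
                    p += 1
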