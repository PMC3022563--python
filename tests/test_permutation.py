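import math

import numpy as np
import pytest

from episcan import core_data
from episcan.permutation import (
    NullMaxima,
    PermutationPlan,
    _exceed_rank,
    fdr_threshold,
    fwer_adjusted_pvalues,
    make_plan,
    permutation_maxima,
    permute_phenotype,
    scan_with_error_control,
)
from episcan.core_data import ScanResult, ScanRow
from episcan.stats import brute_force_scan
from episcan.synth import null_binary_dataset, null_quantitative_dataset


def identity_plan(n, K=1):
    return PermutationPlan(n=n, K=K, seed=0,
                           permutations=np.tile(np.arange(n), (K, 1)))


class TestPlan:
    def test_same_seed_bit_identical(self):
        p1 = make_plan(30, 10, 7)
        p2 = make_plan(30, 10, 7)
        assert np.array_equal(p1.permutations, p2.permutations)

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError, match="invalid permutation"):
            PermutationPlan(n=3, K=1, seed=0, permutations=np.array([[0, 0, 2]]))

    def test_permute_identity_and_multiset(self):
        _, y = null_quantitative_dataset(1, m=4, n=20)
        same = permute_phenotype(y, np.arange(20))
        assert np.array_equal(same.values, y.values)
        rng = np.random.default_rng(0)
        shuf = permute_phenotype(y, rng.permutation(20))
        assert np.array_equal(np.sort(shuf.values), np.sort(y.values))
        assert shuf.kind == y.kind


class TestMaxima:
    def test_identity_permutation_reproduces_observed_max(self):
        G, y = null_binary_dataset(5, m=8, n=30)
        plan = identity_plan(30)
        maxima = permutation_maxima(G, y, plan, "team", "chi2")
        observed = brute_force_scan(G, y, "chi2").rows[0].statistic
        assert maxima.values[0] == pytest.approx(observed, rel=1e-9)

    @pytest.mark.parametrize("engine", ["fastanova", "coe"])
    def test_pruning_protocol_vs_brute_force(self, engine):
        if engine == "fastanova":
            G, y = null_quantitative_dataset(6, m=10, n=30)
            test = "anova"
        else:
            G, y = null_binary_dataset(6, m=10, n=30)
            test = "chi2"
        plan = make_plan(30, 40, 3)
        alpha = 0.2
        maxima = permutation_maxima(G, y, plan, engine, test, alpha=alpha)
        for k in range(40):
            yk = permute_phenotype(y, plan.permutations[k])
            true_max = brute_force_scan(G, yk, test).rows[0].statistic
            if maxima.exact[k]:
                assert maxima.values[k] == pytest.approx(true_max, rel=1e-9)
            else:
                # certified-below entries are genuinely below their threshold
                assert true_max < maxima.threshold[k]

    def test_incompatible_engine_rejected(self):
        G, y = null_binary_dataset(7, m=6, n=20)
        plan = identity_plan(20)
        with pytest.raises(ValueError, match="quantitative"):
            permutation_maxima(G, y, plan, "fastanova", "anova")


class TestAdjustedP:
    def exact_maxima(self, vals):
        vals = np.asarray(vals, float)
        return NullMaxima(vals, np.ones(vals.size, bool),
                          np.full(vals.size, -np.inf))

    def observed(self, stats):
        rows = [ScanRow(f"a{i}", f"b{i}", s, 4) for i, s in enumerate(stats)]
        return ScanResult(rows=rows)

    def test_count_forced_example(self):
        # K=4, maxima {5,4,3,2}, s=3.5 -> (1+2)/5
        adj = fwer_adjusted_pvalues(self.observed([3.5]),
                                    self.exact_maxima([5, 4, 3, 2]))
        assert adj.rows[0].significance == pytest.approx(0.6)
        assert adj.rows[0].significance_kind == "fwer_adjusted_p"

    def test_extremes(self):
        adj = fwer_adjusted_pvalues(self.observed([10.0, 0.5]),
                                    self.exact_maxima([5, 4, 3, 2]))
        by_stat = {r.statistic: r.significance for r in adj.rows}
        assert by_stat[10.0] == pytest.approx(1 / 5)
        assert by_stat[0.5] == pytest.approx(1.0)

    def test_monotone_in_statistic(self):
        adj = fwer_adjusted_pvalues(
            self.observed([1.0, 2.0, 3.0, 4.0]),
            self.exact_maxima([2.5, 1.5, 3.5, 0.5]),
        )
        stats = [r.statistic for r in adj.rows]
        ps = [r.significance for r in adj.rows]
        order = np.argsort(stats)
        assert all(
            ps[order[a]] >= ps[order[a + 1]] for a in range(len(order) - 1)
        )

    def test_below_certification_threshold_errors(self):
        maxima = NullMaxima(
            np.array([5.0, 3.0]), np.array([True, False]), np.array([-np.inf, 3.0])
        )
        with pytest.raises(ValueError, match="certification threshold"):
            fwer_adjusted_pvalues(self.observed([2.0]), maxima)


class TestFdr:
    def test_null_below_everything(self):
        obs = np.array([3.0, 4.0, 5.0])
        null = np.full((3, 10), 1.0)
        t_star, qvals = fdr_threshold(obs, null, 0.1)
        assert t_star == 3.0
        assert np.allclose(qvals, 0.0)

    def test_pure_null_fdr_near_one(self):
        rng = np.random.default_rng(0)
        obs = rng.chisquare(3, size=50)
        null = np.column_stack([obs.copy() for _ in range(8)])
        _, qvals = fdr_threshold(obs, null, 0.05)
        assert qvals[np.argmin(obs)] == pytest.approx(1.0)

    def test_double_loop_oracle(self, rng):
        obs = rng.chisquare(3, size=30)
        null = rng.chisquare(3, size=(30, 7))
        t_star, qvals = fdr_threshold(obs, null, 0.3)
        # literal recount of the estimator and step-up minimum
        grid = np.unique(obs)
        fdr_grid = []
        for t in grid:
            null_mean = np.mean([(null[:, k] >= t).sum() for k in range(7)])
            fdr_grid.append(min(1.0, null_mean / max(1, (obs >= t).sum())))
        for i, s in enumerate(obs):
            expect = min(f for t, f in zip(grid, fdr_grid) if t <= s)
            assert qvals[i] == pytest.approx(expect, rel=1e-12)

    def test_qvalues_monotone(self, rng):
        obs = rng.chisquare(3, size=40)
        null = rng.chisquare(3, size=(40, 5))
        _, qvals = fdr_threshold(obs, null, 0.2)
        order = np.argsort(obs)
        assert all(np.diff(qvals[order]) <= 1e-12)

    def test_q_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_threshold(np.array([1.0]), np.ones((1, 2)), 1.5)


class TestPipeline:
    def test_exceed_rank(self):
        assert _exceed_rank(0.05, 199) == 10
        assert _exceed_rank(0.05, 200) == 11  # ceil(0.05 * 201)

    @pytest.mark.parametrize(
        "engine, test, maker",
        [
            ("fastanova", "anova", null_quantitative_dataset),
            ("coe", "chi2", null_binary_dataset),
            ("team", "gtest", null_binary_dataset),
        ],
    )
    def test_engine_matches_brute_pipeline(self, engine, test, maker):
        G, y = maker(9, m=10, n=35)
        kwargs = dict(K=60, seed=11, alpha=0.1)
        res = scan_with_error_control(G, y, engine, test, **kwargs)
        ref = scan_with_error_control(G, y, "brute", test, **kwargs)
        assert [(r.snp_a, r.snp_b, r.statistic, r.significance) for r in res.rows] == [
            (r.snp_a, r.snp_b, r.statistic, r.significance) for r in ref.rows
        ]

    def test_significant_set_with_planted_effect(self):
        from episcan.synth import binary_scenario, generate_dataset

        cfg = binary_scenario(seed=5)
        G, y = generate_dataset(cfg)
        res = scan_with_error_control(G, y, "team", "gtest", K=100, seed=2,
                                      alpha=0.05)
        pairs = res.pair_set()
        assert (G.snp_ids[cfg.planted.i], G.snp_ids[cfg.planted.j]) in pairs
        for r in res.rows:
            assert r.significance <= 0.05

    def test_fdr_path_returns_qvalues(self):
        from episcan.synth import binary_scenario, generate_dataset

        cfg = binary_scenario(seed=6)
        G, y = generate_dataset(cfg)
        res = scan_with_error_control(G, y, "team", "chi2", K=50, seed=3, fdr=0.1)
        assert len(res) >= 1
        assert all(r.significance_kind == "fdr_q" for r in res.rows)

    def test_fdr_requires_team(self):
        G, y = null_binary_dataset(10, m=6, n=20)
        with pytest.raises(ValueError, match="only with TEAM"):
            scan_with_error_control(G, y, "coe", "chi2", K=10, seed=1, fdr=0.1)

    def test_exactly_one_level(self):
        G, y = null_binary_dataset(10, m=6, n=20)
        with pytest.raises(ValueError, match="exactly one"):
            scan_with_error_control(G, y, "team", "chi2", K=10, seed=1)

    def test_determinism_byte_identical_files(self, tmp_path):
        G, y = null_binary_dataset(12, m=8, n=30)
        files = []
        for tag in ("a", "b"):
            res = scan_with_error_control(G, y, "team", "chi2", K=50, seed=9,
                                          alpha=0.2)
            p = tmp_path / f"{tag}.tsv"
            core_data.write_results(res, p)
            files.append(p.read_bytes())
        assert files[0] == files[1]
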