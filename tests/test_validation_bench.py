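import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from slidr import (
    MutationMatrix,
    SimConfig,
    ViabilityScreen,
    baseline_tests,
    bh_qvalues,
    drug_response_test,
    permutation_control,
    recovery_stats,
    roc_pr_curves,
    simulate_mutation_matrix,
    simulate_screen,
)
from slidr.validation_bench import (
    benchmark_methods,
    exhaustive_permutation_p,
    validate_drug_response,
)


class TestDrugResponse:
    def test_identical_groups_give_half(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        m = np.array([1, 1, 1, 0, 0, 0])
        p, _ = drug_response_test(v, m)
        assert p == pytest.approx(0.5)

    def test_strong_separation_is_significant(self):
        v = np.concatenate([np.full(5, -10.0) + np.arange(5) * 0.01,
                            np.full(5, 10.0) + np.arange(5) * 0.01])
        m = np.array([1] * 5 + [0] * 5)
        p, _ = drug_response_test(v, m)
        assert p < 1e-3

    def test_matches_welch_t_oracle_on_fixed_vectors(self):
        mut = np.array([1.0, 2.0, 0.5, 1.5])
        wt = np.array([2.5, 3.0, 2.0, 3.5])
        p, _ = drug_response_test(
            np.concatenate([mut, wt]), np.array([1, 1, 1, 1, 0, 0, 0, 0])
        )
        # hand-computed Welch statistic mapped through the t tail
        va, vb = mut.var(ddof=1), wt.var(ddof=1)
        t = (mut.mean() - wt.mean()) / np.sqrt(va / 4 + vb / 4)
        df = (va / 4 + vb / 4) ** 2 / ((va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        assert p == pytest.approx(stats.t.cdf(t, df), rel=1e-9)

    def test_small_group_gives_reason_code(self):
        p, reason = drug_response_test(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 0]))
        assert p is None and "fewer than 2" in reason

    def test_validate_pairs_attaches_bh_qvalues_and_skips_self_pairs(self, rng):
        cells = [f"c{i}" for i in range(10)]
        drug_screen = pd.DataFrame(
            rng.normal(size=(2, 10)), index=["drugA", "drugB"], columns=cells
        )
        drug_targets = pd.DataFrame(
            {"drug": ["drugA", "drugB"], "target": ["g1", "g2"]}
        )
        muts = MutationMatrix(
            values=pd.DataFrame(
                [[1] * 4 + [0] * 6, [0] * 5 + [1] * 5], index=["d1", "g2"], columns=cells
            )
        )
        res = validate_drug_response(
            [("d1", "g1"), ("g2", "g2")], drug_screen, drug_targets, muts
        )
        assert [r.target for r in res] == ["g1"]  # oncogene-addiction pair dropped
        assert res[0].q is not None and res[0].q >= res[0].p


class TestBhQvalues:
    def test_single_p_unchanged(self):
        assert bh_qvalues(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_equal_ps_stay_equal(self):
        q = bh_qvalues(np.full(7, 0.04))
        assert np.allclose(q, 0.04)

    def test_matches_step_up_oracle(self, rng):
        p = rng.random(200)
        q = bh_qvalues(p)
        n = len(p)
        order = np.argsort(p)
        expected = np.empty(n)
        running = 1.0
        for rank_pos in range(n - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, p[i] * n / (rank_pos + 1))
            expected[i] = running
        assert np.allclose(q, expected)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p_and_order_preserved(self, ps):
        p = np.array(ps)
        q = bh_qvalues(p)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        # q ranks never invert p ranks
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestPermutationControl:
    def test_zero_observed_count_gives_one(self):
        uni = [(f"d{i}", f"g{i}") for i in range(6)]
        p, _ = permutation_control(uni, 3, lambda pair: False, observed_count=0, B=50, seed=0)
        assert p == 1.0

    def test_unattainable_count_gives_zero(self):
        uni = [(f"d{i}", f"g{i}") for i in range(6)]
        p, _ = permutation_control(uni, 3, lambda pair: False, observed_count=1, B=50, seed=0)
        assert p == 0.0

    def test_k_larger_than_universe_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            permutation_control([("a", "b")], 2, lambda p: True, 0)

    def test_matches_exhaustive_enumeration(self):
        flags = [True, True, False, False, False, True, False]
        uni = [(f"d{i}", f"g{i}") for i in range(len(flags))]
        tester = dict(zip(uni, flags)).__getitem__
        K, obs = 3, 2
        exact = exhaustive_permutation_p(flags, K, obs)
        p, counts = permutation_control(uni, K, tester, obs, B=4000, seed=1)
        se = np.sqrt(exact * (1 - exact) / 4000)
        assert abs(p - exact) < 4 * se + 1e-9

    def test_plus_one_convention(self):
        uni = [(f"d{i}", f"g{i}") for i in range(4)]
        p, _ = permutation_control(
            uni, 2, lambda pair: False, observed_count=1, B=10, seed=0, plus_one=True
        )
        assert p == pytest.approx(1 / 11)


class TestRecoveryStats:
    def test_perfect_prediction_sensitivity_one(self):
        uni = {(f"d{i}", f"g{j}") for i in range(5) for j in range(5)}
        est = set(sorted(uni)[:6])
        r = recovery_stats(est, est, uni)
        assert r.sensitivity == 1.0 and r.n_overlap == 6

    def test_disjoint_sets_p_near_one(self):
        uni = {(f"d{i}", f"g{j}") for i in range(10) for j in range(10)}
        items = sorted(uni)
        r = recovery_stats(set(items[:5]), set(items[50:55]), uni)
        assert r.hypergeom_p > 0.7
        assert r.n_overlap == 0

    def test_matches_exhaustive_enumeration(self):
        from itertools import combinations

        uni = sorted({(f"d{i}", f"g{j}") for i in range(4) for j in range(5)})
        established = set(uni[:5])
        predicted = set(uni[2:6])  # overlap 3
        r = recovery_stats(predicted, established, set(uni))
        hits = total = 0
        for draw in combinations(range(20), 4):
            total += 1
            if sum(uni[i] in established for i in draw) >= r.n_overlap:
                hits += 1
        assert r.hypergeom_p == pytest.approx(hits / total, rel=1e-9)

    def test_accuracy_equals_confusion_recomputation(self):
        uni = {(f"d{i}", f"g{j}") for i in range(6) for j in range(6)}
        items = sorted(uni)
        predicted, established = set(items[:8]), set(items[4:10])
        r = recovery_stats(predicted, established, uni)
        tp = len(predicted & established)
        tn = len(uni - predicted - established)
        assert r.accuracy == pytest.approx((tp + tn) / len(uni))
        fp = len(predicted - established)
        assert r.specificity == pytest.approx(tn / (tn + fp))

    def test_empty_established_errors(self):
        with pytest.raises(ValueError, match="empty"):
            recovery_stats(set(), set(), {("a", "b")})


class TestBaselines:
    def _screen_muts(self, rng, n_genes=30, n_cells=12, n_drivers=3):
        screen = ViabilityScreen(
            values=pd.DataFrame(
                rng.normal(-0.2, 1.0, size=(n_genes, n_cells)),
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"c{j}" for j in range(n_cells)],
            )
        )
        m = np.zeros((n_drivers, n_cells), dtype=int)
        for i in range(n_drivers):
            m[i, rng.choice(n_cells, size=5, replace=False)] = 1
        muts = MutationMatrix(
            values=pd.DataFrame(
                m, index=[f"d{i}" for i in range(n_drivers)], columns=screen.cell_ids
            )
        )
        return screen, muts

    def test_wilcoxon_matches_scipy_exact(self, rng):
        screen, muts = self._screen_muts(rng)
        mine = baseline_tests(screen, muts, "wilcoxon")
        for driver in muts.driver_ids:
            cells = muts.mutated_cells(driver)
            for gene in screen.gene_ids[:10]:
                x = screen.values.loc[gene, cells].to_numpy()
                ref = stats.wilcoxon(x, alternative="less", method="exact").pvalue
                assert mine.loc[gene, driver] == pytest.approx(ref, rel=1e-12)

    def test_wilcoxon_normal_branch_matches_scipy_with_ties(self):
        # ties force the normal approximation; compare against scipy's
        x = np.array([[-1.0, -1.0, 2.0, -3.0, 0.5, -0.5, -2.0, 1.5]])
        from slidr.validation_bench import _wilcoxon_less_zero

        mine = _wilcoxon_less_zero(x)[0]
        ref = stats.wilcoxon(
            x[0], alternative="less", method="approx", correction=True
        ).pvalue
        assert mine == pytest.approx(ref, rel=1e-9)

    def test_ttest_matches_scipy(self, rng):
        screen, muts = self._screen_muts(rng)
        mine = baseline_tests(screen, muts, "ttest")
        driver = muts.driver_ids[0]
        cells = muts.mutated_cells(driver)
        x = screen.values.loc[:, cells].to_numpy()
        ref = stats.ttest_1samp(x, 0.0, axis=1, alternative="less").pvalue
        assert np.allclose(mine[driver].to_numpy(), ref)

    def test_symmetric_values_give_half(self):
        cells = [f"c{i}" for i in range(9)]
        vals = np.array([[-4.0, -3, -2, -1, 0, 1, 2, 3, 4]])
        screen = ViabilityScreen(values=pd.DataFrame(vals, index=["g"], columns=cells))
        muts = MutationMatrix(
            values=pd.DataFrame([[1] * 9], index=["d"], columns=cells)
        )
        w = baseline_tests(screen, muts, "wilcoxon").loc["g", "d"]
        t = baseline_tests(screen, muts, "ttest").loc["g", "d"]
        assert w == pytest.approx(0.5, abs=0.06)
        assert t == pytest.approx(0.5, abs=1e-9)

    def test_extreme_negative_values_reach_test_minimum(self):
        cells = [f"c{i}" for i in range(8)]
        vals = -np.abs(np.random.default_rng(0).normal(10, 1, size=(1, 8)))
        screen = ViabilityScreen(values=pd.DataFrame(vals, index=["g"], columns=cells))
        muts = MutationMatrix(values=pd.DataFrame([[1] * 8], index=["d"], columns=cells))
        w = baseline_tests(screen, muts, "wilcoxon").loc["g", "d"]
        assert w == pytest.approx(2.0**-8, abs=1e-12)  # all-negative signed-rank minimum

    def test_two_sample_variants_match_scipy(self, rng):
        screen, muts = self._screen_muts(rng)
        driver = muts.driver_ids[0]
        cells = muts.mutated_cells(driver)
        wt = [c for c in screen.cell_ids if c not in set(cells)]
        x = screen.values.loc[:, cells].to_numpy()
        y = screen.values.loc[:, wt].to_numpy()
        mw = baseline_tests(screen, muts, "wilcoxon_two_sample")[driver].to_numpy()
        ref = stats.mannwhitneyu(x, y, axis=1, alternative="less").pvalue
        assert np.allclose(mw, ref)


class TestRocPr:
    def test_perfect_separation_auroc_one(self):
        scores = np.array([0.01, 0.02, 0.5, 0.9])
        truth = np.array([1, 1, 0, 0])
        c = roc_pr_curves(scores, truth)
        assert c.auroc == 1.0 and c.aupr == 1.0
        assert (c.fpr[0], c.tpr[0]) == (0.0, 0.0)
        assert (c.fpr[-1], c.tpr[-1]) == (1.0, 1.0)

    def test_random_scores_auroc_near_half(self, rng):
        scores = rng.random(4000)
        truth = (rng.random(4000) < 0.3).astype(int)
        c = roc_pr_curves(scores, truth)
        assert c.auroc == pytest.approx(0.5, abs=0.05)

    def test_auroc_equals_mann_whitney_u_normalization(self, rng):
        scores = rng.random(10)
        truth = np.array([1, 0, 1, 1, 0, 0, 0, 1, 0, 0])
        c = roc_pr_curves(scores, truth)
        pos = -scores[truth == 1]
        neg = -scores[truth == 0]
        u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert c.auroc == pytest.approx(u / (len(pos) * len(neg)))

    def test_degenerate_labels_error(self):
        with pytest.raises(ValueError, match="label"):
            roc_pr_curves(np.array([0.1, 0.2]), np.array([1, 1]))


class TestBenchmarkOrdering:
    def test_rank_scan_beats_baselines_on_planted_screens(self):
        """Mean AUROC and PR-AUC ordering over a few simulated screens."""
        aurocs = {"slidr": [], "wilcoxon": [], "ttest": []}
        auprs = {"slidr": [], "wilcoxon": [], "ttest": []}
        for seed in range(8):
            muts = simulate_mutation_matrix(8, 13, prevalence=0.3, seed=seed)
            screen, truth = simulate_screen(muts, 300, SimConfig(n_true=30, seed=seed))
            curves = benchmark_methods(screen, muts, truth.labels(screen.gene_ids))
            for k, c in curves.items():
                aurocs[k].append(c.auroc)
                auprs[k].append(c.aupr)
        for baseline in ("wilcoxon", "ttest"):
            assert np.mean(aurocs["slidr"]) > np.mean(aurocs[baseline])
            assert np.mean(auprs["slidr"]) > np.mean(auprs[baseline])
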