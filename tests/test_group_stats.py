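from itertools import combinations

import numpy as np
import pytest

import micronet as mn


def exact_ranksum_p(x, y):
    """Brute-force two-sided rank-sum p: enumerate all assignments of the
    pooled ranks to the first sample (tie-free data only)."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    rx = ranks[: len(x)].sum()
    n = len(pooled)
    sums = [sum(c) for c in combinations(range(1, n + 1), len(x))]
    mean = len(x) * (n + 1) / 2
    dev = abs(rx - mean)
    return sum(abs(s - mean) >= dev - 1e-9 for s in sums) / len(sums)


class TestWilcoxon:
    def test_identical_multisets_p_one(self):
        res = mn.wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        res = mn.wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert res.details["method"] == "exact"
        assert res.p_value == pytest.approx(0.1)  # 2/20 most extreme assignments

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(0)
        for n1 in range(2, 6):
            for n2 in range(2, 6):
                if n1 + n2 > 10:
                    continue
                x = rng.standard_normal(n1)
                y = rng.standard_normal(n2)
                res = mn.wilcoxon_rank_sum(x, y)
                assert res.p_value == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(mn.ValidationError):
            mn.wilcoxon_rank_sum([1, 2, 3], [1, 2], paired=True)

    def test_paired_signed_rank_known_case(self):
        # all differences positive, n=6 tie-free: most extreme table, p = 2/2^6
        x = np.array([10.0, 12, 14, 16, 18, 20])
        y = x - np.array([1.0, 2, 3, 4, 5, 6])
        res = mn.wilcoxon_rank_sum(x, y, paired=True)
        assert res.details["method"] == "exact"
        assert res.p_value == pytest.approx(2 / 64)


class TestAnova:
    def test_equal_means_zero_F(self):
        res = mn.oneway_anova([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        res = mn.oneway_anova([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(13.5)
        assert res.details["df"] == (1, 4)

    def test_matches_scipy_recomputation(self):
        from scipy.stats import f_oneway

        rng = np.random.default_rng(1)
        groups = [rng.standard_normal(7), rng.standard_normal(5) + 1, rng.standard_normal(6)]
        res = mn.oneway_anova(groups)
        f, p = f_oneway(*groups)
        assert res.statistic == pytest.approx(f)
        assert res.p_value == pytest.approx(p)

    def test_degenerate_constant_data_missing(self):
        res = mn.oneway_anova([[2.0, 2.0], [2.0, 2.0]])
        assert np.isnan(res.statistic) and np.isnan(res.p_value)


class TestKruskal:
    def test_identical_groups_zero_H(self):
        res = mn.kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_direct_formula(self):
        # tie-free: H = 12/(N(N+1)) * sum n_g rbar_g^2 - 3(N+1)
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        rbar = [1.5, 3.5, 5.5]
        H = 12 / (6 * 7) * sum(2 * r**2 for r in rbar) - 3 * 7
        res = mn.kruskal_wallis(groups)
        assert res.statistic == pytest.approx(H)

    def test_two_groups_squares_ranksum_z(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        H = mn.kruskal_wallis([x, y]).statistic
        w = mn.wilcoxon_rank_sum(x, y).statistic
        n1, n2, N = 10, 10, 20
        z = (w - n1 * (N + 1) / 2) / np.sqrt(n1 * n2 * (N + 1) / 12)
        assert H == pytest.approx(z**2, abs=1e-6)


def make_distance(rng, n):
    return mn.bray_curtis(rng.random((n, 8)))


class TestPermanova:
    def test_perfect_separation(self):
        # groups of 8: the chance a random permutation recreates the exact
        # partition (tying the infinite observed F) is ~1.6e-4 per draw
        d = np.ones((16, 16))
        d[:8, :8] = 0
        d[8:, 8:] = 0
        np.fill_diagonal(d, 0)
        dm = mn.DistanceMatrix([f"s{i}" for i in range(16)], d)
        res = mn.permanova(dm, ["a"] * 8 + ["b"] * 8, n_permutations=99, seed=0)
        assert res.R2 == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        dm = make_distance(rng, 10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(10)
        dm_p = mn.DistanceMatrix(
            [dm.sample_ids[i] for i in perm], dm.d[np.ix_(perm, perm)]
        )
        r1 = mn.permanova(dm, labels, 49, seed=1)
        r2 = mn.permanova(dm_p, labels[perm], 49, seed=1)
        assert r1.R2 == pytest.approx(r2.R2, abs=1e-12)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F, abs=1e-12)

    def test_scale_invariance_of_R2(self):
        rng = np.random.default_rng(6)
        dm = make_distance(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = mn.permanova(dm, labels, 49, seed=2)
        dm2 = mn.DistanceMatrix(dm.sample_ids, dm.d * 3.7)
        r2 = mn.permanova(dm2, labels, 49, seed=2)
        assert r1.R2 == pytest.approx(r2.R2, abs=1e-12)
        assert r1.p_value == r2.p_value

    def test_matches_reference_implementation(self):
        """Cross-check R2 and pseudo-F against scikit-bio's PERMANOVA."""
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        dm = make_distance(rng, 12)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        ours = mn.permanova(dm, labels, 99, seed=3)
        ref = skbio_dist.permanova(
            skbio_dist.DistanceMatrix(dm.d, dm.sample_ids), labels, permutations=99
        )
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-9)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(8)
        dm = make_distance(rng, 5)
        with pytest.raises(mn.ValidationError):
            mn.permanova(dm, ["a", "a", "b", "b", "c"], 9, seed=0)

    def test_determinism(self):
        rng = np.random.default_rng(9)
        dm = make_distance(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = mn.permanova(dm, labels, 199, seed=11)
        r2 = mn.permanova(dm, labels, 199, seed=11)
        assert r1.p_value == r2.p_value


class TestPairwisePermanova:
    def test_pair_count_and_consistency(self):
        rng = np.random.default_rng(10)
        dm = make_distance(rng, 12)
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        results = mn.pairwise_permanova(dm, labels, 49, seed=4)
        assert len(results) == 3
        pair = results[0]
        keep = np.isin(labels, pair.details["pair"])
        ids = [s for s, k in zip(dm.sample_ids, keep) if k]
        standalone = mn.permanova(
            dm.subset(ids), labels[keep], 49,
            mn.stable_seed(4, *pair.details["pair"]),
        )
        assert pair.R2 == pytest.approx(standalone.R2, abs=1e-12)

    def test_bh_adjustment_values(self):
        assert mn.bh_adjust([0.01, 0.02, 0.9]) == pytest.approx([0.03, 0.03, 0.9])


class TestAnosim:
    def test_perfect_separation_R_one(self):
        d = np.ones((6, 6)) * 0.9
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0)
        dm = mn.DistanceMatrix([f"s{i}" for i in range(6)], d)
        res = mn.anosim(dm, ["a"] * 3 + ["b"] * 3, 99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        dm = make_distance(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = mn.anosim(dm, labels, 49, seed=5)
        dm2 = mn.DistanceMatrix(dm.sample_ids, np.sqrt(dm.d))
        r2 = mn.anosim(dm2, labels, 49, seed=5)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_null_mean_R_near_zero(self):
        """Mean ANOSIM R over 200 random labelings of iid data is ~0."""
        rng = np.random.default_rng(13)
        rs = []
        for s in range(200):
            dm = make_distance(rng, 10)
            res = mn.anosim(dm, ["a"] * 5 + ["b"] * 5, 1, seed=s)
            rs.append(res.statistic)
        assert abs(np.mean(rs)) < 0.05

    def test_matches_reference_implementation(self):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(14)
        dm = make_distance(rng, 12)
        labels = ["a"] * 6 + ["b"] * 6
        ours = mn.anosim(dm, labels, 99, seed=6)
        ref = skbio_dist.anosim(
            skbio_dist.DistanceMatrix(dm.d, dm.sample_ids), labels, permutations=99
        )
        assert ours.statistic == pytest.approx(ref["test statistic"], abs=1e-9)


class TestLefse:
    def _norm(self, values, taxa=None):
        values = np.asarray(values, dtype=float)
        return mn.NormalizedMatrix(
            values=values,
            scaling_factors=np.ones(values.shape[1]),
            css_quantile=0.5,
            css_scale=1000.0,
            taxon_ids=taxa or [f"t{i}" for i in range(values.shape[0])],
            sample_ids=[f"s{j}" for j in range(values.shape[1])],
        )

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(20)
        base = rng.uniform(1, 3, (8, 20))
        base[0, 10:] *= 100  # 100-fold mean shift in class b
        res = mn.lefse_markers(
            self._norm(base), ["a"] * 10 + ["b"] * 10, alpha=0.05,
            lda_threshold=2.0, seed=1,
        )
        assert any(r.taxon == "t0" and r.enriched_class == "b" for r in res)

    def test_alpha_zero_empty(self):
        rng = np.random.default_rng(21)
        res = mn.lefse_markers(
            self._norm(rng.uniform(1, 3, (5, 12))), ["a"] * 6 + ["b"] * 6,
            alpha=0.0, lda_threshold=2.0, seed=2,
        )
        assert res == []

    def test_single_class_rejected(self):
        rng = np.random.default_rng(22)
        with pytest.raises(mn.ValidationError):
            mn.lefse_markers(
                self._norm(rng.uniform(1, 3, (5, 6))), ["a"] * 6, seed=3
            )

    def test_null_false_discoveries_match_screen_level(self):
        """With identically distributed classes, markers arise only from the
        Kruskal-Wallis screen's alpha level: across 100 seeded simulations of
        3 taxa, the empty-list rate stays near its binomial oracle (1-alpha)^3
        and the mean false-marker count stays well below one."""
        empty, n_markers = 0, 0
        for s in range(100):
            rng = np.random.default_rng(s)
            vals = rng.uniform(1, 5, (3, 12))
            res = mn.lefse_markers(
                self._norm(vals), ["a"] * 6 + ["b"] * 6, alpha=0.05,
                lda_threshold=2.0, seed=s,
            )
            empty += (len(res) == 0)
            n_markers += len(res)
        assert empty >= 75  # oracle (1-0.05)^3 ~= 0.857, minus binomial noise
        assert n_markers / 100 < 0.3
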