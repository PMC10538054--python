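"""Nonparametric tests against enumeration oracles, clustering, PCA."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import maldilip as m
from maldilip.stats import (
    DifferentialConfig,
    _kw_statistic,
    differential_features,
    fold_change,
    kruskal_wallis,
    ks_normality,
    pca_scores,
    spearman_hclust,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# independent enumeration oracles (kept deliberately naive)
# ---------------------------------------------------------------------------

def _wilcoxon_oracle(a, b):
    """Two-sided exact p by enumerating all group assignments of the pooled data."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = sps.rankdata(pooled)

    def u_stat(idx):
        ra = ranks[list(idx)].sum()
        return ra - na * (na + 1) / 2

    u_obs = u_stat(range(na))
    mu = na * (len(b)) / 2
    count = total = 0
    for idx in combinations(range(n), na):
        u = u_stat(idx)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
        total += 1
    return count / total


def _kw_oracle(groups):
    """P(H >= H_obs) over all assignments of the pooled data to the group sizes."""
    gs = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(gs)
    sizes = [len(g) for g in gs]
    h_obs = _kw_statistic(gs)
    count = total = 0

    def rec(remaining, gi, chosen):
        nonlocal count, total
        if gi == len(sizes) - 1:
            parts = chosen + [pooled[sorted(remaining)]]
            total += 1
            if _kw_statistic(parts) >= h_obs - 1e-9:
                count += 1
            return
        for comb in combinations(sorted(remaining), sizes[gi]):
            rec(remaining - set(comb), gi + 1, chosen + [pooled[list(comb)]])

    rec(frozenset(range(len(pooled))), 0, [])
    return count / total


class TestWilcoxon:
    def test_exact_small_case(self):
        # all C(4,2)=6 assignments; {1,2} vs {3,4} is one of two extremes
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(2 / 6, abs=1e-9)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("na, nb", [(2, 2), (2, 3), (3, 3), (2, 4), (3, 4), (4, 4), (2, 6)])
    def test_exact_matches_enumeration(self, na, nb, rng):
        for _ in range(3):
            a = rng.normal(size=na)
            b = rng.normal(0.5, size=nb)
            _, p = wilcoxon_rank_sum(a, b)
            assert p == pytest.approx(_wilcoxon_oracle(a, b), abs=1e-9)

    def test_shift_invariance(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=7)
        _, p1 = wilcoxon_rank_sum(a, b)
        _, p2 = wilcoxon_rank_sum(a + 100.0, b + 100.0)
        assert p1 == p2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [1.0, 2.0])


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_h(self):
        # ranks 1..6, group mean ranks 1.5/3.5/5.5:
        # H = 12/(6*7) * [2*(1.5-3.5)^2 + 0 + 2*(5.5-3.5)^2] = 32/7
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7, abs=1e-9)
        assert p == pytest.approx(sps.chi2.sf(32 / 7, 2), abs=1e-6)

    def test_matches_scipy_asymptotic(self, rng):
        groups = [rng.normal(size=5), rng.normal(1, size=6), rng.normal(size=4)]
        h, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    @pytest.mark.parametrize("sizes", [(2, 2), (2, 3), (2, 2, 2), (2, 2, 3), (3, 4)])
    def test_exact_matches_enumeration(self, sizes, rng):
        groups = [rng.normal(loc=i, size=s) for i, s in enumerate(sizes)]
        _, p = kruskal_wallis(groups, method="exact")
        assert p == pytest.approx(_kw_oracle(groups), abs=1e-9)

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestKsNormality:
    def test_normal_draws_rarely_rejected(self):
        rejections = 0
        for seed in range(40):
            x = np.random.default_rng(seed).normal(3.0, 2.0, 500)
            if ks_normality(x) < 0.01:
                rejections += 1
        assert rejections <= 2  # >=95% of seeds keep p > 0.01

    def test_lognormal_draws_rejected(self):
        rejections = 0
        for seed in range(40):
            x = np.random.default_rng(seed).lognormal(0.0, 1.0, 500)
            if ks_normality(x) < 0.01:
                rejections += 1
        assert rejections >= 38

    def test_constant_and_tiny_inputs(self):
        with pytest.warns(UserWarning):
            assert ks_normality([2.0, 2.0, 2.0]) == 0.0
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0])


class TestFoldChange:
    def test_basic_ratios(self):
        assert fold_change(2.0, 2.0) == 1.0
        assert fold_change(4.0, 2.0) == 2.0
        assert fold_change(0.0, 0.0, pseudocount=0.5) == 1.0

    def test_undefined_without_pseudocount(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)

    def test_recovers_planted_ratio_at_cohort_noise(self):
        # FC 2.49 contrast, n = 24/arm, 20% technical noise: estimate lands
        # within [2.2, 2.8] in >=90% of seeds
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            sigma = np.sqrt(np.log(1 + 0.2**2))
            a = 2.49 * rng.lognormal(0, sigma, 24)
            b = rng.lognormal(0, sigma, 24)
            if 2.2 <= fold_change(a.mean(), b.mean()) <= 2.8:
                hits += 1
        assert hits >= 27


class TestDifferentialFeatures:
    @staticmethod
    def _fm(values, groups):
        values = np.asarray(values, float)
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(len(values))], "group": groups}
        )
        mz = 100.0 + np.arange(values.shape[1])
        return m.FeatureMatrix(mz, values, samples)

    def test_identical_groups_not_significant(self, rng):
        v = np.tile(rng.uniform(1, 2, (3, 1)), (2, 1))
        table = differential_features(self._fm(v, ["A"] * 3 + ["B"] * 3))
        assert not table.significant.any()

    def test_degenerate_zero_feature_flagged(self):
        v = np.zeros((4, 1))
        table = differential_features(self._fm(v, ["A", "A", "B", "B"]))
        assert table.degenerate.all() and (table.p_raw == 1.0).all()

    def test_significance_invariant_to_global_rescale(self, rng):
        v = rng.lognormal(0, 0.3, size=(12, 20))
        v[:6, :5] *= 3.0
        fm1 = self._fm(v, ["A"] * 6 + ["B"] * 6)
        fm2 = self._fm(v * 1e4, ["A"] * 6 + ["B"] * 6)
        t1 = differential_features(fm1)
        t2 = differential_features(fm2)
        assert t1.significant.tolist() == t2.significant.tolist()
        assert np.allclose(t1.p_raw, t2.p_raw)

    def test_null_type_one_error_calibrated(self):
        design = m.design_preset("null", seed=11)
        fm, _ = m.simulate_feature_matrix(design, n_features=1000, n_differential=0)
        table = differential_features(
            fm, "group", DifferentialConfig(alpha=0.05, use_fc_rule=False)
        )
        rate = (table.p_raw < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_replicates_averaged_before_testing(self, rng):
        # three technical replicates per biological sample must collapse to
        # one observation; n_bio = 2 per group is below any significance
        base = rng.lognormal(0, 0.2, size=(4, 5))
        v = np.repeat(base, 3, axis=0)
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(12)],
                "bio_sample": np.repeat([f"b{i}" for i in range(4)], 3),
                "group": np.repeat(["A", "A", "B", "B"], 3),
            }
        )
        fm = m.FeatureMatrix(100.0 + np.arange(5), v, samples)
        table = differential_features(fm)
        # U statistic range for n=2 vs 2 confirms tests ran on 2+2, not 6+6
        assert table.statistic.max() <= 4.0


class TestSpearmanHclust:
    def test_duplicated_blocks_recovered(self, rng):
        a = rng.normal(size=(1, 20)) + rng.normal(0, 0.01, size=(4, 20))
        b = rng.normal(size=(1, 20)) + rng.normal(0, 0.01, size=(4, 20))
        x = np.vstack([a, b])
        _, labels = spearman_hclust(x.T, on="features", k=2)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_monotone_transform_distance_zero(self, rng):
        base = rng.normal(size=50)
        x = np.vstack([base, np.exp(base), -base])  # monotone up, monotone down
        z, _ = spearman_hclust(x.T, on="features")
        # first merge joins the two monotonically equivalent features at height 0
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_feature_distance_two(self, rng):
        base = np.arange(10.0)
        x = np.vstack([base, base[::-1], base + 0.5]).T
        d = 1 - pd.DataFrame(x).corr("spearman").to_numpy()
        assert d[0, 1] == pytest.approx(2.0)


class TestPca:
    def test_two_clusters_separate_on_pc1(self, rng):
        x = rng.normal(0, 0.3, size=(20, 30))
        x[:10] += 4.0 * rng.random(30)
        scores, _, _ = pca_scores(x, n_components=2)
        from sklearn.metrics import silhouette_score

        labels = [0] * 10 + [1] * 10
        assert silhouette_score(scores[:, :1], labels) > 0.8

    def test_scores_orthogonal(self, rng):
        x = rng.normal(size=(15, 8))
        scores, _, _ = pca_scores(x, n_components=4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_explained_variance_sums_to_total(self, rng):
        x = rng.normal(size=(10, 6))
        _, _, ev = pca_scores(x, n_components=6)
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_truncation_warns(self, rng):
        x = rng.normal(size=(3, 10))
        with pytest.warns(UserWarning, match="rank"):
            scores, _, _ = pca_scores(x, n_components=5)
        assert scores.shape[1] <= 2
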