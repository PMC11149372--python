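"""Metric tests against brute-force oracles and the printed p-value regime."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import equigen.metrics as em


class TestAUROC:
    def test_perfect_separation(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        assert em.auroc(s, y) == 1.0
        assert em.aupr(s, y) == 1.0

    def test_null_scores_near_half(self, rng):
        s = rng.random(10_000)
        y = rng.integers(0, 2, 10_000)
        assert abs(em.auroc(s, y) - 0.5) < 0.02

    def test_matches_pairwise_concordance_oracle(self, rng):
        s = rng.random(50).round(1)  # rounding forces ties
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        pos = s[y == 1]
        neg = s[y == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert em.auroc(s, y) == pytest.approx(conc / (len(pos) * len(neg)))

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_monotone_transform(self, k):
        rng = np.random.default_rng(17)
        s = rng.random(200)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        assert em.auroc(np.exp(k * s), y) == pytest.approx(em.auroc(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            em.auroc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestTjurR2:
    def test_probabilities_equal_labels(self):
        y = np.array([0, 1, 0, 1])
        assert em.tjur_r2(y.astype(float), y) == 1.0

    def test_constant_probability_zero(self):
        y = np.array([0, 1, 0, 1])
        assert em.tjur_r2(np.full(4, 0.7), y) == 0.0

    def test_matches_two_group_mean_difference(self, rng):
        p = rng.random(300)
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        direct = p[y == 1].mean() - p[y == 0].mean()
        assert em.tjur_r2(p, y) == pytest.approx(direct)
        assert -1.0 <= em.tjur_r2(p, y) <= 1.0


class TestYouden:
    def test_perfect_separation_j_is_one(self):
        s = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([0, 0, 1, 1])
        thr, sens, spec = em.youden_threshold(s, y)
        assert sens + spec - 1 == pytest.approx(1.0)
        assert 0.2 < thr <= 0.8

    def test_null_scores_j_near_zero(self, rng):
        s = rng.random(5000)
        y = rng.integers(0, 2, 5000)
        _, sens, spec = em.youden_threshold(s, y)
        assert abs(sens + spec - 1) < 0.05

    def test_matches_exhaustive_scan_oracle(self, rng):
        s = rng.random(100).round(1)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        thr, sens, spec = em.youden_threshold(s, y)
        best = -np.inf
        best_thr = None
        for t in sorted(np.unique(s)):
            se = (s[y == 1] >= t).mean()
            sp = (s[y == 0] < t).mean()
            if se + sp - 1 > best + 1e-12:
                best = se + sp - 1
                best_thr = t
        assert thr == pytest.approx(best_thr)
        assert sens + spec - 1 == pytest.approx(best)


class TestAdjustedPredictiveValues:
    def test_perfect_test_for_any_prevalence(self):
        ppv, npv = em.adjusted_ppv_npv(1.0, 1.0, 0.103)
        assert ppv == 1.0 and npv == 1.0

    def test_confusion_table_oracle_at_stated_prevalence(self):
        # build a pseudo-population realizing sens=.8, spec=.9, prev=.103
        sens, spec, prev = 0.8, 0.9, 0.103
        n = 1_000_000
        tp = sens * prev * n
        fn = (1 - sens) * prev * n
        tn = spec * (1 - prev) * n
        fp = (1 - spec) * (1 - prev) * n
        ppv, npv = em.adjusted_ppv_npv(sens, spec, prev)
        assert ppv == pytest.approx(tp / (tp + fp))
        assert npv == pytest.approx(tn / (tn + fn))
        assert ppv == pytest.approx(0.479, abs=0.001)
        assert npv == pytest.approx(0.975, abs=0.001)

    def test_half_prevalence_identity(self):
        ppv, _ = em.adjusted_ppv_npv(0.7, 0.8, 0.5)
        assert ppv == pytest.approx(0.7 / (0.7 + 0.2))

    def test_undefined_denominator_nan(self):
        ppv, npv = em.adjusted_ppv_npv(0.0, 1.0, 0.0)
        assert np.isnan(ppv)

    def test_matches_raw_confusion_values_at_empirical_prevalence(self, rng):
        s = rng.random(400)
        y = rng.integers(0, 2, 400)
        y[:2] = [0, 1]
        thr, sens, spec = em.youden_threshold(s, y)
        raw_ppv, raw_npv = em.confusion_ppv_npv(s, y, thr)
        adj_ppv, adj_npv = em.adjusted_ppv_npv(sens, spec, y.mean())
        assert adj_ppv == pytest.approx(raw_ppv)
        assert adj_npv == pytest.approx(raw_npv)


class TestWilcoxon:
    def test_identical_groups_large_p(self):
        x = np.arange(8.0)
        assert em.rank_sum_test(x, x) >= 0.5

    def test_exact_enumeration_matches_direct_oracle_n4(self, rng):
        x = rng.random(4)
        y = rng.random(4)
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[:4].sum()
        count = sum(
            ranks[list(idx)].sum() >= obs - 1e-9
            for idx in combinations(range(8), 4)
        )
        assert em.rank_sum_test(x, y) == pytest.approx(count / 70)

    def test_exact_matches_scipy_without_ties(self, rng):
        x = rng.normal(1, 1, 8)
        y = rng.normal(0, 1, 8)
        ours = em.rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(float(ref))

    def test_complete_separation_n20_matches_printed_minimum(self):
        # 20 runs per group with full separation: the asymptotic one-sided
        # p-value bottoms out around 3.3e-8, the floor seen in such designs
        x = np.linspace(10, 11, 20)
        y = np.linspace(0, 1, 20)
        p = em.rank_sum_test(x, y)
        assert p == pytest.approx(3.4e-8, rel=0.1)

    def test_sign_test_binomial(self):
        d = np.array([1.0] * 15 + [-1.0] * 5)
        assert em.sign_test(d) == pytest.approx(
            float(stats.binomtest(15, 20, 0.5, alternative="greater").pvalue)
        )

    def test_signed_rank_one_sided(self):
        d = np.array([0.5, 0.7, 0.2, 0.9, 0.4, 0.6])
        assert em.signed_rank_test(d) < 0.05


class TestDisparityStats:
    def test_identical_runs_zero_gap(self):
        runs = np.full(5, 0.75)
        summary = em.disparity_stats({"Mix1_LR": runs, "Mix2_LR": runs})
        assert summary.G["Mix_LR"] == 0.0
        assert summary.p_values["G_Mix_LR"] >= 0.5

    def test_full_summary_shape(self, rng):
        keys = ["Mix1_LR", "Mix2_LR", "Mix1_DL", "Mix2_DL", "Ind1_LR", "Ind2_LR",
                "Ind1_DL", "Ind2_DL", "NT_LR", "NT_DL", "TL_LR", "TL_DL"]
        data = {k: 0.7 + 0.01 * rng.random(6) for k in keys}
        data["TL_DL"] = data["TL_DL"] + 0.05
        summary = em.disparity_stats(data)
        assert set(summary.G) == {"Mix_LR", "Mix_DL", "Ind_LR", "Ind_DL"}
        assert set(summary.I) == {"Mix2_LR", "Ind2_LR", "NT_LR",
                                  "Mix2_DL", "Ind2_DL", "NT_DL"}
        assert summary.D is not None and summary.D > 0
        assert summary.p_values["D"] < 0.05
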