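"""Simulator unit and property tests: frequencies, effects, liabilities, labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import equigen.synth_data as sd


class TestRhoSchedule:
    @pytest.mark.parametrize(
        "dk,r,expected",
        [
            (42.7, 0.5, 0.80),
            (46.1, 0.5, 0.77),
            (80.6, 0.5, 0.58),
            (94.1, 0.5, 0.54),
            (46.1, 1.0, 0.74),
            (80.6, 1.0, 0.42),
            (94.1, 1.0, 0.36),
        ],
    )
    def test_power_law_values(self, dk, r, expected):
        assert round(sd.rho_schedule(42.7, dk, 0.8, r), 2) == expected

    @given(
        dk=st.floats(1.0, 500.0),
        r=st.floats(0.1, 2.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_distance(self, dk, r):
        d0 = 42.7
        rho = sd.rho_schedule(d0, dk, 0.8, r)
        rho_further = sd.rho_schedule(d0, dk * 1.5, 0.8, r)
        assert rho_further < rho or dk * 1.5 == dk

    def test_rejects_nonpositive_distance(self):
        with pytest.raises(ValueError):
            sd.rho_schedule(0.0, 10.0)


class TestGeneticDistance:
    def test_identical_profiles_zero(self):
        f = np.full(10, 0.3)
        assert sd.genetic_distance(f, f) == 0.0

    def test_forced_two_snp_value(self):
        assert sd.genetic_distance(np.array([0.1, 0.5]), np.array([0.3, 0.2])) == pytest.approx(0.5)

    def test_matches_elementwise_sum_oracle(self, rng):
        a = rng.uniform(0.05, 0.95, 500)
        b = rng.uniform(0.05, 0.95, 500)
        brute = sum(abs(x - y) for x, y in zip(a, b))
        assert sd.genetic_distance(a, b) == pytest.approx(brute)
        assert sd.genetic_distance(b, a) == pytest.approx(brute)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sd.genetic_distance(np.array([0.1]), np.array([0.1, 0.2]))


class TestFrequencyProfiles:
    def test_zero_divergence_copies_eur(self):
        profiles = sd.simulate_frequency_profiles(100, {"AMR": 0.0}, seed=1)
        eur, amr = profiles
        assert np.array_equal(eur.frequencies, amr.frequencies)

    def test_seed_determinism_and_sensitivity(self):
        a = sd.simulate_frequency_profiles(50, {"AFR": 0.2}, seed=3)
        b = sd.simulate_frequency_profiles(50, {"AFR": 0.2}, seed=3)
        c = sd.simulate_frequency_profiles(50, {"AFR": 0.2}, seed=4)
        assert np.array_equal(a[1].frequencies, b[1].frequencies)
        assert not np.array_equal(a[1].frequencies, c[1].frequencies)

    def test_bounds_respected(self):
        profiles = sd.simulate_frequency_profiles(200, {"AFR": 0.5}, seed=2)
        for p in profiles:
            assert p.frequencies.min() >= sd.FREQ_MIN
            assert p.frequencies.max() <= sd.FREQ_MAX

    @pytest.mark.parametrize("pop,target", sorted(sd.GENETIC_DISTANCES.items()))
    def test_calibrated_divergence_hits_printed_distance(self, pop, target):
        c = sd.calibrate_divergence(target, m=500, seed=11)
        dists = []
        for s in range(20):
            profiles = sd.simulate_frequency_profiles(500, {pop: c}, seed=100 + s)
            dists.append(sd.genetic_distance(profiles[0], profiles[1]))
        assert abs(np.mean(dists) - target) <= 0.05 * target


class TestCalibrateDivergence:
    def test_zero_target(self):
        assert sd.calibrate_divergence(0.0, 500, seed=0) == 0.0

    def test_unattainable_target_rejected(self):
        with pytest.raises(ValueError):
            sd.calibrate_divergence(500.0, 500, seed=0)

    def test_afr_target_monte_carlo(self):
        c = sd.calibrate_divergence(94.1, 500, seed=5)
        assert 0 < c < 1
        dists = []
        for s in range(20):
            profiles = sd.simulate_frequency_profiles(500, {"AFR": c}, seed=s)
            dists.append(sd.genetic_distance(profiles[0], profiles[1]))
        assert 89.4 <= np.mean(dists) <= 98.8


class TestEffects:
    def test_bounded_support(self):
        w = sd.draw_effects(10_000, seed=0)
        assert np.all(np.abs(w) <= 1.0)

    def test_symmetric_mean(self):
        w = sd.draw_effects(100_000, seed=1)
        assert abs(w.mean()) < 0.01

    def test_seed_determinism(self):
        assert np.array_equal(sd.draw_effects(100, 5), sd.draw_effects(100, 5))

    def test_rho_one_identity(self):
        w = sd.draw_effects(100, 0)
        wp, _ = sd.correlate_effects(w, 1.0, seed=9)
        assert np.allclose(wp, w)

    def test_rho_zero_uncorrelated(self):
        w = sd.draw_effects(100_000, 0)
        wp, _ = sd.correlate_effects(w, 0.0, seed=9)
        assert abs(np.corrcoef(w, wp)[0, 1]) < 0.01

    def test_rho_recovery_at_study_scale(self):
        # m=500 as in the study; correlation recovered on average over 50 draws
        rho = 0.58
        cors = []
        for s in range(50):
            w = sd.draw_effects(500, seed=s)
            wp, _ = sd.correlate_effects(w, rho, seed=1000 + s)
            cors.append(np.corrcoef(w, wp)[0, 1])
        assert abs(np.mean(cors) - rho) < 0.02

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            sd.correlate_effects(np.ones(3), 1.5, 0)


class TestLiability:
    def test_h2_one_is_pure_genetic_score(self, rng):
        X = rng.binomial(2, 0.3, size=(500, 50)).astype(float)
        W = rng.normal(size=50)
        g = sd.compute_liability(X, W, h2=1.0, seed=0)
        score = X @ W
        score = (score - score.mean()) / score.std()
        assert np.allclose(g, score)

    @pytest.mark.parametrize("h2", [0.25, 0.5])
    def test_heritability_recovery(self, h2, rng):
        X = rng.binomial(2, rng.uniform(0.05, 0.95, 500), size=(10_000, 500)).astype(float)
        W = sd.draw_effects(500, seed=3)
        g = sd.compute_liability(X, W, h2=h2, seed=4)
        r2 = np.corrcoef(g, X @ W)[0, 1] ** 2
        assert abs(r2 - h2) <= 0.03
        assert abs(g.var() - 1.0) <= 0.05

    def test_zero_variance_rejected(self):
        X = np.zeros((100, 5))
        with pytest.raises(ValueError):
            sd.compute_liability(X, np.ones(5), 0.5, 0)


class TestAssignLabels:
    def test_balanced_split(self, rng):
        g = rng.normal(size=1000)
        y, thr = sd.assign_labels(g, (1, 1))
        assert y.sum() == 500
        assert np.all((g > thr) == (y == 1))

    def test_one_to_four_split(self, rng):
        g = rng.normal(size=1000)
        y, _ = sd.assign_labels(g, (1, 4))
        assert y.sum() == 200

    def test_ties_fall_to_control_side(self):
        g = np.array([0.0, 0.0, 0.0, 1.0])
        y, thr = sd.assign_labels(g, (1, 1))
        # threshold lands on the tied value; strict ">" puts ties in controls
        assert thr == 0.0
        assert y.tolist() == [0, 0, 0, 1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sd.assign_labels(np.array([]), (1, 1))


class TestBuildDataset:
    def test_shapes_splits_and_genotype_means(self):
        cfg = sd.DatasetConfig(name="t", ddp="AMR", h2=0.5, r=0.5,
                               m=60, n_eur=1200, n_ddp=400)
        data = sd.generate_dataset(cfg, seed=5)
        assert data.X.shape == (1600, 60)
        assert set(data.populations) == {"EUR", "AMR"}
        # split fractions within rounding per (ancestry, label) stratum
        for pop in ("EUR", "AMR"):
            n_pop = int(data.mask(pop).sum())
            n_train = int(data.mask(pop, "train").sum())
            assert abs(n_train - 0.8 * n_pop) <= 2
            assert int(data.mask(pop, "validation").sum()) + int(
                data.mask(pop, "test").sum()
            ) == n_pop - n_train
        # per-population case fraction ~ 1:1 (exact up to one individual)
        for pop in ("EUR", "AMR"):
            ypop = data.y[data.mask(pop)]
            assert abs(int(ypop.sum()) - len(ypop) // 2) <= 1

    def test_genotype_frequencies_match_binomial_oracle(self):
        m, n = 40, 4000
        profiles = sd.simulate_frequency_profiles(m, {"EAS": 0.05}, seed=8)
        rng = sd._rng(3, "geno-test")
        X = sd.draw_genotypes(profiles[0], n, rng)
        f = profiles[0].frequencies
        se = np.sqrt(2 * f * (1 - f) / n)
        assert np.all(np.abs(X.mean(axis=0) - 2 * f) <= 3 * se + 1e-9)

    def test_end_to_end_seed_determinism(self):
        cfg = sd.DatasetConfig(name="t", ddp="SAS", h2=0.25, r=1.0,
                               m=30, n_eur=300, n_ddp=120)
        d1 = sd.generate_dataset(cfg, seed=9)
        d2 = sd.generate_dataset(cfg, seed=9)
        assert np.array_equal(d1.X, d2.X)
        assert np.array_equal(d1.y, d2.y)
        assert np.array_equal(d1.split, d2.split)
        assert d1.X.tobytes() == d2.X.tobytes()


class TestClinicalCovariates:
    def test_covariates_appended_and_predictive(self):
        profiles = sd.simulate_frequency_profiles(20, {"AMR": 0.05}, seed=1)
        W = sd.draw_effects(20, 2)
        Wp, z = sd.correlate_effects(W, 0.7, 3)
        em = sd.EffectModel(W=W, W_prime=Wp, rho=0.7, h2=0.5, zeta_prime=z)
        lc = sd.LiabilityConfig(h2=0.5)
        data = sd.build_dataset(profiles, em, {"EUR": 600, "AMR": 200}, lc,
                                seed=4, clinical_effects=(1.0, 0.8))
        assert data.X.shape[1] == 22
        assert data.snp_ids[-2:] == ["cov_cont", "cov_bin"]
        # a strong continuous covariate separates cases from controls
        c = data.X[:, -2]
        assert c[data.y == 1].mean() > c[data.y == 0].mean() + 0.2


class TestCompendium:
    def test_sixteen_configs_with_table_rho_column(self):
        configs = sd.sd_compendium()
        assert len(configs) == 16
        rho = [round(c.rho, 2) for c in configs]
        assert rho[:8] == [0.80, 0.77, 0.58, 0.54] * 2
        assert rho[8:] == [0.80, 0.74, 0.42, 0.36] * 2
        # SD9/SD13 replicate SD1/SD5 apart from the name
        for a, b in ((0, 8), (4, 12)):
            ca, cb = configs[a], configs[b]
            assert (ca.ddp, ca.h2, ca.rho) == (cb.ddp, cb.h2, cb.rho)

    def test_star_compendium_ratio(self):
        star = sd.sd_compendium(case_control_ratio=(1, 4))
        assert all(c.case_control_ratio == (1, 4) for c in star)
        assert star[0].name == "SD1*"
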