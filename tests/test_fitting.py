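"""Coefficient and radius estimation, zone exclusion, CV, and error metrics."""

import numpy as np
import pytest
from scipy.optimize import least_squares

import flatsphere as fs
from flatsphere.fitting import FitConfig, _gap_residuals

from conftest import K_REF, R_REF


def iterative_k_fit(profile, R_true):
    """Independent oracle: generic iterative least squares over k on the
    same objective the closed form solves."""
    res = least_squares(
        lambda k: _gap_residuals(R_true, profile.L_mm, profile.G_mm, k[0]),
        x0=[0.0],
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    return float(res.x[0])


class TestEstimateK:
    def test_zero_on_ideal_profile(self):
        p = fs.simulate_profile(R_REF, 0.0, M_min=0.6 * np.pi * R_REF)
        assert fs.estimate_k(p, R_REF).estimate == pytest.approx(0.0, abs=1e-9)

    def test_exact_recovery_on_noiseless_profile(self, noiseless_profile):
        fit = fs.estimate_k(noiseless_profile, R_REF)
        assert fit.estimate == pytest.approx(K_REF, rel=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_matches_iterative_least_squares_on_noisy_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            R = rng.uniform(1.2, 2.0)
            k = 2 * np.pi * rng.uniform(0.05, 0.25)
            p = fs.simulate_profile(
                R, k, M_min=rng.uniform(0.5, 0.7) * np.pi * R,
                noise_sd_frac=0.02, seed=rng,
            )
            closed = fs.estimate_k(p, R).estimate
            assert closed == pytest.approx(iterative_k_fit(p, R), abs=1e-6)

    def test_negative_estimate_is_warned_not_rejected(self):
        p = fs.simulate_profile(R_REF, 0.0, M_min=0.6 * np.pi * R_REF)
        shrunk = fs.GapProfile(
            L_px=p.L_px, L_mm=p.L_mm, G_mm=p.G_mm * 0.9, M_mm=p.M_mm,
            scale_um_per_px=p.scale_um_per_px,
        )
        fit = fs.estimate_k(shrunk, R_REF)
        assert fit.estimate < 0
        assert any("negative" in w for w in fit.warnings)

    def test_radii_beyond_hemisphere_rejected(self, noiseless_profile):
        with pytest.raises(ValueError, match="beyond pi\\*R_true"):
            fs.estimate_k(noiseless_profile, R_true=0.5)


class TestEstimateR:
    def test_exact_recovery_with_true_k(self, noiseless_profile):
        fit = fs.estimate_R(noiseless_profile, K_REF)
        assert fit.converged
        assert fit.estimate == pytest.approx(R_REF, rel=1e-6)

    def test_ideal_profile_with_zero_k(self):
        p = fs.simulate_profile(2.0, 0.0, M_min=0.6 * np.pi * 2.0)
        assert fs.estimate_R(p, 0.0).estimate == pytest.approx(2.0, rel=1e-6)

    def test_large_initial_radius_does_not_collapse(self, noiseless_profile):
        # starting at R=100 working units must land on the same optimum
        single = fs.estimate_R(
            noiseless_profile, K_REF, FitConfig(R_init=100.0, multi_start=False)
        )
        multi = fs.estimate_R(noiseless_profile, K_REF)
        assert single.estimate == pytest.approx(multi.estimate, rel=1e-8)
        assert single.estimate == pytest.approx(R_REF, rel=1e-6)

    def test_lower_bound_warning_pins_corneal_angle(self):
        # gaps far larger than any sphere can explain push R to the bound
        p = fs.simulate_profile(R_REF, K_REF, M_min=0.6 * np.pi * R_REF)
        inflated = fs.GapProfile(
            L_px=p.L_px, L_mm=p.L_mm,
            G_mm=np.minimum(p.G_mm * 20, 2 * np.pi * p.L_mm * 0.999),
            M_mm=p.M_mm, scale_um_per_px=p.scale_um_per_px,
        )
        fit = fs.estimate_R(inflated, 0.0)
        assert any("corneal angle pinned" in w for w in fit.warnings)


class TestRoundTripProperty:
    def test_noiseless_recovery_over_random_parameters(self):
        # 50 random (R*, k*) draws with 0 < k*/2pi < R*/5: both stages exact
        rng = np.random.default_rng(2024)
        for _ in range(50):
            R = rng.uniform(0.8, 3.0)
            k = 2 * np.pi * rng.uniform(1e-4, R / 5)
            p = fs.simulate_profile(R, k, M_min=rng.uniform(0.45, 0.75) * np.pi * R)
            assert fs.estimate_k(p, R).estimate == pytest.approx(k, rel=1e-6)
            assert fs.estimate_R(p, k).estimate == pytest.approx(R, rel=1e-6)


class TestExcludeZone:
    def test_low_zone_removes_largest_radii(self, noiseless_profile):
        out = fs.exclude_zone(noiseless_profile, 0.1, "low")
        assert out.n_points == 450
        np.testing.assert_array_equal(out.L_mm, noiseless_profile.L_mm[:450])

    def test_high_zone_removes_smallest_radii(self, noiseless_profile):
        out = fs.exclude_zone(noiseless_profile, 0.3, "high")
        assert out.n_points == 350
        np.testing.assert_array_equal(out.L_mm, noiseless_profile.L_mm[150:])

    def test_zero_fraction_is_identity(self, noiseless_profile):
        out = fs.exclude_zone(noiseless_profile, 0.0, "low")
        np.testing.assert_array_equal(out.L_mm, noiseless_profile.L_mm)
        np.testing.assert_array_equal(out.G_mm, noiseless_profile.G_mm)

    def test_invalid_inputs(self, noiseless_profile):
        with pytest.raises(ValueError, match="fraction"):
            fs.exclude_zone(noiseless_profile, 1.0, "low")
        with pytest.raises(ValueError, match="zone"):
            fs.exclude_zone(noiseless_profile, 0.1, "middle")


class TestZoneSensitivity:
    def test_invariant_on_exact_model_data(self, noiseless_profile):
        table = fs.zone_sensitivity(noiseless_profile, R_REF)
        k_all = table.loc[table["zone"] == "all", "k_mm"].iloc[0]
        assert np.all(np.abs(table["k_mm"] - k_all) <= 1e-9 * abs(k_all))

    def test_equator_disturbance_hits_low_zone_exclusions_harder(self, noiseless_profile):
        # add an extra gap disturbance only near the equator (L > 0.8*M_min):
        # removing low-latitude (large-L) points then shifts k, removing
        # high-latitude (small-L) points barely does
        p = noiseless_profile
        G = p.G_mm.copy()
        sel = p.L_mm > 0.8 * p.M_min_mm
        G[sel] *= 1.10
        disturbed = fs.GapProfile(L_px=p.L_px, L_mm=p.L_mm,
                                  G_mm=np.minimum(G, 2 * np.pi * p.L_mm),
                                  M_mm=p.M_mm, scale_um_per_px=p.scale_um_per_px)
        table = fs.zone_sensitivity(disturbed, R_REF)
        low = table[table["zone"] == "low"]["rel_dev_pct"].abs()
        high = table[table["zone"] == "high"]["rel_dev_pct"].abs()
        assert low.min() > high.max()

    def test_empty_fractions_yield_full_data_only(self, noiseless_profile):
        table = fs.zone_sensitivity(noiseless_profile, R_REF, fractions=[])
        assert len(table) == 1
        assert table["zone"].iloc[0] == "all"


class TestCrossValidation:
    @staticmethod
    def _cohort(m, seed=11):
        return [(s.profile, s.R) for s in
                fs.simulate_cohort(m=m, seed=seed, n_points=120, noise_sd_frac=0.01)]

    def test_23_samples_split_8_8_7_and_5_5_5_4_4(self):
        samples = self._cohort(23)
        r3 = fs.cv_learn_k(samples, scheme="3fold", repeats=1, seed=0)
        sizes3 = sorted(23 - r3.fold_k["n_train"])
        assert sizes3 == [7, 8, 8]
        r5 = fs.cv_learn_k(samples, scheme="5fold", repeats=1, seed=0)
        sizes5 = sorted(23 - r5.fold_k["n_train"])
        assert sizes5 == [4, 4, 5, 5, 5]

    def test_loo_is_deterministic_with_m_splits(self):
        samples = self._cohort(6)
        res = fs.cv_learn_k(samples, scheme="loo")
        assert len(res.fold_k) == 6
        assert (res.fold_k["n_train"] == 5).all()
        assert res.repeats == 1
        assert any("deterministic" in n for n in res.notes)
        assert (res.table["R_hat_sd_mm"] == 0).all()

    def test_fold_assignment_reproducible_from_seed(self):
        samples = self._cohort(9)
        a = fs.cv_learn_k(samples, scheme="3fold", repeats=3, seed=5)
        b = fs.cv_learn_k(samples, scheme="3fold", repeats=3, seed=5)
        assert a.fold_k.equals(b.fold_k)
        assert a.table.equals(b.table)

    def test_scheme_sample_count_mismatch(self):
        samples = self._cohort(3)
        with pytest.raises(ValueError, match="at least 5"):
            fs.cv_learn_k(samples, scheme="5fold")
        with pytest.raises(ValueError, match="scheme"):
            fs.cv_learn_k(samples, scheme="2fold")

    def test_corrected_model_beats_uncorrected(self):
        # directional benefit of the learned correction on a cohort with
        # genuinely positive distortion coefficients
        cohort = fs.simulate_cohort(m=8, seed=3, n_points=200, noise_sd_frac=0.01)
        samples = [(s.profile, s.R) for s in cohort]
        res = fs.cv_learn_k(samples, scheme="loo")
        err_corrected = res.table.attrs["mean_abs_diff_mm"]
        err_raw = np.mean(
            [abs(fs.estimate_R(p, 0.0).estimate - r) for p, r in samples]
        )
        assert err_corrected < err_raw


class TestEvaluate:
    def test_tabled_sample(self):
        df = fs.evaluate([1.70], [1.71])
        assert df["abs_diff_mm"].iloc[0] == pytest.approx(0.01, abs=1e-12)
        assert df["rel_diff_pct"].iloc[0] == pytest.approx(0.5848, abs=1e-3)
        assert df["accuracy_class"].iloc[0] == 1
        assert df["diff_mm"].iloc[0] > 0  # ground truth minus estimate

    def test_perfect_estimate(self):
        df = fs.evaluate([1.6], [1.6])
        assert df["abs_diff_mm"].iloc[0] == 0.0
        assert df["rel_diff_pct"].iloc[0] == 0.0
        assert df["accuracy_class"].iloc[0] == 1

    def test_class_boundaries_are_inclusive(self):
        df = fs.evaluate([0.95, 0.90, 0.89], [1.0, 1.0, 1.0])
        assert list(df["accuracy_class"]) == [1, 2, 3]

    def test_length_mismatch_and_bad_truth(self):
        with pytest.raises(ValueError, match="length mismatch"):
            fs.evaluate([1.0, 2.0], [1.0])
        with pytest.raises(ValueError, match="positive"):
            fs.evaluate([1.0], [0.0])
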