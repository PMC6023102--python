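import numpy as np
import pytest
from scipy import stats

from cgmard import (
    InvalidInputError,
    PairedDataset,
    ProtocolConfig,
    ReferenceErrorModel,
    SensorConfig,
    SurfaceCoefficients,
    build_scenario,
    compute_mri,
    delta_mard,
    fit_surface_coefficients,
    mard_ladder,
    mc_mard_distribution,
    mri_surface,
    sigma_mard,
    subsample_mard_ci,
)


class TestSurfaceFormulas:
    def test_delta_examples(self):
        # a(10) = 0.01244 - 0.0037 = 0.00874 -> 0.00874*25 = 0.2185
        assert delta_mard(5.0, 10.0) == pytest.approx(0.2185, abs=1e-6)
        # a(16) = 0.00652 -> 0.652 at err_ref = 10
        assert delta_mard(10.0, 16.0) == pytest.approx(0.652, abs=1e-6)
        assert delta_mard(0.0, 12.0) == 0.0

    def test_sigma_examples(self):
        coeff = SurfaceCoefficients.from_mard2(12.0)
        assert coeff.b == pytest.approx(9.9478, abs=1e-4)
        assert sigma_mard(0.0, 100, 12.0) == pytest.approx(0.99478, abs=1e-5)

    def test_sigma_vanishes_for_large_n(self):
        vals = [sigma_mard(5.0, n, 12.0) for n in (10, 100, 1000, 100000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 0.05

    def test_validity_range_warning(self):
        with pytest.warns(UserWarning, match="outside"):
            delta_mard(5.0, 25.0)

    def test_negative_err_rejected(self):
        with pytest.raises(InvalidInputError):
            delta_mard(-1.0, 12.0)


class TestMri:
    def test_closed_form_at_zero_offset(self):
        res = compute_mri(n_ref=200, err_ref=0.0, mard2=12.0)
        sigma = sigma_mard(0.0, 200, 12.0)
        # machine precision against the exact Gaussian quantile; the rounded
        # 1.959964 constant only carries ~7 significant digits
        assert res.mri == pytest.approx(stats.norm.ppf(0.975) * sigma, rel=1e-12)
        assert res.mri == pytest.approx(1.959964 * sigma, rel=1e-6)

    def test_quadrature_oracle(self):
        # the Gaussian N(delta, sigma^2) mass on [-MRI, MRI] must equal gamma
        for n in (50, 400):
            for e in (0.0, 5.0, 10.0):
                for m2 in (10.0, 16.0):
                    res = compute_mri(n, e, m2)
                    d, s = delta_mard(e, m2), sigma_mard(e, n, m2)
                    mass, _ = stats.norm(d, s).cdf(res.mri), None
                    mass = stats.norm(d, s).cdf(res.mri) - stats.norm(d, s).cdf(-res.mri)
                    assert mass == pytest.approx(0.95, abs=1e-9)

    def test_strictly_increasing_in_err_ref(self):
        vals = [compute_mri(200, e, 12.0).mri for e in (0, 2, 4, 6, 8, 10)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invalid_gamma(self):
        with pytest.raises(InvalidInputError):
            compute_mri(100, 5.0, 12.0, gamma=1.5)


class TestMriSurface:
    def test_single_cell_matches_compute_mri(self):
        surf = mri_surface([100], [5.0], 12.0)
        assert surf.iloc[0, 0] == compute_mri(100, 5.0, 12.0).mri

    def test_monotonicities_and_sign(self):
        surf = mri_surface([50, 100, 400], [0.0, 5.0, 10.0], 12.0)
        assert (surf.values >= 0).all()
        assert (np.diff(surf.values, axis=0) <= 1e-12).all()  # down in n_ref
        assert (np.diff(surf.values, axis=1) >= -1e-12).all()  # up in err_ref

    def test_better_sensor_more_sensitive_to_reference_error(self):
        # dMRI/derr larger at MARD2=10 than at MARD2=16
        def sens(m2):
            s = mri_surface([200], [4.0, 6.0], m2)
            return (s.iloc[0, 1] - s.iloc[0, 0]) / 2.0

        assert sens(10.0) > sens(16.0)


class TestSubsampleCi:
    def test_full_sample_zero_width(self, dense_paired_12pct):
        est = subsample_mard_ci(dense_paired_12pct, dense_paired_12pct.n, reps=100, seed=1)
        assert est.ci_high - est.ci_low == pytest.approx(0.0, abs=1e-12)
        assert est.gamma == 0.95

    def test_identical_pairs_zero_width(self):
        p = PairedDataset(
            times=np.arange(50.0),
            cgm_values=np.full(50, 110.0),
            ref_values=np.full(50, 100.0),
        )
        est = subsample_mard_ci(p, 10, reps=200, seed=1)
        assert est.ci_low == est.ci_high == pytest.approx(10.0)

    def test_width_scales_inverse_sqrt(self, dense_paired_12pct):
        # CI width at n vs 4n: ratio ~ 2, averaged over seeds
        ratios = []
        for s in range(5):
            w1 = subsample_mard_ci(dense_paired_12pct, 100, reps=600, seed=s)
            w4 = subsample_mard_ci(dense_paired_12pct, 400, reps=600, seed=s + 100)
            ratios.append((w1.ci_high - w1.ci_low) / (w4.ci_high - w4.ci_low))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)

    def test_n_ref_validation(self, dense_paired_12pct):
        with pytest.raises(InvalidInputError):
            subsample_mard_ci(dense_paired_12pct, dense_paired_12pct.n + 1, reps=100)


class TestMcDistribution:
    def test_degenerate_no_error_full_sample(self, dense_paired_12pct):
        from cgmard import compute_mard

        full = compute_mard(dense_paired_12pct).mard
        d = mc_mard_distribution(dense_paired_12pct, dense_paired_12pct.n, 0.0,
                                 reps=50, seed=3)
        assert d.sd == pytest.approx(0.0, abs=1e-12)
        assert d.mean == pytest.approx(full)

    def test_mean_nondecreasing_in_err_ref(self, dense_paired_12pct):
        means = [
            mc_mard_distribution(dense_paired_12pct, 1000, e, reps=1000, seed=5).mean
            for e in (0.0, 5.0, 10.0)
        ]
        assert means[0] < means[1] < means[2]

    def test_sd_decreasing_in_n_ref(self, dense_paired_12pct):
        sds = [
            mc_mard_distribution(dense_paired_12pct, n, 5.0, reps=1000, seed=6).sd
            for n in (50, 200, 800)
        ]
        assert sds[0] > sds[1] > sds[2]

    def test_seed_reproducibility(self, dense_paired_12pct):
        a = mc_mard_distribution(dense_paired_12pct, 200, 5.0, reps=200, seed=9)
        b = mc_mard_distribution(dense_paired_12pct, 200, 5.0, reps=200, seed=9)
        np.testing.assert_array_equal(a.samples, b.samples)


class TestSurfaceRefit:
    def test_refit_predicts_mc_moments(self, dense_paired_12pct):
        # the fitted Gaussian surface must reproduce independent MC moments
        # across a 3x3 design grid within 15% relative
        coef = fit_surface_coefficients(
            dense_paired_12pct, n_ref_grid=[100, 300, 900],
            err_ref_grid=[0.0, 4.0, 8.0], reps=300, seed=21,
        )
        for n in (100, 300, 900):
            for e in (0.0, 4.0, 8.0):
                d = mc_mard_distribution(
                    dense_paired_12pct, n, e, reps=400, seed=1000 + n + int(e)
                )
                assert d.mean == pytest.approx(coef.mard2 + coef.delta(e), rel=0.15)
                assert d.sd == pytest.approx(coef.sigma(e, n), rel=0.15)


class TestMardLadder:
    @pytest.fixture(scope="class")
    def small_scenario(self):
        proto = ProtocolConfig(n_subjects=3, n_days=3, excursion_days=(2,))
        return build_scenario(proto, SensorConfig(), seed=4)

    def test_ideal_sensor_all_levels_zero(self):
        proto = ProtocolConfig(n_subjects=2, n_days=2, excursion_days=(2,))
        sensor = SensorConfig(
            tau=0.0, noise_sd_percent=0.0, run_in_percent=0.0,
            drift_rate_percent_per_day=0.0,
            calibration_error=ReferenceErrorModel(0.0),
        )
        ladder = mard_ladder(build_scenario(proto, sensor, seed=4),
                             err_ref=0.0, reps=50, seed=9)
        assert ladder.values.max() == pytest.approx(0.0, abs=1e-12)

    def test_expected_value_ordering(self, small_scenario):
        ladder = mard_ladder(small_scenario, err_ref=5.0, reps=500, seed=9)
        m = ladder["mean_mard"]
        tol = 0.05
        assert m["MARD1"] <= m["MARD2"] + tol
        assert m["MARD2"] <= m["MARD3"] + tol
        assert m["MARD3"] <= m["MARDreal"] + tol
        # the delay and reference-error steps increase MARD outright
        assert m["MARD2"] > m["MARD1"] + 0.3
        assert m["MARDreal"] > m["MARD3"] + 0.1

    def test_sd_ordering(self, small_scenario):
        ladder = mard_ladder(small_scenario, err_ref=5.0, reps=500, seed=9)
        s = ladder["sd_mard"]
        tol = 0.03
        assert s["MARD1"] <= s["MARD2"] + tol
        assert s["MARD2"] <= s["MARD3"] + tol
        assert s["MARD3"] <= s["MARDreal"] + tol
        # finite sampling visibly widens the distribution
        assert s["MARD3"] > s["MARD2"] + 0.05
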