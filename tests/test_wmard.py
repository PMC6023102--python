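import numpy as np
import pytest
from scipy.integrate import quad

from cgmard import (
    CoverageError,
    InvalidInputError,
    PairedDataset,
    ReferenceDistribution,
    compute_weights,
    compute_wmard,
    estimate_density,
    reference_pdf,
    validate_coverage,
)


class TestReferenceDistribution:
    def test_zero_outside_truncation(self):
        dist = ReferenceDistribution()
        assert reference_pdf(500.0, dist) == 0.0
        assert reference_pdf(-5.0, dist) == 0.0
        assert reference_pdf(0.0, dist) == 0.0

    def test_normalization_constant(self):
        # k = Phi((ln 450 - mu)/sigma), argument ~3.113
        dist = ReferenceDistribution()
        assert dist.k == pytest.approx(0.9991, abs=2e-4)

    def test_density_integrates_to_one(self):
        dist = ReferenceDistribution()
        total, _ = quad(lambda x: dist.pdf(x), 1e-6, dist.upper, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_mode_matches_grid_search(self):
        dist = ReferenceDistribution()
        assert dist.mode == pytest.approx(117.9, abs=0.1)
        grid = np.linspace(50, 250, 20001)
        assert grid[np.argmax(dist.pdf(grid))] == pytest.approx(dist.mode, abs=0.05)

    def test_sampling_matches_cdf(self):
        dist = ReferenceDistribution()
        draws = dist.rvs(20000, rng=5)
        assert draws.max() <= dist.upper
        # quartiles of draws vs analytic quantiles
        for q in (0.25, 0.5, 0.75):
            emp = np.quantile(draws, q)
            grid = np.linspace(20, 449, 5000)
            ana = grid[np.searchsorted(dist.cdf(grid), q)]
            assert emp == pytest.approx(ana, rel=0.02)


class TestDensityEstimate:
    def test_single_location_peak_value(self):
        # all mass at 100: density there is the Gaussian peak 1/(10 sqrt(2pi))
        d = estimate_density([100.0, 100.0], bandwidth=10.0)
        assert d(100.0)[0] == pytest.approx(0.039894, abs=1e-6)

    def test_two_point_hand_value(self):
        d = estimate_density([90.0, 110.0], bandwidth=10.0)
        assert d(100.0)[0] == pytest.approx(0.039894 * np.exp(-0.5), abs=1e-6)

    def test_integrates_to_one(self):
        rng = np.random.default_rng(2)
        d = estimate_density(rng.uniform(60, 300, 200), bandwidth=10.0)
        grid = np.linspace(-100, 500, 4001)
        total = np.trapezoid(d(grid), grid)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_grid_path_matches_exact(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(50, 400, 500)
        d = estimate_density(vals, bandwidth=10.0)
        x = rng.uniform(45, 405, 200)
        exact = d(x)
        fast = d(x, grid_interpolated=True)
        np.testing.assert_allclose(fast, exact, rtol=5e-4)

    def test_matches_scipy_gaussian_kde(self):
        # independent oracle: scipy's KDE with the bandwidth factor set so
        # that the absolute kernel SD is 10 mg/dL
        from scipy.stats import gaussian_kde

        rng = np.random.default_rng(6)
        vals = rng.uniform(60, 350, 300)
        d = estimate_density(vals, bandwidth=10.0)
        oracle = gaussian_kde(vals, bw_method=10.0 / vals.std(ddof=1))
        x = np.linspace(50, 360, 50)
        np.testing.assert_allclose(d(x), oracle(x), rtol=1e-6)

    def test_needs_two_values(self):
        with pytest.raises(InvalidInputError):
            estimate_density([100.0])


class TestWeights:
    def test_matching_densities_give_unit_weights(self):
        dist = ReferenceDistribution()
        vals = dist.rvs(4000, rng=11)
        p_hat = estimate_density(vals, bandwidth=10.0)
        w = compute_weights(vals, dist, p_hat)
        assert np.median(w) == pytest.approx(1.0, abs=0.1)

    def test_overrepresented_region_downweighted(self):
        dist = ReferenceDistribution()
        # pile extra points near 100 on top of a representative sample
        vals = np.concatenate([dist.rvs(2000, rng=12), np.full(2000, 100.0)])
        p_hat = estimate_density(vals, bandwidth=10.0)
        w = compute_weights(vals, dist, p_hat)
        near = np.abs(vals - 100.0) < 5
        assert np.mean(w[near]) < 1.0

    def test_hand_built_ratio(self):
        class FakeDensity:
            def __call__(self, x, grid_interpolated=False):
                return np.full(np.atleast_1d(x).shape, 0.002)

        class FakePref:
            upper = 450.0

            def pdf(self, x):
                return np.full(np.atleast_1d(x).shape, 0.004)

        w = compute_weights([150.0], FakePref(), FakeDensity())
        assert w[0] == pytest.approx(2.0)

    def test_above_truncation_gets_zero_weight(self):
        dist = ReferenceDistribution(upper=450.0)
        vals = np.concatenate([dist.rvs(500, rng=13), [460.0]])
        p_hat = estimate_density(vals, bandwidth=10.0)
        w = compute_weights(vals, dist, p_hat)
        assert w[-1] == 0.0


class TestCoverage:
    def test_well_covered_design_passes(self):
        vals = np.concatenate(
            [np.arange(70.0, 351.0, 5.0), np.full(3, 60.0), np.full(3, 360.0),
             np.linspace(90, 180, 37)]  # pad to ~100 points
        )
        report = validate_coverage(vals)
        assert report.passed
        assert report.gap_70_200 <= 5.0
        assert report.frac_below_70 > 0.01
        assert report.frac_above_350 > 0.005

    def test_missing_hypo_fails(self):
        vals = np.concatenate([np.arange(70.0, 351.0, 5.0), np.full(3, 360.0)])
        report = validate_coverage(vals)
        assert not report.hypo_rule
        assert not report.passed

    def test_interior_gap_fails(self):
        vals = np.concatenate(
            [[70.0, 85.0], np.arange(100.0, 351.0, 5.0), np.full(3, 60.0),
             np.full(3, 360.0)]
        )
        report = validate_coverage(vals)
        assert report.gap_70_200 == pytest.approx(15.0)
        assert not report.gap_rule_70_200

    def test_boundary_gap_counts(self):
        # all points clustered at the high end of [70, 200]
        vals = np.concatenate(
            [np.arange(150.0, 351.0, 5.0), np.full(3, 60.0), np.full(3, 360.0)]
        )
        report = validate_coverage(vals)
        assert report.gap_70_200 == pytest.approx(80.0)
        assert not report.passed


class TestWmard:
    def test_perfect_sensor_zero(self, range_cohort):
        p = PairedDataset(
            times=range_cohort.times,
            cgm_values=range_cohort.ref_values,
            ref_values=range_cohort.ref_values,
        )
        res = compute_wmard(p)
        assert res.wmard == pytest.approx(0.0, abs=1e-12)

    def test_coverage_failure_raises_unless_forced(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(100, 200, 300)  # no hypo, no hyper
        p = PairedDataset(times=np.arange(300.0), cgm_values=ref * 1.05, ref_values=ref)
        with pytest.raises(CoverageError):
            compute_wmard(p)
        res = compute_wmard(p, force=True)
        assert res.wmard > 0

    def test_self_weighting_identity(self):
        # sampled from the target distribution, WMARD converges to MARD
        dist = ReferenceDistribution()
        rng = np.random.default_rng(8)
        ref = dist.rvs(5000, rng=rng)
        cgm = np.maximum(ref * (1 + 0.08 * rng.normal(size=5000)), 1.0)
        p = PairedDataset(times=np.arange(5000.0), cgm_values=cgm, ref_values=ref)
        res = compute_wmard(p, force=True)
        assert abs(res.wmard - res.mard) < 0.1
        assert res.effective_sample_size > 0.8 * p.n

    def test_result_carries_diagnostics(self, range_cohort):
        res = compute_wmard(range_cohort)
        assert res.coverage.passed
        assert res.n == range_cohort.n
        assert len(res.weights) == range_cohort.n
        assert np.all(res.weights >= 0)
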