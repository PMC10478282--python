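import numpy as np
import pytest

from tteval import (
    ObservationBand,
    ObservationScheme,
    PredictionInterval,
    PredictionIntervalEstimator,
    SurvivalData,
    TimeGrid,
    build_prediction_interval,
    fit_km,
    juncture,
    observation_band,
    raw_coverage,
)


class TestTimeGrid:
    def test_uniform_grid_spans_window(self):
        g = TimeGrid.uniform(10, 1000)
        assert g.points[0] == 0 and g.points[-1] == 10
        assert len(g) == 1001

    def test_event_time_grid(self):
        pool = SurvivalData([3, 1, 3, 7.5])
        g = TimeGrid.from_event_times(pool, t_end=5)
        np.testing.assert_allclose(g.points, [0, 1, 3])

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            TimeGrid(np.array([]))
        with pytest.raises(ValueError):
            TimeGrid(np.array([0.0, 2.0, 1.0]))


class TestBuildPredictionInterval:
    def test_degenerate_pool_zero_variance(self, rng):
        pool = SurvivalData(np.full(500, 4.0))
        grid = TimeGrid.uniform(4.0, 40)
        pi = build_prediction_interval(pool, 30, 50, grid, rng)
        np.testing.assert_allclose(pi.lo, pi.hi)
        np.testing.assert_allclose(pi.lo, (grid.points < 4.0).astype(float))

    def test_single_iteration_band_is_that_curve(self, rng):
        pool = SurvivalData(rng.exponential(10, 1000))
        grid = TimeGrid.uniform(15, 100)
        seed_state = rng.bit_generator.state
        pi = build_prediction_interval(pool, 40, 1, grid, rng)
        # replay the same draw to recover the subsample
        rng2 = np.random.default_rng()
        rng2.bit_generator.state = seed_state
        idx = rng2.choice(len(pool), 40, replace=False)
        km = fit_km(pool.times[idx])
        np.testing.assert_allclose(pi.lo, pi.hi)
        np.testing.assert_allclose(pi.lo, km.predict(grid.points))

    def test_exponential_pool_brackets_analytic_survival(self, exp_pool):
        """At t = 1/λ the band straddles e^-1 for same-rate subsamples."""
        grid = TimeGrid.uniform(20, 200)
        pi = build_prediction_interval(
            exp_pool, 74, 2000, grid, np.random.default_rng(5)
        )
        t = 1 / 0.08
        j = np.searchsorted(grid.points, t)
        assert pi.lo[j] < np.exp(-1) < pi.hi[j]

    def test_band_monotone_and_bounded(self, exp_pool):
        grid = TimeGrid.uniform(30, 300)
        pi = build_prediction_interval(
            exp_pool, 74, 300, grid, np.random.default_rng(6)
        )
        assert np.all(np.diff(pi.lo) <= 1e-12)
        assert np.all(np.diff(pi.hi) <= 1e-12)
        assert np.all((0 <= pi.lo) & (pi.lo <= pi.hi) & (pi.hi <= 1))

    def test_pool_smaller_than_sample_raises(self, rng):
        pool = SurvivalData([1, 2, 3.0])
        with pytest.raises(ValueError, match="pool smaller"):
            build_prediction_interval(pool, 5, 10, TimeGrid.uniform(3, 10), rng)

    def test_censored_pool_uses_product_limit(self, rng):
        pool = SurvivalData(rng.exponential(10, 300), rng.random(300) > 0.2)
        grid = TimeGrid.uniform(10, 50)
        pi = build_prediction_interval(pool, 50, 20, grid, rng)
        assert np.all(pi.lo <= pi.hi)

    def test_estimator_facade(self, rng):
        pool = SurvivalData(rng.exponential(10, 2000))
        est = PredictionIntervalEstimator(
            sample_size=50, n_iter=100, grid=TimeGrid.uniform(15, 100),
            random_state=3,
        ).fit(pool)
        assert est.lo_.shape == est.grid_.points.shape
        obs = SurvivalData(rng.exponential(10, 50))
        assert 0 <= est.score(obs) <= 100


def _piecewise_interval(grid, pieces):
    """Build (lo, hi) arrays from [(t_from, lo, hi), ...] segments."""
    lo = np.empty_like(grid)
    hi = np.empty_like(grid)
    for t_from, lo_v, hi_v in pieces:
        mask = grid >= t_from
        lo[mask], hi[mask] = lo_v, hi_v
    return lo, hi


class TestMetrics:
    def test_observed_median_curve_fully_covered(self, exp_pool, rng):
        grid = TimeGrid.uniform(20, 200)
        pi = build_prediction_interval(exp_pool, 74, 500, grid, rng)
        median_curve = fit_km(
            SurvivalData(np.random.default_rng(8).exponential(1 / 0.08, 5000))
        )
        assert raw_coverage(median_curve, pi) > 99.0

    def test_curve_above_band_zero_coverage(self):
        grid = TimeGrid.uniform(10, 100)
        lo, hi = _piecewise_interval(grid.points, [(0.0, 0.1, 0.4)])
        pi = PredictionInterval(grid, lo, hi, n_iter=1, sample_size=1)
        high = fit_km(SurvivalData([12.0], [0]))  # S = 1 everywhere
        assert raw_coverage(high, pi) == 0.0

    def test_band_identical_to_interval_full_juncture(self):
        grid = TimeGrid.uniform(10, 100)
        lo, hi = _piecewise_interval(grid.points, [(0.0, 0.3, 0.8), (5.0, 0.1, 0.5)])
        pi = PredictionInterval(grid, lo, hi, n_iter=1, sample_size=1)
        band = ObservationBand(grid.points, lo.copy(), hi.copy())
        assert juncture(band, pi) == 100.0

    def test_disjoint_band_zero_juncture(self):
        grid = TimeGrid.uniform(10, 100)
        lo, hi = _piecewise_interval(grid.points, [(0.0, 0.1, 0.3)])
        pi = PredictionInterval(grid, lo, hi, n_iter=1, sample_size=1)
        b_lo, b_hi = _piecewise_interval(grid.points, [(0.0, 0.5, 0.9)])
        band = ObservationBand(grid.points, b_lo, b_hi)
        assert juncture(band, pi) == 0.0

    def test_mismatched_grids_rejected(self):
        g1, g2 = TimeGrid.uniform(10, 100), TimeGrid.uniform(10, 50)
        lo1, hi1 = _piecewise_interval(g1.points, [(0.0, 0.1, 0.3)])
        lo2, hi2 = _piecewise_interval(g2.points, [(0.0, 0.1, 0.3)])
        pi = PredictionInterval(g1, lo1, hi1, n_iter=1, sample_size=1)
        band = ObservationBand(g2.points, lo2, hi2)
        with pytest.raises(ValueError, match="grid"):
            juncture(band, pi)

    def test_touching_boundary_counts_as_covered(self):
        grid = TimeGrid.uniform(10, 10)
        lo, hi = _piecewise_interval(grid.points, [(0.0, 0.5, 1.0)])
        pi = PredictionInterval(grid, lo, hi, n_iter=1, sample_size=1)
        # observed curve sits exactly on the lower boundary after t=1
        obs = fit_km(SurvivalData([1.0, 1.0, 12, 12], [1, 1, 0, 0]))
        assert raw_coverage(obs, pi) == 100.0

    def test_widening_interval_never_lowers_metrics(self, exp_pool, rng):
        grid = TimeGrid.uniform(20, 200)
        pi = build_prediction_interval(exp_pool, 74, 300, grid, rng)
        obs = fit_km(SurvivalData(rng.exponential(9, 74)))
        band = observation_band(obs, ObservationScheme(2.0), grid.points)
        wide = PredictionInterval(
            grid,
            np.clip(pi.lo - 0.1, 0, 1),
            np.clip(pi.hi + 0.1, 0, 1),
            n_iter=pi.n_iter,
            sample_size=pi.sample_size,
        )
        assert raw_coverage(obs, wide) >= raw_coverage(obs, pi)
        assert juncture(band, wide) >= juncture(band, pi)
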