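import numpy as np
import pandas as pd
import pytest
from scipy import stats

from surfdrift.synthetic_data import SynthConfig, WindSeries, synth_winds
from surfdrift.wind_response import (
    binned_distributions,
    direction_bin,
    major_axis_fit,
    merge_winds,
    speed_bin,
    tukey_pairwise,
    window_mean,
)


def _series(speed, direction, start="2015-01-01", station="A"):
    n = len(speed)
    return WindSeries(
        station=station,
        times=pd.date_range(start, periods=n, freq="15min"),
        speed_ms=np.asarray(speed, float),
        direction_deg=np.asarray(direction, float),
    )


class TestMerge:
    def test_identical_series_unchanged(self):
        a = _series([5, 6, 7], [10, 20, 30])
        m = merge_winds(a, _series([5, 6, 7], [10, 20, 30], station="B"))
        assert np.allclose(m.speed_ms, a.speed_ms)
        assert np.allclose(m.direction_deg, a.direction_deg)

    def test_collinear_speeds_average(self):
        m = merge_winds(_series([4], [90.0]), _series([6], [90.0]))
        assert m.speed_ms[0] == pytest.approx(5.0)
        assert m.direction_deg[0] == pytest.approx(90.0)

    def test_opposite_directions_cancel(self):
        m = merge_winds(_series([5], [0.0]), _series([5], [180.0]))
        assert m.speed_ms[0] == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(m.direction_deg[0])

    def test_scalar_speed_option(self):
        m = merge_winds(_series([5], [0.0]), _series([5], [180.0]), how="scalar")
        assert m.speed_ms[0] == pytest.approx(5.0)

    def test_no_overlap_rejected(self):
        a = _series([1, 2], [0, 0], start="2015-01-01")
        b = _series([1, 2], [0, 0], start="2016-06-01")
        with pytest.raises(ValueError, match="overlap"):
            merge_winds(a, b)


class TestWindowMean:
    def test_constant_series(self):
        w = _series(np.full(400, 5.0), np.full(400, 90.0))
        sp, dr, sd = window_mean(w, "2015-01-01", 2.0)
        assert sp == pytest.approx(5.0)
        assert dr == pytest.approx(90.0)
        assert sd == 0.0

    def test_linear_ramp_mean(self):
        n = 96 * 2 + 1  # exactly two days inclusive
        speed = np.linspace(0, 10, n)
        w = _series(speed, np.zeros(n))
        sp, _, _ = window_mean(w, "2015-01-01", 2.0)
        assert sp == pytest.approx(5.0, abs=10 / n)

    def test_inclusive_ends_sample_count(self):
        """A 1.9-day window spans 45.6 h; at 15-min cadence the last included
        sample sits at 45.5 h, giving 183 samples."""
        w = _series(np.arange(400, dtype=float), np.zeros(400))
        t0 = pd.Timestamp("2015-01-01")
        sel = (w.times >= t0) & (w.times <= t0 + pd.Timedelta(days=1.9))
        assert sel.sum() == 183
        sp, _, _ = window_mean(w, t0, 1.9)
        assert sp == pytest.approx(np.arange(183).mean())

    def test_window_past_record_rejected(self):
        w = _series(np.full(40, 5.0), np.zeros(40))
        with pytest.raises(ValueError, match="beyond"):
            window_mean(w, "2015-01-01", 5.0)

    def test_circular_mean_wraps_north(self):
        n = 97
        dirs = np.where(np.arange(n) % 2 == 0, 350.0, 10.0)
        w = _series(np.full(n, 5.0), dirs)
        _, dr, _ = window_mean(w, "2015-01-01", 1.0)
        assert dr == pytest.approx(0.0, abs=0.5) or dr == pytest.approx(360.0, abs=0.5)


class TestMajorAxis:
    def test_noiseless_line_recovered(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fit = major_axis_fit(x, 3.0 - 0.18 * x)
        assert fit.slope == pytest.approx(-0.18)
        assert fit.intercept == pytest.approx(3.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_equal_variances_gives_unit_slope(self):
        """With s_xx = s_yy and positive covariance the major axis is the
        diagonal (slope exactly 1) even though OLS would give < 1."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        e = rng.normal(size=500)
        y = 0.6 * x + 0.8 * e
        # symmetrize empirically: rescale y to match x variance exactly
        y = y * x.std(ddof=1) / y.std(ddof=1)
        fit = major_axis_fit(x, y)
        assert fit.slope == pytest.approx(1.0, abs=1e-9)
        ols = np.cov(x, y, ddof=1)[0, 1] / x.var(ddof=1)
        assert ols < 1.0

    def test_swap_gives_reciprocal_slope(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        y = -0.5 * x + rng.normal(size=200) * 0.3
        f1 = major_axis_fit(x, y)
        f2 = major_axis_fit(y, x)
        assert f2.slope == pytest.approx(1.0 / f1.slope, rel=1e-9)

    def test_matches_principal_axis_of_covariance(self):
        """Independent oracle: the MA slope is the direction of the leading
        eigenvector of the 2x2 covariance matrix."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = 1.7 * x + rng.normal(size=300)
        fit = major_axis_fit(x, y)
        cov = np.cov(x, y, ddof=1)
        w, v = np.linalg.eigh(cov)
        lead = v[:, np.argmax(w)]
        assert fit.slope == pytest.approx(lead[1] / lead[0], rel=1e-9)

    def test_unbiased_under_symmetric_errors_where_ols_attenuates(self):
        """With equal error on both variables the MA slope stays at the true
        value while OLS is attenuated toward zero."""
        rng = np.random.default_rng(8)
        t = rng.normal(size=4000)
        x = t + rng.normal(size=4000) * 0.5
        y = t + rng.normal(size=4000) * 0.5
        ma = major_axis_fit(x, y).slope
        ols = np.cov(x, y, ddof=1)[0, 1] / x.var(ddof=1)
        assert ma == pytest.approx(1.0, abs=0.05)
        assert ols < 0.9

    def test_ci_contains_slope_and_degenerate_errors(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=100)
        y = 2 * x + rng.normal(size=100) * 0.5
        fit = major_axis_fit(x, y)
        assert fit.ci_lo <= fit.slope <= fit.ci_hi
        with pytest.raises(ValueError, match="zero variance"):
            major_axis_fit(np.ones(10), rng.normal(size=10))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            major_axis_fit([1, 2], [3, 4])


class TestBinning:
    @pytest.mark.parametrize("speed,expected", [(7.4, 7), (7.5, 8), (0.2, 0)])
    def test_speed_bins_half_open(self, speed, expected):
        assert speed_bin([speed])[0] == expected

    @pytest.mark.parametrize("deg,expected", [(359.0, 0), (14.9, 0), (15.0, 30), (210.0, 210)])
    def test_direction_bins_wrap(self, deg, expected):
        assert direction_bin([deg])[0] == expected

    def test_every_sample_in_exactly_one_bin(self):
        rng = np.random.default_rng(7)
        speeds = rng.uniform(0, 14, 300)
        res = rng.uniform(0.2, 5, 300)
        bins = binned_distributions(speeds, res, mode="speed")
        assert sum(b.n for b in bins) == 300


class TestTukey:
    def test_identical_groups_not_distinguished(self):
        g = {"a": np.full(15, 2.0) + np.arange(15) * 1e-3,
             "b": np.full(15, 2.0) + np.arange(15) * 1e-3}
        table, excluded = tukey_pairwise(g)
        assert float(table["p-adj"].iloc[0]) > 0.9

    def test_separated_groups_flagged_vs_scipy_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.normal(1.0, 0.05, 20)
        b = rng.normal(3.0, 0.05, 20)
        table, _ = tukey_pairwise({"a": a, "b": b})
        assert float(table["p-adj"].iloc[0]) < 0.01
        # independent route: scipy's studentized-range based Tukey HSD
        oracle = stats.tukey_hsd(a, b)
        assert oracle.pvalue[0, 1] < 0.01

    def test_small_groups_excluded(self):
        g = {"a": [1.0, 1.1, 0.9], "b": [2.0, 2.1, 1.9], "c": [5.0]}
        table, excluded = tukey_pairwise(g)
        assert excluded == ["c"]
        assert len(table) == 1

    def test_all_groups_small_rejected(self):
        with pytest.raises(ValueError):
            tukey_pairwise({"a": [1.0], "b": [2.0]})


def test_merged_wind_tracks_latent_wind():
    cfg = SynthConfig(duration_days=10.0, seed=12)
    a, b = synth_winds(cfg)
    m = merge_winds(a, b)
    # station noise is small: merged speed correlates strongly with either
    r = np.corrcoef(m.speed_ms, a.speed_ms)[0, 1]
    assert r > 0.9
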