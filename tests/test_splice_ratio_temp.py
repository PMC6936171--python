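"""Splicing ratios, fold ranges, and temperature regression."""

import numpy as np
import pytest

from dielsplice.rhythm_stats import IsoformSeries
from dielsplice.splice_ratio_temp import (
    AlignmentError,
    InsufficientDataError,
    RatioSeries,
    TemperatureSeries,
    default_pseudo_count,
    ratio_fold_range,
    ratio_series,
    temp_regression,
)


def series(values, isoform="FS", zt=None):
    values = np.asarray(values, float)
    if zt is None:
        zt = np.arange(len(values), dtype=float)
    return IsoformSeries(
        gene_id="g", isoform_id=isoform, organ="L1", season_id="winter",
        zt=np.asarray(zt, float), replicate=np.ones(len(values), int),
        abundance=values,
    )


def make_ratio(log_ratios, zt=None, clock=None, base=10.0):
    log_ratios = np.asarray(log_ratios, float)
    n = len(log_ratios)
    if zt is None:
        zt = np.linspace(0, 22, n)
    if clock is None:
        clock = np.asarray(zt, float)
    return RatioSeries(
        gene_id="g", event_id="AS", organ="L1", season_id="winter",
        zt=np.asarray(zt, float), replicate=np.ones(n, int),
        clock_time=np.asarray(clock, float), log_ratio=log_ratios,
        pseudo_count=0.0, log_base=base,
    )


class TestRatioSeries:
    def test_equal_abundances_give_zero(self):
        rs = ratio_series(series([2.0, 3.0, 1.0], "AS"), series([2.0, 3.0, 1.0]))
        assert np.allclose(rs.log_ratio, 0.0)

    def test_tenfold_gives_one_in_log10(self):
        rs = ratio_series(series([10.0, 50.0], "AS", zt=[0, 2]),
                          series([1.0, 5.0], zt=[0, 2]))
        assert np.allclose(rs.log_ratio, 1.0)

    def test_antisymmetry(self, rng):
        a = series(rng.lognormal(size=8), "AS")
        f = series(rng.lognormal(size=8))
        fwd = ratio_series(a, f, pseudo=0.01)
        rev = ratio_series(f, a, pseudo=0.01)
        assert np.allclose(fwd.log_ratio, -rev.log_ratio)

    def test_double_zero_points_dropped_with_count(self):
        rs = ratio_series(series([1.0, 0.0, 2.0], "AS"), series([1.0, 0.0, 4.0]),
                          pseudo=0.1)
        assert rs.n_dropped == 1
        assert len(rs.log_ratio) == 2

    def test_misaligned_series_rejected(self):
        with pytest.raises(AlignmentError):
            ratio_series(series([1.0, 2.0], "AS", zt=[0, 2]),
                         series([1.0, 2.0], zt=[0, 4]))

    def test_generator_mean_recovered(self, rng):
        """log10 ratio of -1 plus noise sd 0.05 over 42 points recovers the
        mean within 0.02."""
        n = 42
        lr = -1.0 + rng.normal(0, 0.05, n)
        fs = rng.lognormal(0, 0.1, n) + 0.5
        as_ab = fs * 10**lr
        zt = np.tile(np.linspace(0, 26, 14), 3)[:n]
        rep = np.repeat([1, 2, 3], 14)[:n]
        a = IsoformSeries("g", "AS", "L1", "w", zt, rep, as_ab,
                          point_id=np.arange(n))
        f = IsoformSeries("g", "FS", "L1", "w", zt, rep, fs,
                          point_id=np.arange(n))
        rs = ratio_series(a, f)
        assert rs.log_ratio.mean() == pytest.approx(-1.0, abs=0.02)

    def test_default_pseudo_count_is_half_min_nonzero(self):
        assert default_pseudo_count([0.0, 0.4, 1.0]) == pytest.approx(0.2)
        assert default_pseudo_count([0.0, 0.0]) == 0.0


class TestFoldRange:
    def test_constant_ratio_fold_one(self):
        assert ratio_fold_range(make_ratio(np.full(5, -0.3))) == pytest.approx(1.0)

    def test_two_decades_fold_100(self):
        assert ratio_fold_range(make_ratio([-1.0, 0.0, 1.0])) == pytest.approx(100.0)

    def test_constructed_77_fold_series(self):
        span = np.log10(77.0)
        lr = np.linspace(-span / 2, span / 2, 14)
        assert ratio_fold_range(make_ratio(lr)) == pytest.approx(77.0, rel=1e-9)

    def test_base_invariance_on_linear_scale(self):
        lr10 = np.array([-1.0, -0.2, 0.5])
        lre = lr10 * np.log(10.0)
        f10 = ratio_fold_range(make_ratio(lr10, base=10.0))
        fe = ratio_fold_range(make_ratio(lre, base=np.e))
        assert f10 == pytest.approx(fe)

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            ratio_fold_range(make_ratio([0.0], zt=[0.0]))


class TestTempRegression:
    TEMPS = TemperatureSeries("winter", np.arange(0.0, 40.0, 1.0),
                              20.0 + 0.5 * np.arange(0.0, 40.0, 1.0))

    def test_noiseless_line_recovered(self):
        clock = np.linspace(0, 26, 14)
        temp = self.TEMPS.at(clock)
        lr = 1.0 - 0.05 * temp
        res = temp_regression(make_ratio(lr, clock=clock), self.TEMPS)
        assert res.slope == pytest.approx(-0.05, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)
        assert res.significant_negative

    def test_matches_closed_form_ols(self):
        clock = np.array([0.0, 2.0, 5.0, 9.0, 14.0])
        lr = np.array([0.3, -0.1, 0.2, -0.4, 0.1])
        x = self.TEMPS.at(clock)
        res = temp_regression(make_ratio(lr, clock=clock), self.TEMPS)
        beta = np.cov(x, lr, ddof=1)[0, 1] / np.var(x, ddof=1)
        alpha = lr.mean() - beta * x.mean()
        r2 = np.corrcoef(x, lr)[0, 1] ** 2
        assert res.slope == pytest.approx(beta, abs=1e-9)
        assert res.intercept == pytest.approx(alpha, abs=1e-9)
        assert res.r_squared == pytest.approx(r2, abs=1e-9)

    def test_permutation_null_matches_alpha_over_two(self, rng):
        """Against permuted temperatures, the significant-negative rate is
        about alpha/2 (half of the two-sided alpha)."""
        clock = np.tile(np.linspace(0, 26, 14), 3)
        x = self.TEMPS.at(clock)
        lr = rng.normal(size=len(clock))
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = rng.permutation(len(clock))
            res = temp_regression(make_ratio(lr, clock=clock[perm]), self.TEMPS)
            hits += res.significant_negative
        rate = hits / n_perm
        assert abs(rate - 0.025) < 0.015

    def test_insufficient_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            temp_regression(make_ratio([0.1, 0.2], zt=[0.0, 2.0], clock=[0.0, 2.0]),
                            self.TEMPS)

    def test_uncovered_sampling_instant_rejected(self):
        with pytest.raises(ValueError):
            self.TEMPS.at(np.array([55.0]))
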