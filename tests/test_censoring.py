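import numpy as np
import pytest
from scipy import stats

from plastrend.censoring import (
    CensoredSeries,
    censoring_report,
    hirsch_stedinger_positions,
    ros_impute,
)
from plastrend.exceptions import InsufficientDataError, PlastrendError


def make_series(values, censored, limits):
    return CensoredSeries(np.asarray(values, float), np.asarray(censored, bool),
                          np.asarray(limits, float))


# Frozen from an independent from-scratch evaluation of the plotting-position
# and least-squares formulas (single limit 1.0; detects 1.5, 2, 3.5, 5, 10;
# three non-detects). Exceedance of the limit = 5/8; detect positions
# 0.375 + 0.625 r/6; censored positions 0.375 r/4; then OLS of log value on
# normal quantiles and prediction at the censored positions.
HAND_ORACLE = {
    "positions": [0.09375, 0.1875, 0.28125,
                  0.47916667, 0.58333333, 0.6875, 0.79166667, 0.89583333],
    "intercept": 0.45835956,
    "slope": 1.46157711,
    "imputed": [0.23038234, 0.43245650, 0.67835349],
}


def hand_series():
    return make_series(
        [np.nan, np.nan, np.nan, 1.5, 2.0, 3.5, 5.0, 10.0],
        [True, True, True, False, False, False, False, False],
        [1.0, 1.0, 1.0, np.nan, np.nan, np.nan, np.nan, np.nan],
    )


class TestPlottingPositions:
    def test_hand_worked_single_limit(self):
        p = hirsch_stedinger_positions(hand_series())
        assert np.allclose(p, HAND_ORACLE["positions"], atol=1e-8)

    def test_positions_in_unit_interval_multiple_limits(self, rng):
        x = rng.lognormal(1.0, 1.0, 200)
        limits = rng.choice([0.5, 1.0, 2.0], 200)
        cen = x < limits
        s = make_series(np.where(cen, np.nan, x), cen, np.where(cen, limits, np.nan))
        p = hirsch_stedinger_positions(s)
        assert np.all((p > 0) & (p < 1))
        # detected values keep their rank order in the positions
        det = ~s.censored
        order = np.argsort(s.values[det])
        assert np.all(np.diff(p[det][order]) > 0)


class TestROSImpute:
    def test_no_censoring_is_identity(self, rng):
        x = rng.lognormal(0.0, 1.0, 50)
        s = make_series(x, np.zeros(50, bool), np.full(50, np.nan))
        res = ros_impute(s)
        assert np.array_equal(res.values, x)
        assert res.n_clipped == 0

    def test_matches_hand_oracle(self):
        res = ros_impute(hand_series())
        assert res.log_mean == pytest.approx(HAND_ORACLE["intercept"], abs=1e-6)
        assert res.log_sd == pytest.approx(HAND_ORACLE["slope"], abs=1e-6)
        assert np.allclose(res.values[:3], HAND_ORACLE["imputed"], atol=1e-6)

    def test_lognormal_tail_monte_carlo(self, rng):
        """Imputed log-values of a censored lognormal tail match the analytic
        conditional mean of a standard normal below its 10th percentile."""
        x = rng.lognormal(0.0, 1.0, 2000)
        thr = np.quantile(x, 0.10)
        cen = x < thr
        s = make_series(np.where(cen, np.nan, x), cen, np.where(cen, thr, np.nan))
        res = ros_impute(s)
        z = stats.norm.ppf(0.10)
        true_cond = -stats.norm.pdf(z) / 0.10   # E[Z | Z < z]
        assert np.log(res.values[cen]).mean() == pytest.approx(true_cond, abs=0.1)

    def test_uncensored_values_untouched(self, rng):
        x = rng.lognormal(0.0, 1.0, 300)
        cen = x < 0.3
        s = make_series(np.where(cen, np.nan, x), cen, np.where(cen, 0.3, np.nan))
        res = ros_impute(s)
        assert np.array_equal(res.values[~cen], x[~cen])

    def test_imputations_never_exceed_their_limit(self, rng):
        x = rng.lognormal(0.0, 2.0, 500)
        limits = rng.choice([0.1, 0.5, 2.0], 500)
        cen = x < limits
        s = make_series(np.where(cen, np.nan, x), cen, np.where(cen, limits, np.nan))
        res = ros_impute(s)
        assert np.all(res.values[cen] <= limits[cen] + 1e-12)

    def test_raising_a_limit_does_not_decrease_imputations(self):
        low = ros_impute(hand_series()).values[:3]
        s2 = make_series(
            [np.nan, np.nan, np.nan, 1.5, 2.0, 3.5, 5.0, 10.0],
            [True, True, True, False, False, False, False, False],
            [1.4, 1.4, 1.4, np.nan, np.nan, np.nan, np.nan, np.nan],
        )
        high = ros_impute(s2).values[:3]
        assert np.all(high >= low - 1e-12)

    def test_log_space_normality_across_replicates(self):
        """After imputation, observed+imputed log values stay consistent with
        a normal model in the vast majority of lognormal replicates."""
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            r = np.random.default_rng(1000 + rep)
            x = r.lognormal(0.0, 1.0, 300)
            thr = np.quantile(x, 0.2)
            cen = x < thr
            s = make_series(np.where(cen, np.nan, x), cen,
                            np.where(cen, thr, np.nan))
            res = ros_impute(s)
            _, pval = stats.shapiro(np.log(res.values))
            rejections += pval < 0.01
        assert rejections / n_rep <= 0.05

    def test_insufficient_data_errors(self):
        with pytest.raises(InsufficientDataError):
            ros_impute(make_series([np.nan, np.nan, 1.0, 2.0],
                                   [True, True, False, False],
                                   [1.0, 1.0, np.nan, np.nan]))
        x = np.r_[np.full(13, np.nan), [1.0, 2.0, 3.0]]
        cen = np.r_[np.ones(13, bool), np.zeros(3, bool)]
        lim = np.r_[np.full(13, 0.5), np.full(3, np.nan)]
        with pytest.raises(InsufficientDataError):
            ros_impute(make_series(x, cen, lim))  # 13/16 censored > 0.8
        # entirely censored input cannot even be constructed
        with pytest.raises(InsufficientDataError):
            make_series([np.nan], [True], [1.0])

    def test_nonpositive_uncensored_rejected(self):
        with pytest.raises(PlastrendError):
            make_series([0.0, 1.0, 2.0], [False, False, False],
                        [np.nan, np.nan, np.nan])


class TestReport:
    def test_counts(self, rng):
        x = rng.lognormal(0.0, 1.0, 100)
        cen = np.zeros(100, bool)
        cen[:20] = True
        s = make_series(np.where(cen, np.nan, x), cen, np.where(cen, 0.5, np.nan))
        rep = censoring_report(s)
        assert rep["n"] == 100 and rep["n_censored"] == 20
        assert rep["censored_fraction"] == pytest.approx(0.20)

    def test_empty_series_warns(self):
        s = make_series([], [], [])
        with pytest.warns(UserWarning):
            rep = censoring_report(s)
        assert rep["n"] == 0

    def test_after_imputation_no_censored_left(self, processed):
        assert not processed["censored"].any()
        assert processed["concentration"].gt(0).all()
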