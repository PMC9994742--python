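import datetime as dt

import numpy as np
import pandas as pd
import pytest

from plastrend.constants import Constants
from plastrend.exceptions import ModelError
from plastrend.trend_model import (
    DAY_ZERO,
    DAYS_PER_YEAR,
    ModelInput,
    TrendFit,
    count_to_mass,
    fit_joint,
    fit_stage1,
    fit_stage2,
    globalize,
    mean_concentration,
    prepare_model_input,
    render_table,
    render_trend,
    run_two_stage,
)

BASINS = ["NorthAtlantic", "NorthPacific", "SouthPacific"]
OFFSETS = {"NorthAtlantic": 0.0, "NorthPacific": 0.6, "SouthPacific": -0.4}


def synthetic_inputs(rng, n=5000, beta_z=2.0, noise=0.5, trend=None):
    z = rng.normal(0.0, 1.0, n)
    basin = rng.choice(BASINS, n)
    t = rng.uniform(0.0, 41.0 * DAYS_PER_YEAR, n)
    y = beta_z * z + np.array([OFFSETS[b] for b in basin]) + rng.normal(0, noise, n)
    if trend is not None:
        y = y + trend(t)
    return ModelInput(log_concentration=y, expected_z=z, basin=basin,
                      time_days=t, concentration=np.exp(y))


class TestStage1:
    def test_removes_expected_covariate(self, rng):
        inputs = synthetic_inputs(rng)
        res = fit_stage1(inputs)
        rho = np.corrcoef(res.residuals, inputs.expected_z)[0, 1]
        assert abs(rho) < 0.05
        assert abs(res.residuals.mean()) < 0.02

    def test_single_basin_drops_term_with_warning(self, rng):
        inputs = synthetic_inputs(rng, n=500)
        single = ModelInput(inputs.log_concentration, inputs.expected_z,
                            np.array(["NorthAtlantic"] * 500, dtype=object),
                            inputs.time_days, inputs.concentration)
        with pytest.warns(UserWarning, match="basin term dropped"):
            res = fit_stage1(single)
        assert not res.basin_term_used

    def test_too_few_stations_rejected(self, rng):
        inputs = synthetic_inputs(rng, n=20)
        with pytest.raises(ModelError):
            fit_stage1(inputs)

    def test_gamma_family_sensitivity_option(self, rng):
        inputs = synthetic_inputs(rng, n=800)
        res = fit_stage1(inputs, family="gamma")
        assert res.family == "gamma"
        # both families should broadly agree on the debiased residuals
        base = fit_stage1(inputs)
        assert np.corrcoef(res.residuals, base.residuals)[0, 1] > 0.9


class TestStage2:
    def test_constant_residuals_recovered(self, rng):
        t = rng.uniform(0, 41 * DAYS_PER_YEAR, 400)
        r = np.full(400, 0.7)
        fit = fit_stage2(r, t)
        assert np.max(np.abs(fit.r_hat - 0.7)) < 1e-6
        assert np.all(fit.se > 0)

    def test_known_sine_signal_recovered(self, rng):
        n = 8000
        t = rng.uniform(0, 41 * DAYS_PER_YEAR, n)
        signal = np.sin(2 * np.pi * t / (20 * DAYS_PER_YEAR))
        r = signal + rng.normal(0, 0.3, n)
        fit = fit_stage2(r, t)
        g_years = (fit.grid_dates - pd.Timestamp(DAY_ZERO)).days.to_numpy()
        true_grid = np.sin(2 * np.pi * g_years / (20 * DAYS_PER_YEAR))
        assert np.corrcoef(fit.r_hat, true_grid)[0, 1] >= 0.9

    def test_se_wider_where_data_sparse(self, rng):
        # dense 1990-2015, a handful of stations at the edges
        t_dense = rng.uniform(11 * DAYS_PER_YEAR, 36 * DAYS_PER_YEAR, 3000)
        t_edge = rng.uniform(0, 2 * DAYS_PER_YEAR, 10)
        t = np.r_[t_dense, t_edge]
        r = rng.normal(0, 0.5, t.size)
        fit = fit_stage2(r, t)
        years = fit.grid_dates.year
        se_left = fit.se[years <= 1985].mean()
        se_right = fit.se[years >= 2017].mean()
        se_mid = fit.se[(years >= 1995) & (years <= 2010)].mean()
        assert se_left > 2 * se_mid
        assert se_right > 2 * se_mid

    def test_needs_two_distinct_years(self, rng):
        t = rng.uniform(0, 100.0, 50)  # all in 1979
        with pytest.raises(ModelError):
            fit_stage2(rng.normal(size=50), t)


def flat_trend_fit(se=1e-9):
    grid = pd.date_range("1979-01-01", "2019-12-31", freq="D")
    n = len(grid)
    return TrendFit(grid_dates=grid, r_hat=np.zeros(n), se=np.full(n, se),
                    edf=1.0, lambda_=1.0, method="reml", n_obs=100)


class TestGlobalize:
    def test_flat_trend_closed_form(self):
        """r = 0 everywhere and mean concentration 1e5 pieces/km^2 gives
        1e5 x 3.619e8 km^2 = 36.19 trillion particles every year."""
        table = globalize(flat_trend_fit(), 1e5)
        assert len(table) == 41
        assert np.allclose(table["count_mean"], 36.19, rtol=1e-6)

    def test_bounds_ordered(self, processed):
        _, _, table, _ = run_two_stage(processed)
        assert (table["count_lower"] <= table["count_mean"]).all()
        assert (table["count_mean"] <= table["count_upper"]).all()
        # multiplicative bounds are asymmetric on the raw scale
        up = table["count_upper"] - table["count_mean"]
        down = table["count_mean"] - table["count_lower"]
        assert (up > down).all()

    def test_doubling_mean_conc_doubles_all_columns(self):
        t1 = globalize(flat_trend_fit(se=0.1), 1e5)
        t2 = globalize(flat_trend_fit(se=0.1), 2e5)
        for col in ("count_mean", "count_lower", "count_upper",
                    "mass_mean", "mass_lower", "mass_upper"):
            assert np.allclose(t2[col], 2 * t1[col], rtol=1e-12)

    def test_anchor_subtracted(self):
        fit = flat_trend_fit()
        fit.anchor_log = np.log(2.0)
        table = globalize(fit, 1e5)
        assert np.allclose(table["count_mean"], 36.19 / 2.0, rtol=1e-6)


class TestCountToMass:
    @pytest.mark.parametrize("count_tr,mass_mt", [
        (171.16, 2.33), (81.98, 1.11), (357.56, 4.86),
        (46.82, 0.64), (15.40, 0.21), (142.50, 1.94),
    ])
    def test_fixed_conversion_two_decimals(self, count_tr, mass_mt):
        assert round(count_to_mass(count_tr * 1e12), 2) == mass_mt

    def test_zero(self):
        assert count_to_mass(0.0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ModelError):
            count_to_mass(-1.0)


class TestReporting:
    def test_table_shape_and_internal_consistency(self, processed, tmp_path):
        _, trend, table, _ = run_two_stage(processed)
        assert len(table) == 41
        assert table["year"].tolist() == list(range(1979, 2020))
        for col in ("mean", "lower", "upper"):
            assert np.allclose(table[f"mass_{col}"],
                               count_to_mass(table[f"count_{col}"].to_numpy() * 1e12),
                               rtol=1e-12)
        assert table["n_samples"].sum() == len(processed)

        render_table(table, tmp_path / "table1.csv")
        back = pd.read_csv(tmp_path / "table1.csv", comment="#")
        assert len(back) == 41
        render_trend(trend, tmp_path / "trend.csv")
        daily = pd.read_csv(tmp_path / "trend.csv")
        assert len(daily) == len(trend.grid_dates)

    def test_constants_echoed_in_header(self, processed, tmp_path):
        _, _, table, _ = run_two_stage(processed)
        render_table(table, tmp_path / "t.csv")
        head = (tmp_path / "t.csv").read_text().splitlines()[:4]
        assert any("ocean_area_km2=361900000" in ln for ln in head)
        assert any("particle_mass_g=0.0136" in ln for ln in head)


class TestPipelineProperties:
    def test_scale_equivariance(self, processed):
        """Multiplying every concentration by k multiplies the whole annual
        table by k (to 1%, after refitting)."""
        _, _, base, _ = run_two_stage(processed)
        scaled = processed.copy()
        scaled["concentration"] = scaled["concentration"] * 3.0
        _, _, tab3, _ = run_two_stage(scaled)
        assert np.allclose(tab3["count_mean"], 3.0 * base["count_mean"], rtol=0.01)

    def test_joint_model_within_two_stage_band(self, processed):
        """A single combined smooth model stays inside the two-stage model's
        2 SE band for the vast majority of years (the decomposition and the
        joint fit tell the same temporal story)."""
        inputs = prepare_model_input(processed)
        s1 = fit_stage1(inputs)
        trend = fit_stage2(s1.residuals, inputs.time_days)
        grid, joint_t = fit_joint(inputs)
        # compare centered annual means of the two temporal effects
        years = trend.grid_dates.year
        df = pd.DataFrame({"year": years,
                           "two_stage": trend.r_hat,
                           "joint": joint_t,
                           "se": trend.se})
        ann = df.groupby("year").mean()
        two = ann.two_stage - ann.two_stage.mean()
        joint = ann.joint - ann.joint.mean()
        inside = (np.abs(two - joint) <= 2 * ann.se).mean()
        assert inside >= 0.9


def test_mean_concentration_methods(rng):
    inputs = synthetic_inputs(rng, n=300)
    arith = mean_concentration(inputs)
    assert arith == pytest.approx(inputs.concentration.mean())
    weights = {b: 1.0 / 3 for b in BASINS}
    weighted = mean_concentration(inputs, method="basin_area", basin_weights=weights)
    assert weighted > 0
    with pytest.raises(ModelError):
        mean_concentration(inputs, method="nope")
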