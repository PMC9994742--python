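"""Synthetic survey campaigns with the statistical structure the model assumes.

The generator exists so that every pipeline stage — ingestion, wind
correction, basin covariates, censored imputation, the two-stage trend —
can be exercised and its parameter recovery measured without any external
download. It emulates, per station:

* six-basin spatial structure with basin-specific log-mean concentrations;
* a shared static spatial pattern through the synthetic expected field
  (``field_coef`` log-units per z-unit), plus iid lognormal station noise;
* a multiplicative temporal trend ``m(t)`` (flat, log-linear, or a
  piecewise stagnation-then-rise shape);
* wind-dependent surface depletion: the *observable* concentration is the
  true one divided by the same mixing factor the pipeline later applies,
  with winds drawn Rayleigh per basin;
* Poisson catch sampling over the swept area, which produces true zero
  catches at low concentrations — the censored records the ROS step must
  handle;
* survey effort that is deliberately uneven across years and basins
  (sparse 1980s, dense 1990s–2015, sparse afterwards; northern basins
  heavily over-represented).

A matching truth table (:func:`true_global_series`) gives the exact annual
global counts implied by the configuration, for recovery tests.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field as dc_field
from typing import Callable

import numpy as np
import pandas as pd

from .constants import FIRST_YEAR, LAST_YEAR, OCEAN_AREA_KM2, PARTICLE_MASS_G
from .exceptions import ConfigError
from .spatial_reference import (
    Basin,
    BasinPolygons,
    ExpectedField,
    scale_center_by_basin,
)
from .wind_correction import WindCorrectionParams, mixing_factor

__all__ = [
    "SimulationConfig",
    "synthetic_expected_field",
    "default_station_allocation",
    "trend_flat",
    "trend_loglinear",
    "trend_piecewise",
    "default_trend",
    "simulate_campaign",
    "true_global_series",
]

#: Survey-effort profile, stations per year 1979..2019 (uneven on purpose:
#: a handful of 1980s cruises, dense coverage 1990-2015, little after).
YEAR_EFFORT = (
    4, 0, 0, 0, 0, 0, 6, 18, 79, 4, 70,
    52, 118, 206, 144, 129, 139, 162, 155, 165, 141,
    177, 186, 170, 164, 155, 194, 202, 185, 176, 224,
    268, 354, 279, 146, 108, 91, 2, 27, 0, 8,
)

#: Share of each year's stations by basin (northern basins dominate).
BASIN_SHARES = {
    Basin.NORTH_ATLANTIC.value: 0.33,
    Basin.NORTH_PACIFIC.value: 0.34,
    Basin.SOUTH_ATLANTIC.value: 0.06,
    Basin.SOUTH_PACIFIC.value: 0.09,
    Basin.INDIAN.value: 0.10,
    Basin.MEDITERRANEAN.value: 0.08,
}

#: Basin log-mean true concentrations (log pieces km^-2), gyre-rich basins
#: slightly higher. Chosen so the station-weighted and area-weighted global
#: means nearly coincide, i.e. the campaign is spatially unbalanced in
#: effort but approximately representative in level (see docs/methods.md).
BASIN_LOG_MEAN = {
    Basin.NORTH_ATLANTIC.value: 10.20,
    Basin.NORTH_PACIFIC.value: 10.30,
    Basin.SOUTH_ATLANTIC.value: 10.20,
    Basin.SOUTH_PACIFIC.value: 10.30,
    Basin.INDIAN.value: 10.30,
    Basin.MEDITERRANEAN.value: 10.40,
}

_GYRES = (
    # (lat, lon, amplitude, radius_deg) of subtropical-gyre maxima
    (30.0, -140.0, 3.0, 18.0),
    (28.0, -45.0, 2.8, 15.0),
    (-30.0, -110.0, 2.2, 18.0),
    (-30.0, -15.0, 2.0, 15.0),
    (-30.0, 80.0, 2.2, 16.0),
    (36.0, 18.0, 1.5, 8.0),
)


def synthetic_expected_field(seed: int = 0, resolution: float = 1.0) -> ExpectedField:
    """A synthetic, clearly non-physical stand-in expected-concentration field.

    Subtropical-gyre Gaussian maxima over a small smooth random background;
    every cell is ocean (no land mask). It shares the interface of a real
    1° modeled concentration surface but none of its physics — use it for
    tests and simulations only.
    """
    rng = np.random.default_rng(seed)
    lats = np.arange(-90 + resolution / 2, 90, resolution)
    lons = np.arange(-180 + resolution / 2, 180, resolution)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    values = np.full(glat.shape, 0.2)
    for lat0, lon0, amp, rad in _GYRES:
        dlon = (glon - lon0 + 180.0) % 360.0 - 180.0
        d2 = (glat - lat0) ** 2 + dlon ** 2
        values += amp * np.exp(-d2 / (2.0 * rad ** 2))
    # smooth low-amplitude background so no basin is degenerate
    for _ in range(6):
        lat0 = rng.uniform(-60, 60)
        lon0 = rng.uniform(-180, 180)
        dlon = (glon - lon0 + 180.0) % 360.0 - 180.0
        values += 0.3 * np.exp(-((glat - lat0) ** 2 + dlon ** 2) / (2 * 25.0 ** 2))
    values += rng.normal(0.0, 0.02, size=values.shape)
    polygons = BasinPolygons.default()
    codes = polygons.assign_many(glat.ravel(), glon.ravel()).reshape(values.shape)
    return ExpectedField(lats, lons, values, codes.astype(np.int8), scaled=False)


def default_station_allocation(effort=YEAR_EFFORT,
                               basin_shares=None) -> dict:
    """Deterministic (year, basin) -> station count map from the effort profile."""
    basin_shares = basin_shares or BASIN_SHARES
    alloc = {}
    for year, n in zip(range(FIRST_YEAR, LAST_YEAR + 1), effort):
        if n == 0:
            continue
        given = 0
        items = list(basin_shares.items())
        for b, share in items[1:]:
            nb = int(round(n * share))
            if nb:
                alloc[(year, b)] = nb
            given += nb
        first_b = items[0][0]
        if n - given > 0:
            alloc[(year, first_b)] = n - given
    return alloc


def trend_flat() -> Callable[[np.ndarray], np.ndarray]:
    """No temporal change: m(t) = 1."""
    return lambda year_frac: np.ones_like(np.asarray(year_frac, dtype=float))


def trend_loglinear(log_change_per_decade: float) -> Callable:
    """Exponential trend: m doubles per decade at log_change = ln 2."""
    def m(year_frac):
        yf = np.asarray(year_frac, dtype=float)
        return np.exp(log_change_per_decade * (yf - FIRST_YEAR) / 10.0)
    return m


def trend_piecewise(knot_years, knot_log_m) -> Callable:
    """Piecewise-linear log trend through (year, log m) knots."""
    ky = np.asarray(knot_years, dtype=float)
    kv = np.asarray(knot_log_m, dtype=float)
    def m(year_frac):
        yf = np.asarray(year_frac, dtype=float)
        return np.exp(np.interp(yf, ky, kv))
    return m


def default_trend() -> Callable:
    """Stagnation-then-rise: mild 1980s–90s fluctuation, a dip around 2004,
    then a steady rise to roughly 4.5x the dip by 2019."""
    return trend_piecewise(
        (1979.0, 1988.0, 1996.0, 2004.0, 2019.0),
        (0.0, 0.10, 0.25, -0.60, 0.90),
    )


@dataclass
class SimulationConfig:
    """Everything that defines one synthetic campaign."""

    seed: int = 17
    first_year: int = FIRST_YEAR
    last_year: int = LAST_YEAR
    station_allocation: dict = dc_field(default_factory=default_station_allocation)
    basin_log_mean: dict = dc_field(default_factory=lambda: dict(BASIN_LOG_MEAN))
    spatial_sd: float = 1.2
    field_coef: float = 1.0
    trend_fn: Callable = dc_field(default_factory=default_trend)
    wind_rayleigh_scale: dict = dc_field(
        default_factory=lambda: {b.value: 6.0 for b in Basin})
    tow_width_choices: tuple = (0.5, 0.6, 1.0)
    tow_width_probs: tuple = (0.2, 0.6, 0.2)
    tow_distance_log_median: float = float(np.log(1000.0))  # metres
    tow_distance_log_sd: float = 0.5
    mesh_menu: dict = dc_field(
        default_factory=lambda: {53.0: 0.002, 200.0: 0.025, 333.0: 0.948, 505.0: 0.025})
    field_seed: int = 0
    #: wind parameters used by the *generator*; set differently from the
    #: pipeline's to study mis-specified wind correction.
    gen_wind_params: WindCorrectionParams = dc_field(default_factory=WindCorrectionParams)

    def validate(self) -> None:
        if self.spatial_sd <= 0 or self.tow_distance_log_sd <= 0:
            raise ConfigError("all standard deviations must be > 0")
        yf = np.linspace(self.first_year, self.last_year + 1, 500)
        if np.any(self.trend_fn(yf) <= 0):
            raise ConfigError("trend function m(t) must be strictly positive")
        if abs(sum(self.mesh_menu.values()) - 1.0) > 1e-9:
            raise ConfigError("mesh_menu probabilities must sum to 1")
        if abs(sum(self.tow_width_probs) - 1.0) > 1e-9:
            raise ConfigError("tow_width_probs must sum to 1")
        for (year, basin), n in self.station_allocation.items():
            if n < 0 or basin not in self.basin_log_mean:
                raise ConfigError(f"bad allocation entry {(year, basin, n)}")


def _basin_cells(field: ExpectedField, code: int):
    """Ocean-cell indices of a basin and their cos-latitude weights."""
    mask = (field.basin_codes == code) & np.isfinite(field.values)
    ii, jj = np.nonzero(mask)
    w = np.cos(np.deg2rad(field.lat_centers[ii]))
    return ii, jj, w / w.sum()


def simulate_campaign(config: SimulationConfig,
                      field: ExpectedField | None = None):
    """Generate one campaign: a station table plus a per-station truth table.

    The station table follows the :mod:`plastrend.station_io` CSV schema.
    The truth table records each station's true surface concentration, the
    trend value m(t) and the field z-value that produced it.
    """
    config.validate()
    raw_field = field if field is not None else synthetic_expected_field(config.field_seed)
    sfield = raw_field if raw_field.scaled else scale_center_by_basin(raw_field)
    res = sfield.resolution

    cells = {b.value: _basin_cells(sfield, b.code) for b in Basin}
    rows, truth_rows = [], []
    sid = 0
    for (year, basin), n in sorted(config.station_allocation.items()):
        # one child generator per (year, basin) group: draws in one group do
        # not shift any other group's stream, so campaigns differing in one
        # knob stay pairwise comparable
        rng = np.random.default_rng([config.seed, year, Basin(basin).code])
        ii, jj, w = cells[basin]
        if ii.size == 0:
            raise ConfigError(f"basin {basin} has no ocean cells in the field")
        pick = rng.choice(ii.size, size=n, p=w)
        lat = sfield.lat_centers[ii[pick]] + rng.uniform(-res / 2, res / 2, n)
        lon = sfield.lon_centers[jj[pick]] + rng.uniform(-res / 2, res / 2, n)
        lat = np.clip(lat, -89.999, 89.999)
        z = sfield.values[ii[pick], jj[pick]]
        doy = rng.integers(1, 366, size=n)
        year_frac = year + (doy - 0.5) / 365.0
        m_t = config.trend_fn(year_frac)
        log_c = (config.basin_log_mean[basin] + config.field_coef * z
                 + rng.normal(0.0, config.spatial_sd, n) + np.log(m_t))
        u10 = rng.rayleigh(config.wind_rayleigh_scale[basin], n)
        factor = mixing_factor(u10, config.gen_wind_params)
        c_obs = np.exp(log_c) / factor
        width = rng.choice(config.tow_width_choices, size=n, p=config.tow_width_probs)
        distance = np.exp(rng.normal(config.tow_distance_log_median,
                                     config.tow_distance_log_sd, n))
        area = width * distance / 1e6
        catch = rng.poisson(c_obs * area)
        mesh = rng.choice(list(config.mesh_menu.keys()), size=n,
                          p=list(config.mesh_menu.values()))
        dates = [dt.date(year, 1, 1) + dt.timedelta(days=int(d) - 1) for d in doy]
        for k in range(n):
            rows.append({
                "station_id": f"SYN-{sid:06d}",
                "date": dates[k].isoformat(),
                "latitude": round(float(lat[k]), 6),
                "longitude": round(float(lon[k]), 6),
                "particle_count": int(catch[k]),
                "tow_width_m": float(width[k]),
                "tow_distance_m": round(float(distance[k]), 3),
                "mesh_size_um": float(mesh[k]),
                "net_opening_m": float(width[k]),
                "wind_speed_u10_ms": round(float(u10[k]), 4),
                "source": "synthetic",
            })
            truth_rows.append({
                "station_id": f"SYN-{sid:06d}",
                "basin": basin,
                "true_concentration": float(np.exp(log_c[k])),
                "trend_m": float(m_t[k]),
                "expected_z": float(z[k]),
                "wind_factor": float(factor[k]),
            })
            sid += 1
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def true_global_series(config: SimulationConfig,
                       field: ExpectedField | None = None) -> pd.DataFrame:
    """Exact annual global truth implied by a configuration.

    Per basin the grid-mean true concentration is
    ``exp(mu_b + sd^2/2) * mean_cells(exp(coef * z)) * mean_days(m(t))``;
    basins combine with cos-latitude ocean-area weights, then scale by the
    global ocean area. Counts in trillion particles, mass in million tonnes
    (same per-particle mass constant as the pipeline).
    """
    config.validate()
    raw_field = field if field is not None else synthetic_expected_field(config.field_seed)
    sfield = raw_field if raw_field.scaled else scale_center_by_basin(raw_field)

    gz, areaw = {}, {}
    total_w = 0.0
    for b in Basin:
        mask = (sfield.basin_codes == b.code) & np.isfinite(sfield.values)
        ii, _ = np.nonzero(mask), None
        coslat = np.cos(np.deg2rad(sfield.lat_centers))[:, None] * np.ones_like(sfield.values)
        wsum = float(coslat[mask].sum())
        areaw[b.value] = wsum
        total_w += wsum
        gz[b.value] = float(np.average(np.exp(config.field_coef * sfield.values[mask]),
                                       weights=coslat[mask]))
    rows = []
    for year in range(config.first_year, config.last_year + 1):
        doy = np.arange(1, 366)
        m_bar = float(np.mean(config.trend_fn(year + (doy - 0.5) / 365.0)))
        conc = 0.0
        for b in Basin:
            mu = config.basin_log_mean[b.value]
            conc += (areaw[b.value] / total_w) * np.exp(mu + config.spatial_sd ** 2 / 2.0) \
                * gz[b.value] * m_bar
        count_tr = conc * OCEAN_AREA_KM2 / 1e12
        rows.append({
            "year": year,
            "true_concentration": conc,
            "count_trillions": count_tr,
            "mass_million_tonnes": count_tr * 1e12 * PARTICLE_MASS_G / 1e12,
        })
    return pd.DataFrame(rows)
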