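"""Read, validate, filter and standardize surface net-tow station records.

A *station* is one surface net tow: where and when it happened, how the sea
surface was swept (trawl aperture width x tow distance, or a precomputed
swept area), and how many plastic particles were caught. Concentration is
areal: particles caught divided by the swept area, in pieces km^-2.

A zero catch is not a true zero — it means the concentration was below the
smallest observable value for that tow, 1 / swept_area. Such records are
flagged ``censored`` and carry a ``detection_limit`` instead of a
concentration; downstream imputation (see :mod:`plastrend.censoring`)
replaces them with estimated values.

CSV schema (UTF-8, header row). Mandatory columns:

    station_id, latitude, longitude, particle_count, mesh_size_um, source

plus a date — either a ``date`` column (ISO ``YYYY-MM-DD``) or ``year`` and
``month`` columns (day imputed as the 15th) — and a resolvable geometry:
either ``swept_area_km2`` or both ``tow_width_m`` and ``tow_distance_m``
(``tow_width_m`` is the aperture dimension transverse to the tow direction).
Optional columns: ``day``, ``net_opening_m``, ``wind_speed_u10_ms``.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import FIRST_YEAR, LAST_YEAR
from .exceptions import (
    InvalidDateError,
    InvalidGeometryError,
    MissingGeometryError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "MANDATORY_COLUMNS",
    "MESH_MIN_UM",
    "MESH_MAX_UM",
    "compute_swept_area",
    "compute_concentration",
    "add_concentrations",
    "filter_mesh",
    "MeshFilterReport",
    "impute_day",
    "normalize_longitude",
    "read_stations",
    "write_stations",
]

MANDATORY_COLUMNS = (
    "station_id",
    "latitude",
    "longitude",
    "particle_count",
    "mesh_size_um",
    "source",
)

#: Inclusive lower-mesh-size window retained by the standard filter (µm).
MESH_MIN_UM = 53.0
MESH_MAX_UM = 505.0

M2_PER_KM2 = 1e6


def compute_swept_area(tow_width_m: float, tow_distance_m: float) -> float:
    """Swept sea-surface area of one tow, in km².

    ``tow_width_m`` is the net aperture width transverse to the tow
    direction; ``tow_distance_m`` the distance towed.
    """
    if not (tow_width_m > 0):
        raise InvalidGeometryError(f"tow width must be > 0 m, got {tow_width_m}")
    if not (tow_distance_m > 0):
        raise InvalidGeometryError(f"tow distance must be > 0 m, got {tow_distance_m}")
    return tow_width_m * tow_distance_m / M2_PER_KM2


def _resolve_area(swept_area_km2, tow_width_m, tow_distance_m) -> float:
    if swept_area_km2 is not None and np.isfinite(swept_area_km2):
        if swept_area_km2 <= 0:
            raise InvalidGeometryError(f"swept area must be > 0 km², got {swept_area_km2}")
        return float(swept_area_km2)
    if (tow_width_m is not None and np.isfinite(tow_width_m)
            and tow_distance_m is not None and np.isfinite(tow_distance_m)):
        return compute_swept_area(float(tow_width_m), float(tow_distance_m))
    raise MissingGeometryError(
        "record has neither swept_area_km2 nor a (tow_width_m, tow_distance_m) pair"
    )


def compute_concentration(particle_count: int, swept_area_km2=None,
                          tow_width_m=None, tow_distance_m=None):
    """Concentration of one record: ``(concentration, censored, detection_limit)``.

    A positive catch gives ``count / area`` (pieces km^-2) and no detection
    limit; a zero catch is censored with detection limit ``1 / area`` and no
    concentration (NaN, to be imputed downstream).
    """
    if particle_count < 0 or int(particle_count) != particle_count:
        raise ValidationError([(0, f"particle_count must be a non-negative integer, got {particle_count}")])
    area = _resolve_area(swept_area_km2, tow_width_m, tow_distance_m)
    if particle_count == 0:
        return np.nan, True, 1.0 / area
    return particle_count / area, False, np.nan


def add_concentrations(stations: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`compute_concentration` over a station table.

    Adds ``swept_area_km2`` (resolved), ``concentration``, ``censored`` and
    ``detection_limit`` columns; input table is not modified.
    """
    df = stations.copy()
    width = df.get("tow_width_m", pd.Series(np.nan, index=df.index)).astype(float)
    dist = df.get("tow_distance_m", pd.Series(np.nan, index=df.index)).astype(float)
    area = df.get("swept_area_km2", pd.Series(np.nan, index=df.index)).astype(float)

    from_dims = area.isna() & width.notna() & dist.notna()
    bad_dims = from_dims & ((width <= 0) | (dist <= 0))
    if bad_dims.any():
        raise InvalidGeometryError(
            f"{int(bad_dims.sum())} record(s) with non-positive tow width/distance"
        )
    area = area.where(~from_dims, width * dist / M2_PER_KM2)
    if area.isna().any():
        n = int(area.isna().sum())
        raise MissingGeometryError(f"{n} record(s) with unresolvable swept area")
    if (area <= 0).any():
        raise InvalidGeometryError("non-positive swept area")

    count = df["particle_count"].astype(float)
    censored = count == 0
    df["swept_area_km2"] = area
    df["concentration"] = np.where(censored, np.nan, count / area)
    df["censored"] = censored
    df["detection_limit"] = np.where(censored, 1.0 / area, np.nan)
    return df


@dataclass(frozen=True)
class MeshFilterReport:
    """What the mesh-size filter kept and dropped."""

    n_input: int
    n_kept: int
    min_um: float
    max_um: float

    @property
    def n_dropped(self) -> int:
        return self.n_input - self.n_kept

    @property
    def kept_share_pct(self) -> float:
        """Percentage of input records kept, one-decimal rounding."""
        if self.n_input == 0:
            return 0.0
        return round(100.0 * self.n_kept / self.n_input, 1)


def filter_mesh(stations: pd.DataFrame, min_um: float = MESH_MIN_UM,
                max_um: float = MESH_MAX_UM):
    """Keep records whose lower mesh size lies in [min_um, max_um] (inclusive).

    Returns ``(filtered_table, MeshFilterReport)``. Nets with meshes outside
    the window retain a non-comparable particle-size fraction, so they are
    excluded from the trend analysis.
    """
    mesh = stations["mesh_size_um"].astype(float)
    keep = (mesh >= min_um) & (mesh <= max_um)
    report = MeshFilterReport(
        n_input=len(stations), n_kept=int(keep.sum()), min_um=min_um, max_um=max_um
    )
    return stations.loc[keep].copy(), report


def mesh_share_pct(n_mesh: int, n_total: int) -> float:
    """Share of stations using a given mesh, as a percentage at one decimal."""
    if n_total <= 0:
        raise ValidationError([(0, "n_total must be positive")])
    return round(100.0 * n_mesh / n_total, 1)


def impute_day(year: int, month: int) -> dt.date:
    """Mid-month date for records reported only to year+month precision."""
    if not 1 <= month <= 12:
        raise InvalidDateError(f"month must be in 1..12, got {month}")
    return dt.date(int(year), int(month), 15)


def normalize_longitude(lon):
    """Map longitudes into [-180, 180)."""
    return ((np.asarray(lon, dtype=float) + 180.0) % 360.0) - 180.0


def _parse_dates(df: pd.DataFrame, errors: list) -> pd.Series:
    if "date" in df.columns:
        parsed = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
        for idx in df.index[parsed.isna()]:
            errors.append((idx + 2, f"unparseable date {df.at[idx, 'date']!r}"))
        return parsed
    if "year" in df.columns and "month" in df.columns:
        out = pd.Series(pd.NaT, index=df.index, dtype="datetime64[ns]")
        day = df["day"] if "day" in df.columns else pd.Series(np.nan, index=df.index)
        for idx in df.index:
            try:
                y, m = int(df.at[idx, "year"]), int(df.at[idx, "month"])
                d = day.iloc[df.index.get_loc(idx)]
                if pd.isna(d):
                    out.at[idx] = pd.Timestamp(impute_day(y, m))
                else:
                    out.at[idx] = pd.Timestamp(year=y, month=m, day=int(d))
            except (ValueError, InvalidDateError) as exc:
                errors.append((idx + 2, f"invalid date fields: {exc}"))
        return out
    raise SchemaError(["date (or year+month)"])


def read_stations(path) -> pd.DataFrame:
    """Read and validate a station CSV.

    Raises :class:`SchemaError` when mandatory columns are missing and
    :class:`ValidationError` listing every malformed row with its physical
    line number (header = line 1); malformed rows are never silently
    dropped. Longitudes are normalized to [-180, 180); dates outside the
    1979–2019 analysis window are flagged in ``date_out_of_window`` (and a
    warning emitted) but retained — the trend model chooses its own window.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    has_geom = ("swept_area_km2" in df.columns
                or ("tow_width_m" in df.columns and "tow_distance_m" in df.columns))
    if not has_geom:
        missing.append("swept_area_km2 (or tow_width_m+tow_distance_m)")
    if "date" not in df.columns and not {"year", "month"} <= set(df.columns):
        missing.append("date (or year+month)")
    if missing:
        raise SchemaError(missing)

    errors: list = []
    df = df.reset_index(drop=True)
    dates = _parse_dates(df, errors)

    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    count = pd.to_numeric(df["particle_count"], errors="coerce")
    mesh = pd.to_numeric(df["mesh_size_um"], errors="coerce")
    for idx in df.index:
        ln = idx + 2  # header occupies line 1
        if pd.isna(lat.iloc[idx]) or not -90 <= lat.iloc[idx] <= 90:
            errors.append((ln, f"latitude out of [-90, 90]: {df.at[idx, 'latitude']!r}"))
        if pd.isna(lon.iloc[idx]):
            errors.append((ln, f"unparseable longitude: {df.at[idx, 'longitude']!r}"))
        c = count.iloc[idx]
        if pd.isna(c) or c < 0 or c != int(c):
            errors.append((ln, f"particle_count must be a non-negative integer: {df.at[idx, 'particle_count']!r}"))
        if pd.isna(mesh.iloc[idx]) or mesh.iloc[idx] <= 0:
            errors.append((ln, f"mesh_size_um must be > 0: {df.at[idx, 'mesh_size_um']!r}"))
    if errors:
        raise ValidationError(sorted(set(errors)))

    df["latitude"] = lat
    df["longitude"] = normalize_longitude(lon)
    df["particle_count"] = count.astype(int)
    df["mesh_size_um"] = mesh
    df["date"] = dates.dt.date
    window = ((dates >= pd.Timestamp(FIRST_YEAR, 1, 1))
              & (dates <= pd.Timestamp(LAST_YEAR, 12, 31)))
    df["date_out_of_window"] = ~window
    if df["date_out_of_window"].any():
        warnings.warn(
            f"{int(df['date_out_of_window'].sum())} record(s) dated outside "
            f"{FIRST_YEAR}-01-01..{LAST_YEAR}-12-31 (flagged, retained)",
            stacklevel=2,
        )
    return df


def write_stations(stations: pd.DataFrame, path) -> None:
    """Write a station table as CSV (dates in ISO format, full float precision)."""
    df = stations.copy()
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)
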