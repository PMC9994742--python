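"""Ocean-basin assignment and the per-basin scaled expected-concentration field.

Surface-plastic surveys are spatially biased: ships sample gyre centres and
coastal waters far more often than the open southern oceans. To correct for
that, every station is (a) assigned to one of six ocean basins and (b) given
the value of a static *expected-concentration field* — a 1°-resolution
modeled surface of relative plastic concentration — at its position. The
field is centered and scaled (z-scored) **within each basin** so it acts as
a stable, time-free spatial reference: a station's covariate says "how rich
is this spot relative to its basin", independent of when it was sampled.

The basin partition ships as an editable GeoJSON polygon file (see
``data/basins.geojson``); the packaged boundaries are deliberately simple
(equator splits, fixed meridians, a Mediterranean priority box). Any
user-supplied 1° grid in long CSV form (lat, lon, value) can stand in for
the expected field.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape

from .exceptions import (
    BasinAssignmentError,
    DegenerateBasinError,
    FieldLookupError,
    FieldStateError,
)

__all__ = [
    "Basin",
    "BasinPolygons",
    "ExpectedField",
    "assign_basin",
    "scale_center_by_basin",
    "lookup_expected",
    "attach_spatial",
    "basin_area_weights",
]

logger = logging.getLogger(__name__)


class Basin(str, Enum):
    """The six ocean basins of the analysis."""

    NORTH_ATLANTIC = "NorthAtlantic"
    SOUTH_ATLANTIC = "SouthAtlantic"
    NORTH_PACIFIC = "NorthPacific"
    SOUTH_PACIFIC = "SouthPacific"
    INDIAN = "Indian"
    MEDITERRANEAN = "Mediterranean"

    @property
    def code(self) -> int:
        return list(Basin).index(self)

    @classmethod
    def from_code(cls, code: int) -> "Basin":
        return list(cls)[code]


class BasinPolygons:
    """Priority-ordered basin polygons with deterministic point assignment."""

    def __init__(self, named_polygons):
        # named_polygons: list of (Basin, shapely geometry), in priority order
        self.items = list(named_polygons)
        for _, geom in self.items:
            shapely.prepare(geom)

    @classmethod
    def default(cls) -> "BasinPolygons":
        with resources.files("plastrend.data").joinpath("basins.geojson").open() as fh:
            return cls.from_geojson(json.load(fh))

    @classmethod
    def from_geojson(cls, obj) -> "BasinPolygons":
        if isinstance(obj, (str, bytes)):
            obj = json.loads(obj)
        feats = sorted(obj["features"], key=lambda f: f["properties"].get("priority", 0))
        return cls([(Basin(f["properties"]["basin"]), shape(f["geometry"])) for f in feats])

    @classmethod
    def from_file(cls, path) -> "BasinPolygons":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))

    def assign_many(self, lats, lons, fallback_nearest: bool = True) -> np.ndarray:
        """Basin codes for arrays of points; -1 only if unassignable.

        Points covered by no polygon (enclosed seas outside the partition)
        are assigned to the nearest basin when ``fallback_nearest`` is set,
        with a log entry; otherwise they raise.
        """
        lats = np.asarray(lats, dtype=float)
        lons = np.asarray(lons, dtype=float)
        pts = shapely.points(lons, lats)
        codes = np.full(lats.shape, -1, dtype=np.int8)
        for basin, geom in self.items:
            mask = (codes == -1) & shapely.covers(geom, pts)
            codes[mask] = basin.code
        unassigned = codes == -1
        if unassigned.any():
            if not fallback_nearest:
                raise BasinAssignmentError(
                    f"{int(unassigned.sum())} point(s) outside every basin polygon"
                )
            idx = np.nonzero(unassigned)[0]
            for i in idx:
                dists = [geom.distance(pts[i]) for _, geom in self.items]
                codes[i] = self.items[int(np.argmin(dists))][0].code
            logger.info("%d point(s) assigned to nearest basin (outside all polygons)",
                        idx.size)
        return codes

    def assign(self, latitude: float, longitude: float) -> Basin:
        code = int(self.assign_many([latitude], [longitude])[0])
        return Basin.from_code(code)


def assign_basin(latitude, longitude, polygons: BasinPolygons | None = None) -> Basin:
    """Assign one station position to its ocean basin."""
    polygons = polygons or BasinPolygons.default()
    if not -90 <= latitude <= 90:
        raise BasinAssignmentError(f"latitude out of range: {latitude}")
    return polygons.assign(latitude, longitude)


@dataclass(frozen=True)
class ExpectedField:
    """A 1° (or other resolution) gridded relative-concentration surface.

    Cells are square, node-registered at half-integer centers; ``values``
    is (nlat, nlon) with NaN marking land/no-data cells; ``basin_codes``
    holds each cell's :class:`Basin` code (-1 where unassigned).
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    values: np.ndarray
    basin_codes: np.ndarray
    scaled: bool = False

    def __post_init__(self):
        nlat, nlon = self.values.shape
        if self.lat_centers.shape != (nlat,) or self.lon_centers.shape != (nlon,):
            raise FieldStateError("grid axes do not match value array shape")

    @property
    def resolution(self) -> float:
        return float(np.diff(self.lat_centers).mean()) if self.lat_centers.size > 1 else 1.0

    @classmethod
    def from_long_csv(cls, path, polygons: BasinPolygons | None = None) -> "ExpectedField":
        """Load a (lat, lon, value) long-format CSV onto a regular grid."""
        df = pd.read_csv(path)
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        values = np.full((lats.size, lons.size), np.nan)
        li = np.searchsorted(lats, df["lat"].to_numpy())
        lj = np.searchsorted(lons, df["lon"].to_numpy())
        values[li, lj] = df["value"].to_numpy()
        polygons = polygons or BasinPolygons.default()
        glat, glon = np.meshgrid(lats, lons, indexing="ij")
        codes = polygons.assign_many(glat.ravel(), glon.ravel()).reshape(values.shape)
        codes = np.where(np.isfinite(values), codes, -1).astype(np.int8)
        return cls(lats, lons, values, codes, scaled=False)

    def to_long_csv(self, path) -> None:
        glat, glon = np.meshgrid(self.lat_centers, self.lon_centers, indexing="ij")
        ok = np.isfinite(self.values)
        pd.DataFrame({
            "lat": glat[ok], "lon": glon[ok], "value": self.values[ok],
        }).to_csv(path, index=False)


def scale_center_by_basin(field: ExpectedField) -> ExpectedField:
    """Z-score field values within each basin (mean 0, sd 1 per basin).

    Uses the sample standard deviation (ddof=1). Refuses already-scaled
    fields and basins that are degenerate (fewer than 2 ocean cells or zero
    variance).
    """
    if field.scaled:
        raise FieldStateError("field is already scaled; refusing to scale twice")
    values = field.values.copy()
    ocean = np.isfinite(values)
    for code in np.unique(field.basin_codes[field.basin_codes >= 0]):
        mask = (field.basin_codes == code) & ocean
        n = int(mask.sum())
        if n < 2:
            raise DegenerateBasinError(
                f"basin {Basin.from_code(int(code)).value} has {n} ocean cell(s)"
            )
        mu = values[mask].mean()
        sd = values[mask].std(ddof=1)
        if sd <= 0:
            raise DegenerateBasinError(
                f"basin {Basin.from_code(int(code)).value} has zero variance"
            )
        values[mask] = (values[mask] - mu) / sd
    return replace(field, values=values, scaled=True)


def _cell_indices(field: ExpectedField, lats, lons):
    res = field.resolution
    lat0 = field.lat_centers[0] - res / 2.0
    lon0 = field.lon_centers[0] - res / 2.0
    i = np.clip(np.floor((np.asarray(lats, float) - lat0) / res).astype(int),
                0, field.lat_centers.size - 1)
    j = np.clip(np.floor((np.asarray(lons, float) - lon0) / res).astype(int),
                0, field.lon_centers.size - 1)
    return i, j


def lookup_expected(field: ExpectedField, lats, lons, search_deg: float = 2.0):
    """Field value of the cell containing each point (nearest-ocean fallback).

    The field is piecewise constant: all points in a cell share its value.
    When the containing cell is land/no-data, the nearest ocean cell within
    ``search_deg`` degrees (by great-circle-agnostic center distance, with
    longitude wraparound) is used; beyond that, :class:`FieldLookupError`.
    """
    if not field.scaled:
        raise FieldStateError("expected field must be scaled before lookup")
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    i, j = _cell_indices(field, lats, lons)
    out = field.values[i, j].astype(float)
    missing = np.nonzero(~np.isfinite(out))[0]
    res = field.resolution
    w = int(np.ceil(search_deg / res))
    nlat, nlon = field.values.shape
    for k in missing:
        best, best_d = np.nan, np.inf
        for di in range(-w, w + 1):
            ii = i[k] + di
            if not 0 <= ii < nlat:
                continue
            for dj in range(-w, w + 1):
                jj = (j[k] + dj) % nlon
                v = field.values[ii, jj]
                if not np.isfinite(v):
                    continue
                dlat = field.lat_centers[ii] - lats[k]
                dlon = (field.lon_centers[jj] - lons[k] + 180.0) % 360.0 - 180.0
                d = float(np.hypot(dlat, dlon))
                if d <= search_deg and d < best_d:
                    best, best_d = v, d
        if not np.isfinite(best):
            raise FieldLookupError(
                f"no ocean cell within {search_deg}° of ({lats[k]:.2f}, {lons[k]:.2f})"
            )
        out[k] = best
    return out if out.size > 1 else float(out[0])


def attach_spatial(stations: pd.DataFrame, field: ExpectedField,
                   polygons: BasinPolygons | None = None) -> pd.DataFrame:
    """Add ``basin`` and ``expected_z`` columns to a station table."""
    polygons = polygons or BasinPolygons.default()
    df = stations.copy()
    codes = polygons.assign_many(df["latitude"].to_numpy(), df["longitude"].to_numpy())
    df["basin"] = [Basin.from_code(int(c)).value for c in codes]
    df["expected_z"] = np.atleast_1d(
        lookup_expected(field, df["latitude"].to_numpy(), df["longitude"].to_numpy())
    )
    return df


def basin_area_weights(field: ExpectedField) -> dict:
    """Fraction of total ocean area in each basin (cos-latitude weighted)."""
    ocean = np.isfinite(field.values)
    coslat = np.cos(np.deg2rad(field.lat_centers))[:, None] * np.ones_like(field.values)
    total = float(coslat[ocean].sum())
    out = {}
    for code in np.unique(field.basin_codes[field.basin_codes >= 0]):
        mask = (field.basin_codes == code) & ocean
        out[Basin.from_code(int(code)).value] = float(coslat[mask].sum()) / total
    return out
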