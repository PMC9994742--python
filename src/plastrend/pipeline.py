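"""Single-command orchestration: ingest -> windcorrect -> basin -> impute -> fit.

Every stage reads and writes plain CSV, so any intermediate can be
inspected or re-entered by hand. A run manifest (config snapshot, input
checksums, seed, package version, timestamp) is written *before* results;
re-running with identical config and inputs reproduces ``table1.csv``
bit-identically because every stage is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .censoring import impute_table
from .constants import Constants
from .exceptions import StageError
from .spatial_reference import BasinPolygons, ExpectedField, attach_spatial, basin_area_weights, scale_center_by_basin
from .station_io import add_concentrations, filter_mesh, read_stations, write_stations
from .synthetic_data import synthetic_expected_field
from .trend_model import render_table, render_trend, run_two_stage
from .wind_correction import WindCorrectionParams, correct_table

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of a full pipeline run (mirrors the CLI flags)."""

    stations_csv: str
    out_dir: str
    field_csv: str | None = None        # None -> packaged synthetic field
    boundaries_geojson: str | None = None
    seed: int = 17
    min_mesh_um: float = 53.0
    max_mesh_um: float = 505.0
    wind_params: WindCorrectionParams = field(default_factory=WindCorrectionParams)
    max_censored_frac: float = 0.8
    impute_group_by: str | None = None  # None = pooled globally; "basin" option
    nbasis_stage1: int = 10
    nbasis_stage2: int = 20
    smoothing_method: str = "reml"      # or "gcv"
    family: str = "lognormal"           # or "gamma"
    mean_method: str = "arithmetic"     # or "basin_area"
    constants: Constants = field(default_factory=Constants)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    """Provenance record written before any result file."""

    config: dict
    input_checksums: dict
    seed: int
    version: str
    timestamp: str

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the results directory.

    Any stage failure is re-raised as :class:`StageError` naming the stage.
    Outputs: ``manifest.json`` (first), ``clean.csv``, ``imputed.csv``,
    ``table1.csv``, ``trend_daily.csv``, ``diagnostics.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    import datetime as dt

    checksums = {"stations_csv": _sha256(config.stations_csv)}
    if config.field_csv:
        checksums["field_csv"] = _sha256(config.field_csv)
    manifest = RunManifest(
        config=config.snapshot(),
        input_checksums=checksums,
        seed=config.seed,
        version=__version__,
        timestamp=dt.datetime.now().isoformat(timespec="seconds"),
    )
    manifest.write(out / "manifest.json")

    try:
        stations = read_stations(config.stations_csv)
        stations, mesh_report = filter_mesh(stations, config.min_mesh_um,
                                            config.max_mesh_um)
        stations = add_concentrations(stations)
    except Exception as exc:
        raise StageError("ingest", exc) from exc

    try:
        stations = correct_table(stations, config.wind_params)
    except Exception as exc:
        raise StageError("windcorrect", exc) from exc

    try:
        polygons = (BasinPolygons.from_file(config.boundaries_geojson)
                    if config.boundaries_geojson else BasinPolygons.default())
        if config.field_csv:
            fld = ExpectedField.from_long_csv(config.field_csv, polygons)
        else:
            fld = synthetic_expected_field()
        fld = scale_center_by_basin(fld)
        stations = attach_spatial(stations, fld, polygons)
    except Exception as exc:
        raise StageError("basin", exc) from exc
    write_stations(stations, out / "clean.csv")

    try:
        stations, cens_report = impute_table(
            stations, group_by=config.impute_group_by,
            max_censored_frac=config.max_censored_frac)
    except Exception as exc:
        raise StageError("impute", exc) from exc
    write_stations(stations, out / "imputed.csv")

    try:
        weights = basin_area_weights(fld) if config.mean_method == "basin_area" else None
        stage1, trend, table, diagnostics = run_two_stage(
            stations,
            nbasis_stage1=config.nbasis_stage1,
            nbasis_stage2=config.nbasis_stage2,
            method=config.smoothing_method,
            family=config.family,
            mean_method=config.mean_method,
            basin_weights=weights,
            constants=config.constants,
        )
    except Exception as exc:
        raise StageError("fit", exc) from exc

    render_table(table, out / "table1.csv", constants=config.constants)
    render_trend(trend, out / "trend_daily.csv")
    diagnostics.update({
        "seed": config.seed,
        "mesh_filter": {"n_input": mesh_report.n_input, "n_kept": mesh_report.n_kept},
        "censoring": cens_report,
    })
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2, default=str)
    logger.info("pipeline complete: %d stations -> %s", diagnostics["n_stations"], out)
    return out
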