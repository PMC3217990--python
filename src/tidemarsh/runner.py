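"""Scenario configuration and end-to-end pipeline orchestration.

The pipeline stages are: synthesize the tidal month; build the datum
offset surfaces from gauges (IDW at 100 m, resampled to the elevation
grid); reference the elevation raster to MHHW (with vegetation
correction); build response tables for every subregion (SSC, OM) x SLR
combination; project the raster per scenario and checkpoint; classify
habitat and summarize areas by subregion and land status.

Diked areas are treated as if all barriers to tidal inundation were
removed at the simulation epoch: diked pixels run through the same
projection pathway as tidal ones and are distinguished only in the area
accounting (as restoration potential).  Urban pixels are likewise
projected but reported as un-restorable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, NonNegativeFloat

from . import __version__
from .accretion import (DRY_BULK_DENSITY_DEFAULT, SETTLING_VELOCITY_DEFAULT,
                        DepositionLookup)
from .slr import SLRCurve
from .spatial import (GridSpec, classify_habitat, Grid, idw_surface,
                      navd_to_mhhw, project_grid, rasterize_polygons,
                      read_ascii_grid, resample_bilinear, summarize_areas,
                      vegetation_correction)
from .tables import build_response_table
from .tides import TideConstituent, compute_datums, generate_tidal_month

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "run_scenarios"]


class TideConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    target_range: float = Field(1.8, gt=0)
    duration_days: int = Field(28, ge=28)
    step_hours: float = Field(0.1, gt=0, le=0.5)
    constituents: list[dict] | None = None


class SLRConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    initial_rate: NonNegativeFloat = 0.002
    low_total: NonNegativeFloat = 0.52
    high_total: NonNegativeFloat = 1.65


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    settling_velocity: float = Field(SETTLING_VELOCITY_DEFAULT, gt=0)
    dry_bulk_density: float = Field(DRY_BULK_DENSITY_DEFAULT, gt=0)


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    elevation: str = "elevation_navd88.asc"
    gauges: str = "gauges.csv"
    subregions: str = "subregions.geojson"
    vegetation: str | None = "vegetation.asc"
    diked: str = "diked_mask.asc"
    urban: str = "urban_mask.asc"


class ScenarioConfig(BaseModel):
    """Validated scenario configuration (YAML/JSON); unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    tide: TideConfig = TideConfig()
    slr: SLRConfig = SLRConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    ssc_levels: list[str] = ["low", "high"]
    om_levels: list[str] = ["low", "high"]
    slr_labels: list[str] = ["low", "high"]
    checkpoint_years: list[float] = [0.0, 20.0, 40.0, 60.0, 80.0, 100.0]
    anchor_starts: list[float] = [-2.4, -0.5, 0.0]
    veg_corrections: dict[int, float] = {}
    datum_surface_cell: float = Field(100.0, gt=0)
    input_dir: str = "."
    paths: PathsConfig = PathsConfig()
    seed: int = 0
    outdir: str = "outputs"

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_gauges(path):
    import pandas as pd

    df = pd.read_csv(path)
    pts = df[["x", "y"]].to_numpy(float)
    return pts, df


def _coarse_spec(spec: GridSpec, cell: float) -> GridSpec:
    ncols = max(2, int(np.ceil(spec.ncols * spec.cell / cell)))
    nrows = max(2, int(np.ceil(spec.nrows * spec.cell / cell)))
    return GridSpec(spec.x0, spec.y0, cell, nrows, ncols)


def reference_to_mhhw(elev_navd, gauges_df, spec_cell: float,
                      veg=None, corrections=None):
    """Datum-reference an elevation raster: vegetation correction, IDW
    offset surfaces at ``spec_cell`` resolution, bilinear resampling, and
    the NAVD88 + MLLW offset - MHHW offset arithmetic."""
    pts = gauges_df[["x", "y"]].to_numpy(float)
    coarse = _coarse_spec(elev_navd.spec, spec_cell)
    mllw_off = resample_bilinear(
        idw_surface(pts, -gauges_df["navd_at_mllw"].to_numpy(float), coarse),
        elev_navd.spec,
    )
    mhhw_off = resample_bilinear(
        idw_surface(pts, gauges_df["mhhw_minus_mllw"].to_numpy(float), coarse),
        elev_navd.spec,
    )
    corrected = elev_navd
    if veg is not None and corrections:
        corrected = vegetation_correction(elev_navd, veg, corrections)
    return navd_to_mhhw(corrected, mllw_off, mhhw_off)


def run_scenarios(config: ScenarioConfig, *, bay=None) -> dict:
    """Execute the full factorial of spatial change scenarios.

    With ``bay`` given (a :class:`~tidemarsh.fixtures.ToyBay`), inputs are
    taken from it directly; otherwise they are read from
    ``config.input_dir``.  Writes, per scenario and checkpoint, the
    projected-elevation and habitat rasters plus an area-summary CSV, and
    a run manifest; returns a summary dict.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    cons = None
    if config.tide.constituents:
        cons = [TideConstituent(**c) for c in config.tide.constituents]
    tide = generate_tidal_month(
        *( (cons,) if cons else () ),
        target_range=config.tide.target_range,
        duration_days=config.tide.duration_days,
        step_hours=config.tide.step_hours,
    )
    datums = compute_datums(tide)
    curves = {
        "low": SLRCurve("low", config.slr.initial_rate, config.slr.low_total),
        "high": SLRCurve("high", config.slr.initial_rate,
                         config.slr.high_total),
    }
    w_s = config.calibration.settling_velocity
    rho = config.calibration.dry_bulk_density
    lookup = DepositionLookup(tide, w_s)

    # ---- inputs
    if bay is not None:
        elev_navd, veg, diked, urban = bay.elev_navd, bay.veg, bay.diked, bay.urban
        subregions = bay.subregions
        import pandas as pd

        gauges_df = pd.DataFrame(bay.gauges)
        corrections = bay.veg_corrections
    else:
        import pandas as pd

        indir = Path(config.input_dir)
        p = config.paths
        elev_navd = read_ascii_grid(indir / p.elevation, units="m NAVD88")
        veg = (read_ascii_grid(indir / p.vegetation, units="class")
               if p.vegetation else None)
        diked = read_ascii_grid(indir / p.diked, units="mask")
        urban = read_ascii_grid(indir / p.urban, units="mask")
        from .spatial import read_geojson

        subregions = read_geojson(indir / p.subregions)
        gauges_df = pd.read_csv(indir / p.gauges)
        corrections = config.veg_corrections

    elev_mhhw = reference_to_mhhw(elev_navd, gauges_df,
                                  config.datum_surface_cell, veg, corrections)
    sub_raster = rasterize_polygons(subregions, elev_navd.spec, attr="id")
    attrs = {
        int(f["properties"]["id"]): f["properties"] for f in subregions
    }

    # ---- response tables for every (ssc value, om value, slr) needed
    tables = {}
    scenario_list = [
        (s, o, l)
        for s in config.ssc_levels
        for o in config.om_levels
        for l in config.slr_labels
    ]
    for ssc_level, om_level, slr_label in scenario_list:
        for sid, a in attrs.items():
            key = (a[f"ssc_{ssc_level}"], a[f"om_{om_level}"], slr_label)
            if key not in tables:
                tables[key] = build_response_table(
                    key[0], key[1], curves[slr_label], tide,
                    anchor_starts=config.anchor_starts,
                    settling_velocity=w_s, dry_bulk_density=rho,
                    lookup=lookup, datums=datums,
                )

    # ---- project, classify, summarize
    results = {}
    for ssc_level, om_level, slr_label in scenario_list:
        name = f"ssc-{ssc_level}_om-{om_level}_slr-{slr_label}"
        sdir = out / name
        sdir.mkdir(exist_ok=True)
        mapping = {
            sid: (a[f"ssc_{ssc_level}"], a[f"om_{om_level}"], slr_label)
            for sid, a in attrs.items()
        }
        frames = []
        for t in config.checkpoint_years:
            proj = project_grid(elev_mhhw, sub_raster, mapping, t, tables)
            classes = Grid(
                classify_habitat(proj.values).astype(float),
                proj.spec, units="class",
            )
            classes.values[proj.nodata_mask] = np.nan
            proj.to_ascii(sdir / f"elevation_mhhw_t{int(t):03d}.asc")
            classes.to_ascii(sdir / f"habitat_t{int(t):03d}.asc")
            areas = summarize_areas(classes, sub_raster, diked, urban)
            areas.insert(0, "year", t)
            frames.append(areas)
        import pandas as pd

        area_df = pd.concat(frames, ignore_index=True)
        area_df.to_csv(sdir / "areas.csv", index=False)
        results[name] = area_df

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "tide_datums": {"mhhw": datums.mhhw, "mllw": datums.mllw,
                        "range": datums.range},
        "settling_velocity_m_s": w_s,
        "dry_bulk_density_kg_m3": rho,
        "scenarios": sorted(results),
        "checkpoints": list(config.checkpoint_years),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return results
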