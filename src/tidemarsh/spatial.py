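"""Raster pipeline: datum referencing, per-pixel projection, habitat
classification and area accounting.

Rasters are plain numpy grids with an upper-left-anchored, half-open cell
geometry (:class:`GridSpec`); polygon attribution is by cell-center
containment.  Text I/O uses the ESRI ASCII grid format for rasters and
GeoJSON for vectors, so every artifact in the pipeline is inspectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .util import round_decimeter

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "Grid",
    "HabitatClass",
    "read_ascii_grid",
    "idw_surface",
    "resample_bilinear",
    "navd_to_mhhw",
    "vegetation_correction",
    "project_grid",
    "classify_habitat",
    "summarize_areas",
    "rasterize_polygons",
]


@dataclass(frozen=True)
class GridSpec:
    """Georeference of a raster: upper-left corner, square cells.

    Cell (row, col) covers the half-open box
    ``[x0 + col*cell, x0 + (col+1)*cell) x (y0 - (row+1)*cell, y0 - row*cell]``
    with its center at ``(x0 + (col+0.5)*cell, y0 - (row+0.5)*cell)``.
    """

    x0: float
    y0: float
    cell: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinate arrays, each of shape (nrows, ncols)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.y0 - (np.arange(self.nrows) + 0.5) * self.cell
        return np.meshgrid(xs, ys)


@dataclass
class Grid:
    """A raster: 2-D float array + georeference; NaN is nodata.

    ``units`` records what the values mean (e.g. ``"m NAVD88"``,
    ``"m MHHW"``, ``"class"``).
    """

    values: np.ndarray
    spec: GridSpec
    units: str = "m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}"
            )

    def copy(self, values=None, units=None) -> "Grid":
        return Grid(
            self.values.copy() if values is None else values,
            self.spec,
            self.units if units is None else units,
        )

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def to_ascii(self, path) -> None:
        """Write as an ESRI ASCII grid (text)."""
        s = self.spec
        header = (
            f"ncols {s.ncols}\n"
            f"nrows {s.nrows}\n"
            f"xllcorner {s.x0}\n"
            f"yllcorner {s.y0 - s.nrows * s.cell}\n"
            f"cellsize {s.cell}\n"
            f"NODATA_value -9999\n"
        )
        vals = np.where(np.isfinite(self.values), self.values, -9999.0)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.4f")


def read_ascii_grid(path, units: str = "m") -> Grid:
    """Read an ESRI ASCII grid written by :meth:`Grid.to_ascii`."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    cell = header["cellsize"]
    spec = GridSpec(
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nrows * cell,
        cell=cell,
        nrows=nrows,
        ncols=ncols,
    )
    return Grid(values, spec, units)


# ---------------------------------------------------------------------------
# datum surfaces
# ---------------------------------------------------------------------------


def idw_surface(points, values, spec: GridSpec, power: float = 2.0) -> Grid:
    """Inverse-distance-weighted interpolation of point data to a raster.

    All points contribute to every cell with weight ``d**-power``
    (second-order, i.e. power 2, by default); a cell whose center
    coincides with a point takes that point's value exactly.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.size == 0:
        raise ValueError("empty point set")
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    X, Y = spec.cell_centers()
    dx = X[..., None] - points[:, 0]
    dy = Y[..., None] - points[:, 1]
    d2 = dx * dx + dy * dy
    coincident = d2 <= 1e-18
    with np.errstate(divide="ignore"):
        w = d2 ** (-power / 2.0)
    w[coincident] = 0.0
    out = (w * values).sum(axis=-1) / w.sum(axis=-1).clip(1e-300)
    hit = coincident.any(axis=-1)
    if hit.any():
        out[hit] = values[np.argmax(coincident[hit], axis=-1)]
    return Grid(out, spec, units="m")


def resample_bilinear(src: Grid, spec: GridSpec) -> Grid:
    """Bilinearly resample a raster onto another grid (cell centers),
    extrapolating flatly beyond the source's center extent."""
    from scipy.interpolate import RegularGridInterpolator

    s = src.spec
    xs = s.x0 + (np.arange(s.ncols) + 0.5) * s.cell
    ys = s.y0 - (np.arange(s.nrows) + 0.5) * s.cell  # descending
    interp = RegularGridInterpolator(
        (ys[::-1], xs), src.values[::-1, :],
        bounds_error=False, fill_value=None,
    )
    X, Y = spec.cell_centers()
    # clamp to the source center extent: flat extrapolation at the rim
    Xc = np.clip(X, xs[0], xs[-1])
    Yc = np.clip(Y, ys[-1], ys[0])
    out = interp(np.stack([Yc.ravel(), Xc.ravel()], axis=1)).reshape(spec.shape)
    return Grid(out, spec, units=src.units)


def navd_to_mhhw(elev: Grid, mllw_offset: Grid, mhhw_offset: Grid) -> Grid:
    """Convert a NAVD88 elevation raster to MHHW reference.

    MHHW elevation = NAVD88 elevation + MLLW offset - MHHW offset, where
    ``mllw_offset`` converts NAVD88 to a local MLLW reference (the
    negative of the NAVD88 elevation of local MLLW) and ``mhhw_offset`` is
    the local MHHW-above-MLLW height (the great diurnal range surface).
    Nodata propagates.
    """
    for g in (mllw_offset, mhhw_offset):
        if g.spec != elev.spec:
            raise ValueError("offset grids must be co-registered with elevation")
    out = elev.values + mllw_offset.values - mhhw_offset.values
    return Grid(out, elev.spec, units="m MHHW")


def vegetation_correction(elev: Grid, veg: Grid, corrections: dict) -> Grid:
    """Apply per-vegetation-class additive elevation corrections (m).

    Classes absent from ``corrections`` are left unchanged with a logged
    warning; nodata vegetation pixels are unchanged.
    """
    out = elev.values.copy()
    veg_vals = veg.values
    present = np.unique(veg_vals[np.isfinite(veg_vals)]).astype(int)
    for cls in present:
        mask = veg_vals == cls
        if cls in corrections:
            out[mask] += corrections[cls]
        elif corrections.get(int(cls)) is None and cls != 0:
            logger.warning(
                "vegetation class %d has no correction factor (%d pixels)",
                cls, int(mask.sum()),
            )
    return Grid(out, elev.spec, units=elev.units)


# ---------------------------------------------------------------------------
# habitat classification
# ---------------------------------------------------------------------------


class HabitatClass(IntEnum):
    """Intertidal habitat bands (m MHHW, applied after 10-cm rounding).

    subtidal  < -1.8 | mudflat -1.8..-0.6 | low marsh -0.5..-0.3 |
    mid marsh -0.2..0.1 | high marsh 0.2..0.3 | upland > 0.3
    """

    SUBTIDAL = 1
    MUDFLAT = 2
    LOW_MARSH = 3
    MID_MARSH = 4
    HIGH_MARSH = 5
    UPLAND = 6


def classify_habitat(elev_mhhw):
    """Classify elevation(s) relative to MHHW into habitat bands.

    Elevations are rounded to the nearest 10 cm first, which makes the
    published bands tile the elevation axis exactly.  Scalars return a
    :class:`HabitatClass`; arrays return an integer array of class codes
    (NaN-> 0).
    """
    x = np.asarray(elev_mhhw, dtype=float)
    dm = np.where(np.isfinite(x),
                  np.sign(x) * np.floor(np.abs(x) * 10.0 + 0.5), np.nan)
    out = np.zeros(x.shape, dtype=np.int64)
    with np.errstate(invalid="ignore"):
        out[dm <= -19] = HabitatClass.SUBTIDAL
        out[(dm >= -18) & (dm <= -6)] = HabitatClass.MUDFLAT
        out[(dm >= -5) & (dm <= -3)] = HabitatClass.LOW_MARSH
        out[(dm >= -2) & (dm <= 1)] = HabitatClass.MID_MARSH
        out[(dm >= 2) & (dm <= 3)] = HabitatClass.HIGH_MARSH
        out[dm >= 4] = HabitatClass.UPLAND
    if out.ndim == 0:
        if not np.isfinite(x):
            raise ValueError("cannot classify non-finite elevation")
        return HabitatClass(int(out))
    return out


# ---------------------------------------------------------------------------
# per-pixel scenario projection
# ---------------------------------------------------------------------------


def project_grid(elev_mhhw: Grid, subregion_raster: Grid, scenario: dict,
                 t: float, tables: dict) -> Grid:
    """Project an MHHW-referenced elevation raster to checkpoint ``t``.

    ``subregion_raster`` holds integer subregion ids (NaN = outside);
    ``scenario`` maps subregion id -> response-table key; ``tables`` maps
    those keys to :class:`~tidemarsh.tables.ResponseTable`.  Each pixel is
    snapped to the 10-cm grid and looked up in its subregion's table
    (interpolation inside the domain, boundary rules outside).  Pixels in
    no subregion become nodata, with a logged count.
    """
    from .tables import project_elevation

    out = np.full(elev_mhhw.spec.shape, np.nan)
    sub = subregion_raster.values
    n_unassigned = 0
    for sid in np.unique(sub[np.isfinite(sub)]).astype(int):
        if sid not in scenario:
            raise KeyError(f"subregion {sid} has no scenario attribute")
        table = tables[scenario[sid]]
        mask = (sub == sid) & np.isfinite(elev_mhhw.values)
        if not mask.any():
            continue
        x = round_decimeter(elev_mhhw.values[mask])
        # all pixels sharing a 10-cm start share the projection: build a
        # small per-decimeter map instead of projecting per pixel
        dm = np.round(x * 10).astype(np.int64)
        uniq = np.unique(dm)
        proj = {k: project_elevation(k / 10.0, table, t, snap=False)
                for k in uniq}
        out[mask] = np.vectorize(proj.get)(dm)
    valid_elev = np.isfinite(elev_mhhw.values)
    n_unassigned = int((valid_elev & ~np.isfinite(sub)).sum())
    if n_unassigned:
        logger.warning("%d pixels fall in no subregion (set to nodata)",
                       n_unassigned)
    return Grid(out, elev_mhhw.spec, units="m MHHW")


# ---------------------------------------------------------------------------
# area accounting
# ---------------------------------------------------------------------------


def summarize_areas(class_grid: Grid, subregion_raster: Grid,
                    diked_mask: Grid, urban_mask: Grid):
    """Hectare totals per (subregion, land status, habitat class).

    Land-status precedence is urban > diked > tidal: urbanized pixels are
    un-restorable regardless of dikes.  One 5-m pixel is 0.0025 ha.
    """
    import pandas as pd

    for g in (subregion_raster, diked_mask, urban_mask):
        if g.spec != class_grid.spec:
            raise ValueError("all grids must be co-registered")
    cell_ha = class_grid.spec.cell**2 / 1.0e4
    classes = class_grid.values
    sub = subregion_raster.values
    urban = urban_mask.values > 0
    diked = (diked_mask.values > 0) & ~urban
    tidal = ~urban & ~diked
    status_masks = {"urban": urban, "diked": diked, "tidal": tidal}

    rows = []
    sids = np.unique(sub[np.isfinite(sub)]).astype(int)
    for sid in sids:
        in_sub = sub == sid
        for status, smask in status_masks.items():
            base = in_sub & smask & (classes > 0)
            for hc in HabitatClass:
                n = int((base & (classes == hc)).sum())
                rows.append(
                    {
                        "subregion": sid,
                        "land_status": status,
                        "habitat": hc.name.lower(),
                        "area_ha": n * cell_ha,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# vector handling
# ---------------------------------------------------------------------------


def rasterize_polygons(features, spec: GridSpec, attr: str = "id") -> Grid:
    """Burn polygon features into a raster by cell-center containment.

    ``features`` is a GeoJSON-style feature list (each with ``geometry``
    and ``properties``); later features win where polygons overlap.
    """
    import shapely
    from shapely.geometry import shape

    out = np.full(spec.shape, np.nan)
    X, Y = spec.cell_centers()
    for feat in features:
        geom = shape(feat["geometry"])
        val = float(feat["properties"][attr])
        inside = shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(
            spec.shape
        )
        out[inside] = val
    return Grid(out, spec, units="class")


def write_geojson(features, path) -> None:
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh,
                  indent=1)


def read_geojson(path):
    with open(path) as fh:
        return json.load(fh)["features"]
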