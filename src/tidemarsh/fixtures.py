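"""Synthetic inputs: the calibration threshold fixture and a toy bay.

Nothing here is real data.  The threshold fixture encodes the qualitative
sustainability/restoration statements the scenario study is anchored to,
as machine-checkable constraints for :func:`tidemarsh.accretion.calibrate`.
The toy bay is a fully synthetic small embayment (sloping upland fringe,
marsh plain near MHHW, a subsided diked polygon, a subtidal channel, two
biogeomorphic subregions, several tide gauges) that exercises every stage
of the spatial pipeline with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accretion import CalibrationEntry
from .spatial import Grid, GridSpec

__all__ = [
    "make_threshold_fixture",
    "ToyBaySpec",
    "ToyBay",
    "make_toy_bay",
    "write_fixture_files",
]

_LOW = ("low",)
_HIGH = ("high",)
_BOTH = ("low", "high")
_OMS = (1.0, 2.0, 3.0)
_ALL_SSC = (25.0, 50.0, 100.0, 150.0, 200.0, 250.0, 300.0)
_NEVER = 120.0  # "beyond the horizon" threshold for reach-year constraints


def make_threshold_fixture() -> list[CalibrationEntry]:
    """Qualitative threshold constraints for the (w_s, rho_dry) calibration.

    Mandatory entries are the headline thresholds; the remainder fill in
    the rest of the published sustainability/restoration grids.  Durations
    are sustainability durations (years, 20-yr checkpoints); reach years
    are the first checkpoint a start attains mid-marsh elevation
    (>= -0.2 m MHHW after 10-cm rounding).
    """
    E = CalibrationEntry
    return [
        # --- headline thresholds (mandatory) ---
        E("mid marsh not sustainable a full century at any tested SSC, high SLR",
          "duration", _ALL_SSC, _OMS, _HIGH, (0.0,), "le", 80.0),
        E("subtidal restorable to mid marsh within a century at 250 mg/L, high SLR",
          "reach_year", (250.0,), (0.0,), _HIGH, (-2.4,), "le", 100.0),
        E("subtidal NOT restorable within a century at 200 mg/L, high SLR",
          "reach_year", (200.0,), (0.0,), _HIGH, (-2.4,), "ge", _NEVER),
        E("25 mg/L marshes unsustainable beyond 40 yr under either SLR",
          "duration", (25.0,), _OMS, _BOTH, (-0.5, 0.0), "le", 40.0),
        E("mid marsh at 300 mg/L under high SLR sustained to exactly 80 yr",
          "duration", (300.0,), _OMS, _HIGH, (0.0,), "eq", 80.0),
        E("subtidal reaches mid marsh within 20 yr at 300 mg/L, low SLR",
          "reach_year", (300.0,), (0.0,), _LOW, (-2.4,), "le", 20.0),
        E("widening the tide range to 2.8 m lowers century elevation <= 0.2 m",
          "range_deficit", (150.0, 200.0, 250.0, 300.0), (1.0,), _BOTH,
          (-0.5, 0.0), "le", 0.2),
        E("tide-range elevation deficit stays below 5% of predicted accretion",
          "range_deficit_pct", (150.0, 200.0, 250.0, 300.0), (1.0,), _BOTH,
          (-0.5, 0.0), "le", 5.0, mandatory=False),
        # --- remaining grid statements (diagnostic) ---
        E("50 mg/L, high OM, low SLR sustains low marsh a century",
          "duration", (50.0,), (3.0,), _LOW, (-0.5,), "eq", 100.0,
          mandatory=False),
        E("50 mg/L unsustainable within 20 yr under high SLR, any OM",
          "duration", (50.0,), _OMS, _HIGH, (-0.5, 0.0), "le", 0.0,
          mandatory=False),
        E("100 mg/L, low SLR sustains low marsh a century",
          "duration", (100.0,), _OMS, _LOW, (-0.5,), "eq", 100.0,
          mandatory=False),
        E("100 mg/L, high OM, low SLR: mid marsh lasts to 80 yr",
          "duration", (100.0,), (3.0,), _LOW, (0.0,), "eq", 80.0,
          mandatory=False),
        E("100 mg/L, high SLR: low marsh lost within 40 yr",
          "duration", (100.0,), _OMS, _HIGH, (-0.5,), "le", 20.0,
          mandatory=False),
        E("150 mg/L, low SLR: mid marsh sustained a century even at low OM",
          "duration", (150.0,), (1.0,), _LOW, (0.0,), "eq", 100.0,
          mandatory=False),
        E("150 mg/L, high SLR: low marsh with 2 mm/yr OM is sustainable",
          "duration", (150.0,), (2.0,), _HIGH, (-0.5,), "ge", 20.0,
          mandatory=False),
        E("150 mg/L, high SLR: low marsh with 1 mm/yr OM is not sustainable",
          "duration", (150.0,), (1.0,), _HIGH, (-0.5,), "le", 0.0,
          mandatory=False),
        E("200-250 mg/L, high SLR: mid marsh sustainable for at least 20 yr",
          "duration", (200.0, 250.0), _OMS, _HIGH, (0.0,), "ge", 20.0,
          agg="min", mandatory=False),
        E("subtidal restorable within a century at 150 mg/L, low SLR",
          "reach_year", (150.0,), (0.0,), _LOW, (-2.4,), "le", 100.0,
          mandatory=False),
        E("subtidal restoration at 150 mg/L, low SLR takes close to a century",
          "reach_year", (150.0,), (0.0,), _LOW, (-2.4,), "ge", 80.0,
          mandatory=False),
        E("at 100 mg/L, low SLR, restoration succeeds only from marsh starts",
          "reach_year", (100.0,), (0.0,), _LOW, (-2.4,), "ge", _NEVER,
          mandatory=False),
    ]


# ---------------------------------------------------------------------------
# toy bay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyBaySpec:
    """Parameters of the synthetic toy bay.

    The default domain is 200 x 200 cells of 5 m (1 km^2).  Elevations run
    from subtidal (about -3 m MHHW) in the west to upland (+2 m) in the
    east, with additive Gaussian noise of ``noise_sd`` metres emulating
    the vertical-error scale of airborne lidar.  ``seed`` fully determines
    every output.
    """

    nrows: int = 200
    ncols: int = 200
    cell: float = 5.0
    seed: int = 0
    noise_sd: float = 0.05
    x0: float = 0.0
    y0: float = 1000.0


@dataclass
class ToyBay:
    """Bundle of synthetic pipeline inputs plus known ground truth."""

    elev_navd: Grid            # NAVD88-like elevation, with vegetation bias
    gauges: list               # dicts: x, y, mhhw_minus_mllw, navd_at_mllw
    subregions: list           # GeoJSON features with SSC/OM attributes
    subregion_attrs: dict      # id -> {ssc_low, ssc_high, om_low, om_high}
    veg: Grid                  # vegetation class raster (0 = none)
    veg_corrections: dict      # class -> additive elevation correction (m)
    diked: Grid                # 0/1 mask
    urban: Grid                # 0/1 mask
    truth_mhhw: Grid           # true MHHW-referenced elevation (no bias)
    truth_range: Grid          # true MHHW-MLLW field
    truth_navd_at_mllw: Grid   # true NAVD88 elevation of local MLLW


def _rect(x0, y0, x1, y1):
    return {
        "type": "Polygon",
        "coordinates": [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]],
    }


def make_toy_bay(spec: ToyBaySpec = ToyBaySpec()) -> ToyBay:
    """Generate the toy bay: rasters, gauges, subregions and masks.

    Layout (1 km x 1 km default): a west-to-east ramp from -3 to +2 m
    MHHW, a subtidal channel along the south, a subsided diked rectangle
    at about -1.5 m on the eastern plain, an urban rectangle on the
    upland, and a north/south split into two biogeomorphic subregions.
    The tide-gauge set samples gently varying tidal-datum fields so the
    NAVD88 -> MHHW round trip is verifiable against the stored truth.
    """
    if spec.nrows < 10 or spec.ncols < 10:
        raise ValueError("toy bay domain must be at least 10 x 10 cells")
    rng = np.random.default_rng(spec.seed)
    gspec = GridSpec(spec.x0, spec.y0, spec.cell, spec.nrows, spec.ncols)
    X, Y = gspec.cell_centers()
    width = spec.ncols * spec.cell
    height = spec.nrows * spec.cell

    # cross-shore ramp + noise (true MHHW-referenced elevation)
    frac = (X - spec.x0) / width
    elev = -3.0 + 5.0 * frac
    elev = elev + rng.normal(0.0, spec.noise_sd, elev.shape)

    # subtidal channel strip along the southern quarter
    chan = Y < spec.y0 - 0.80 * height
    elev[chan] = np.minimum(elev[chan], -2.5)

    # subsided diked polygon on the eastern plain
    dk_geom = _rect(spec.x0 + 0.65 * width, spec.y0 - 0.55 * height,
                    spec.x0 + 0.90 * width, spec.y0 - 0.25 * height)
    dk_mask = ((X >= spec.x0 + 0.65 * width) & (X < spec.x0 + 0.90 * width)
               & (Y <= spec.y0 - 0.25 * height)
               & (Y > spec.y0 - 0.55 * height))
    elev[dk_mask] = -1.5 + rng.normal(0.0, spec.noise_sd, int(dk_mask.sum()))

    # urban polygon on the upland fringe
    ub_geom = _rect(spec.x0 + 0.92 * width, spec.y0 - 0.95 * height,
                    spec.x0 + 1.00 * width, spec.y0 - 0.60 * height)
    ub_mask = ((X >= spec.x0 + 0.92 * width)
               & (Y <= spec.y0 - 0.60 * height)
               & (Y > spec.y0 - 0.95 * height))

    # tidal-datum truth fields: gentle linear gradients
    rng_field = 1.8 + 0.06 * ((X - spec.x0) / width - 0.5)   # MHHW - MLLW
    mllw_navd = 0.15 + 0.03 * ((spec.y0 - Y) / height - 0.5)  # NAVD of MLLW
    mhhw_navd = mllw_navd + rng_field
    elev_navd = elev + mhhw_navd

    # vegetation bias: the lidar surface rides on top of dense canopy
    veg = np.zeros(gspec.shape)
    corrections = {1: -0.10, 2: -0.30}
    north = Y > spec.y0 - 0.5 * height
    veg[north & (elev > -0.2) & (elev <= 0.3)] = 1          # pickleweed-like
    veg[~north & (elev > -0.5) & (elev <= 0.2) & ~chan] = 2  # tule-like mat
    for cls, corr in corrections.items():
        elev_navd[veg == cls] -= corr  # bias is the negative of the fix

    # gauges: a 5 x 5 grid sampling the datum fields at cell centers
    gauges = []
    for gy in np.linspace(0.1, 0.9, 5):
        for gx in np.linspace(0.1, 0.9, 5):
            col = int(gx * spec.ncols)
            row = int(gy * spec.nrows)
            gauges.append(
                {
                    "x": float(X[row, col]),
                    "y": float(Y[row, col]),
                    "mhhw_minus_mllw": float(rng_field[row, col]),
                    "navd_at_mllw": float(mllw_navd[row, col]),
                }
            )

    split = spec.y0 - 0.5 * height
    attrs = {
        1: {"ssc_low": 100.0, "ssc_high": 250.0, "om_low": 1.0, "om_high": 3.0},
        2: {"ssc_low": 50.0, "ssc_high": 200.0, "om_low": 1.0, "om_high": 2.0},
    }
    subregions = [
        {
            "type": "Feature",
            "geometry": _rect(spec.x0, split, spec.x0 + width, spec.y0),
            "properties": {"id": 1, **attrs[1]},
        },
        {
            "type": "Feature",
            "geometry": _rect(spec.x0, spec.y0 - height, spec.x0 + width, split),
            "properties": {"id": 2, **attrs[2]},
        },
    ]

    mk = lambda a, units: Grid(np.asarray(a, dtype=float), gspec, units)
    return ToyBay(
        elev_navd=mk(elev_navd, "m NAVD88"),
        gauges=gauges,
        subregions=subregions,
        subregion_attrs=attrs,
        veg=mk(veg, "class"),
        veg_corrections=corrections,
        diked=mk(dk_mask, "mask"),
        urban=mk(ub_mask, "mask"),
        truth_mhhw=mk(elev, "m MHHW"),
        truth_range=mk(rng_field, "m"),
        truth_navd_at_mllw=mk(mllw_navd, "m NAVD88"),
    )


def write_fixture_files(bay: ToyBay, outdir) -> None:
    """Materialize the toy bay in the text formats the pipeline reads."""
    import csv
    from pathlib import Path

    from .spatial import write_geojson

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bay.elev_navd.to_ascii(out / "elevation_navd88.asc")
    bay.veg.to_ascii(out / "vegetation.asc")
    bay.diked.to_ascii(out / "diked_mask.asc")
    bay.urban.to_ascii(out / "urban_mask.asc")
    write_geojson(bay.subregions, out / "subregions.geojson")
    with open(out / "gauges.csv", "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["x", "y", "mhhw_minus_mllw", "navd_at_mllw"]
        )
        w.writeheader()
        w.writerows(bay.gauges)
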