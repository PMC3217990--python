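"""Elevation-indexed projection tables and threshold analyses.

A handful of anchored accretion runs (starting elevations -2.4, -0.5 and
0.0 m MHHW) is turned into a lookup from *any* starting elevation on a
10-cm grid to its projected elevation at each 20-yr checkpoint, per
scenario.  Outside the anchored range two boundary rules apply:

* below the -4.0 m lower bound, elevations keep pace with sea level, i.e.
  the projection equals the starting elevation (relative to future MHHW);
* above the scenario's upper bound (1.7 m MHHW for the high SLR curve,
  0.6 m for the low curve) there is no accretion potential and elevations
  simply subside by the cumulative SLR at that checkpoint.

Between the highest anchor (0.0 m) and the upper bound the projection
blends linearly into the no-accretion rule, and between -4.0 m and the
lowest anchor it blends into the keep-pace rule, so the lookup is
continuous across both bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .accretion import (
    AccretionParams,
    RunSpec,
    Trajectory,
    reach_year_from_trajectory,
    simulate_elevation,
    sustainability_duration_from_trajectory,
)
from .slr import SLRCurve, slr_elevation
from .util import round_decimeter

__all__ = [
    "ResponseTable",
    "LOWER_BOUND",
    "UPPER_BOUNDS",
    "build_response_table",
    "interpolate_projection",
    "apply_bounds",
    "project_elevation",
    "sustainability_duration",
    "min_start_for_midmarsh",
    "sustainability_grid",
    "min_start_grid",
]

#: Below this starting elevation (m MHHW) beds are assumed to keep pace
#: with SLR across all scenarios and checkpoints.
LOWER_BOUND = -4.0
#: Upper bound of the interpolation domain per SLR curve label (m MHHW),
#: reflecting the area subjected to future tidal inundation.
UPPER_BOUNDS = {"high": 1.7, "low": 0.6}

#: Interpolation grid limits for exported tables (m MHHW, 10-cm steps).
GRID_MIN, GRID_MAX = -3.7, 1.7


@dataclass
class ResponseTable:
    """(starting elevation, checkpoint) -> projected elevation, one scenario.

    ``anchors`` maps checkpoint year -> (anchor starting elevations,
    projected elevations), both ascending; the anchor arrays include the
    -4.0 m keep-pace point and the scenario upper bound, so plain linear
    interpolation between them realizes the whole piecewise rule.
    """

    scenario: tuple  # (ssc mg/L, om mm/yr, slr label)
    slr: SLRCurve
    years: np.ndarray
    anchors: dict  # year -> (starts ndarray, projections ndarray)

    @property
    def upper_bound(self) -> float:
        return UPPER_BOUNDS[self.slr.label]

    def domain(self, t: float) -> tuple[float, float]:
        return (LOWER_BOUND, self.upper_bound)

    def to_frame(self):
        import pandas as pd

        ssc, om, label = self.scenario
        rows = []
        grid = np.round(np.arange(GRID_MIN, GRID_MAX + 0.05, 0.1), 1)
        for t in self.years:
            for x in grid:
                rows.append(
                    {
                        "ssc_mg_L": ssc,
                        "om_mm_yr": om,
                        "slr_label": label,
                        "year": t,
                        "x_start_m": x,
                        "x_future_m": project_elevation(x, self, t),
                    }
                )
        return pd.DataFrame(rows)


def build_response_table(ssc: float, om: float, slr: SLRCurve,
                         tide, *, anchor_starts=(-2.4, -0.5, 0.0),
                         settling_velocity=None, dry_bulk_density=None,
                         lookup=None, datums=None,
                         horizon: float = 100.0,
                         checkpoint_step: float = 20.0) -> ResponseTable:
    """Run the anchor simulations for one scenario and assemble its table."""
    from .accretion import (DRY_BULK_DENSITY_DEFAULT,
                            SETTLING_VELOCITY_DEFAULT)

    w_s = settling_velocity or SETTLING_VELOCITY_DEFAULT
    rho = dry_bulk_density or DRY_BULK_DENSITY_DEFAULT
    anchor_starts = sorted(anchor_starts)
    trajs = {}
    for start in anchor_starts:
        om_eff = 0.0 if start <= -2.4 else om
        spec = RunSpec(
            start_elevation=start,
            params=AccretionParams(ssc=ssc, om_rate=om_eff,
                                   settling_velocity=w_s,
                                   dry_bulk_density=rho),
            slr=slr, horizon=horizon, checkpoint_step=checkpoint_step,
        )
        trajs[start] = simulate_elevation(spec, tide, lookup=lookup,
                                          datums=datums)

    years = np.arange(0.0, horizon + checkpoint_step / 2, checkpoint_step)
    upper = UPPER_BOUNDS[slr.label]
    anchors = {}
    for i, t in enumerate(years):
        starts = [LOWER_BOUND] + anchor_starts + [upper]
        projs = (
            [LOWER_BOUND]  # keep-pace point: projection = start
            + [float(trajs[s].elevation_mhhw[i]) for s in anchor_starts]
            + [upper - slr_elevation(slr, min(t, 100.0))]
        )
        starts = np.asarray(starts, dtype=float)
        projs = np.asarray(projs, dtype=float)
        # No trajectory crossing: projections must be nondecreasing in the
        # start.  Enforce by running maximum (numerical ties only).
        projs = np.maximum.accumulate(projs)
        anchors[float(t)] = (starts, projs)
    return ResponseTable(scenario=(ssc, om, slr.label), slr=slr,
                         years=years, anchors=anchors)


def _anchors_at(table: ResponseTable, t: float):
    key = float(t)
    if key not in table.anchors:
        raise KeyError(f"no checkpoint {t} in table (have {sorted(table.anchors)})")
    return table.anchors[key]


def interpolate_projection(x: float, table: ResponseTable, t: float) -> float:
    """Two-point linear interpolation between the bracketing anchors.

    ``x`` (m MHHW) must lie inside the scenario's interpolation domain;
    values outside are the province of :func:`apply_bounds`.
    """
    lo, hi = table.domain(t)
    if x < lo or x > hi:
        raise ValueError(
            f"x={x} outside interpolation domain [{lo}, {hi}]; "
            "use apply_bounds"
        )
    starts, projs = _anchors_at(table, t)
    return float(np.interp(x, starts, projs))


def apply_bounds(x: float, t: float, slr: SLRCurve) -> float:
    """Boundary rules for starting elevations outside the table domain.

    Below -4.0 m MHHW the bed keeps pace with SLR (projection = start);
    above the scenario upper bound there is no accretion potential and the
    bed subsides by the cumulative SLR at ``t``.
    """
    upper = UPPER_BOUNDS[slr.label]
    if x < LOWER_BOUND:
        return float(x)
    if x > upper:
        return float(x - slr_elevation(slr, min(t, 100.0)))
    raise ValueError(
        f"x={x} is inside the interpolation domain [{LOWER_BOUND}, {upper}]"
    )


def project_elevation(x: float, table: ResponseTable, t: float,
                      snap: bool = True) -> float:
    """Full projection dispatch: snap to the 10-cm grid, then interpolate
    or apply the boundary rules as appropriate."""
    if snap:
        x = round_decimeter(x)
    lo, hi = table.domain(t)
    if x < lo or x > hi:
        return apply_bounds(x, t, table.slr)
    return interpolate_projection(x, table, t)


# ---------------------------------------------------------------------------
# threshold analyses
# ---------------------------------------------------------------------------


def sustainability_duration(ssc: float, om: float, slr: SLRCurve,
                            start: float, tide, *, lookup=None, datums=None,
                            settling_velocity=None,
                            dry_bulk_density=None) -> float:
    """Longest 20-yr checkpoint with zero elevation loss (10-cm rounded).

    Runs the accretion simulator directly from ``start`` (m MHHW).
    """
    from .accretion import (DRY_BULK_DENSITY_DEFAULT,
                            SETTLING_VELOCITY_DEFAULT)

    spec = RunSpec(
        start_elevation=start,
        params=AccretionParams(
            ssc=ssc, om_rate=om,
            settling_velocity=settling_velocity or SETTLING_VELOCITY_DEFAULT,
            dry_bulk_density=dry_bulk_density or DRY_BULK_DENSITY_DEFAULT,
        ),
        slr=slr,
    )
    traj = simulate_elevation(spec, tide, lookup=lookup, datums=datums)
    return sustainability_duration_from_trajectory(traj)


#: Sentinel returned when no starting elevation attains mid marsh.
UNACHIEVABLE = math.inf


def min_start_for_midmarsh(table: ResponseTable, horizon: float,
                           target: float = -0.2) -> float:
    """Minimum starting elevation whose projection attains mid marsh.

    Scans the 10-cm starting-elevation grid from the bottom of the
    interpolation domain upward and returns the first start whose
    projected elevation at ``horizon`` reaches ``target`` (m MHHW) after
    10-cm rounding.  Returns ``UNACHIEVABLE`` (inf) when no start
    qualifies.  A value at the bottom of the grid means "at least as low
    as" that elevation: starts below the lowest anchor are flagged
    unreliable by the construction of the table itself.
    """
    grid = np.round(np.arange(GRID_MIN, table.upper_bound + 0.05, 0.1), 1)
    for x in grid:
        if round_decimeter(project_elevation(float(x), table, horizon)) >= (
            target - 1e-12
        ):
            return float(x)
    return UNACHIEVABLE


def sustainability_grid(ssc_levels, om_rates, slr_curves, tide, *,
                        starts=(-0.5, 0.0), lookups=None, datums=None,
                        settling_velocity=None, dry_bulk_density=None):
    """Sustainability duration for every (SSC, OM, SLR, start) cell."""
    import pandas as pd

    rows = []
    for slr in slr_curves:
        for ssc in ssc_levels:
            for om in om_rates:
                for start in starts:
                    dur = sustainability_duration(
                        ssc, om, slr, start, tide,
                        lookup=None if lookups is None else lookups,
                        datums=datums,
                        settling_velocity=settling_velocity,
                        dry_bulk_density=dry_bulk_density,
                    )
                    rows.append(
                        {
                            "slr_label": slr.label,
                            "ssc_mg_L": ssc,
                            "om_mm_yr": om,
                            "start_m_mhhw": start,
                            "duration_yr": dur,
                        }
                    )
    return pd.DataFrame(rows)


def min_start_grid(ssc_levels, om_rates, slr_curves, tide, *,
                   horizons=(20.0, 40.0, 60.0, 80.0, 100.0),
                   lookup=None, datums=None,
                   settling_velocity=None, dry_bulk_density=None):
    """Minimum starting elevation for mid-marsh attainment, with habitat
    classification of that start, per scenario and horizon."""
    import pandas as pd

    from .spatial import classify_habitat

    rows = []
    for slr in slr_curves:
        for ssc in ssc_levels:
            for om in om_rates:
                table = build_response_table(
                    ssc, om, slr, tide, lookup=lookup, datums=datums,
                    settling_velocity=settling_velocity,
                    dry_bulk_density=dry_bulk_density,
                )
                for horizon in horizons:
                    m = min_start_for_midmarsh(table, horizon)
                    rows.append(
                        {
                            "slr_label": slr.label,
                            "ssc_mg_L": ssc,
                            "om_mm_yr": om,
                            "horizon_yr": horizon,
                            "min_start_m_mhhw": m,
                            "start_class": (
                                "unachievable" if math.isinf(m)
                                else classify_habitat(m).name.lower()
                            ),
                        }
                    )
    return pd.DataFrame(rows)
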