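# Methods

## Model overview

`tidemarsh` couples a zero-dimensional, tide-resolving marsh accretion
simulator to a raster projection pipeline.  The simulator produces
century-scale bed-elevation trajectories for a handful of anchor starting
elevations under combinations of suspended sediment concentration (SSC),
organic accretion rate (OM) and sea-level-rise (SLR) trajectory.  Those
trajectories are then generalized, by linear interpolation in starting
elevation, into lookup tables that project *any* pixel of an
MHHW-referenced elevation raster to a future elevation — so the expensive
process model runs a few dozen times, not once per pixel.

## Tidal forcing

The boundary condition is a single repeating "tidal month": 28 days of
water levels sampled at 0.1 h, synthesized from four sinusoidal
constituents (M2-, S2-, K1- and O1-like periods with amplitude ratios
0.56 : 0.13 : 0.37 : 0.23 and aligned phases).  This yields a mixed
semidiurnal tide with a pronounced diurnal inequality, spring–neap
modulation from the M2/S2 beat, and spring higher-high waters reaching
roughly 0.35 m above MHHW — the part of the frame that lets a marsh plain
build above MHHW and bank an elevation buffer.  The synthesized levels
are rescaled by a single factor so that the computed great diurnal range
(MHHW − MLLW) equals the configured value (default 1.8 m); because tidal
datums are means of per-tidal-day extrema, they scale exactly with the
levels and one rescale is exact.

Datums are extracted by partitioning the series into consecutive 24.84-h
lunar-day windows: MHHW is the mean of window maxima, MLLW the mean of
window minima, MTL the mean of the series' tidal high and low waters.
Sea-level rise enters as an additive offset to the (fixed-shape) month.

The 0.1-h step keeps the discretization error of extrema below 1 cm at
these amplitudes; a century of forcing is about 1,300 tiled months, i.e.
roughly 70,000 tidal cycles per run.

## Sea-level-rise curves

Both scenario curves are accelerating quadratics in years since 2010,

    E(t) = a t + b t²,  a = 0.002 m/yr,
    b = (E(100) − 100 a) / 100²,

anchored to century totals of 0.52 m (low) and 1.65 m (high).  This is
the standard way the National Research Council scenario family is
extrapolated from a present-day linear trend; only the endpoint totals
are treated as authoritative, and both curves place most of their rise in
the second half of the century.

## Mineral deposition (Krone-type mass balance)

Per sampling step of each tidal inundation:

* **Flood phase** (depth non-decreasing): incoming water holds the
  ambient concentration C₀, and sediment rains out at the settling flux
  w_s·C₀.  The first step of an inundation is weighted by the flooded
  fraction of the step, located from the sign change of depth.
* **Ebb phase** (depth decreasing after local high water): the column is
  no longer replenished and depletes as dC/dt = −w_s·C/h(t).  Over a step
  of depth h this has the exact solution C → C·exp(−w_s Δt/h), and the
  settled mass is h·C·(1 − exp(−w_s Δt/h)).  Depletion restarts from
  ambient at every local high water.  A partial drain-out term accounts
  for the fraction of the step in which the column empties at the end of
  an inundation.

Settled mass divided by the dry bulk density ρ_dry gives bed thickness.
There is no erosion, resuspension or wave term: bed shear stresses are
assumed minimal, which restricts the model's validity to sheltered
settings landward of the marsh–mudflat boundary.  This per-step scheme
agrees with a fine-time-step explicit integration of the same equations
to better than 0.6 % across the tested elevation × settling-velocity
panel (the test suite enforces ≤ 1 %).

Deposition is *exactly linear* in C₀, which the `DepositionLookup` class
exploits: a monthly deposition curve over bed elevation is tabulated once
per (tidal month, w_s) at unit concentration and scaled at lookup time.
Century simulations through the lookup agree with direct month-by-month
integration to better than 1 cm and run ~100× faster; the calibration
sweep and the scenario pipeline use the lookup, and a test pins the two
paths together.

## Organic accretion

OM accrues at a constant configured rate (0–3 mm/yr), added directly to
the bed every month regardless of inundation state or elevation.  For
subtidal starting elevations (−2.4 m MHHW) OM is forced to zero, since no
vegetation is present to supply it.  Because OM is a constant rate, the
century-elevation difference between the 1 and 3 mm/yr settings is
bounded by 0.20 m, and the elevation feedback on mineral deposition can
only shrink that gap — both are enforced as tests.

## Reporting conventions

Elevations are reported relative to the *contemporaneous* MHHW (start
datum + cumulative SLR) at 20-yr checkpoints.  Sustainability is zero
elevation loss: the largest checkpoint at which the elevation, rounded to
the nearest 10 cm (halves away from zero), has not fallen below the
rounded start.  "Attaining mid marsh" likewise means the checkpoint
elevation rounds into the mid-marsh band (≥ −0.2 m MHHW after rounding).
Rounding happens at comparison time only; trajectories remain exact.

## Calibration of w_s and ρ_dry

The settling velocity and dry bulk density are the two constants of the
mass balance that the scenario definitions leave open.  They are selected
by exhaustive grid search (10 settling velocities from 1×10⁻⁵ to
1×10⁻³ m/s, spanning the flocculated-fines literature range, × 7 bulk
densities from 200 to 800 kg/m³) against a fixture of qualitative
threshold statements (`make_threshold_fixture`): sustainability durations
and restoration reach-times on the tested SSC/OM/SLR grids, plus the
tide-range sensitivity bounds.  The objective is lexicographic: most
mandatory entries satisfied, then most entries overall, then proximity to
mid-range parameter values.  The search is deterministic and the selected
pair is frozen as the package defaults:

    w_s = 2×10⁻⁵ m/s,  ρ_dry = 700 kg/m³.

Note that the lower end of the settling-velocity grid sits below the
1×10⁻⁴ m/s often quoted for estuarine flocs.  This is deliberate: the
flood phase of this formulation continuously replenishes the column at
ambient concentration, so it delivers more sediment per cycle than
formulations that treat the high-water column as a finite reservoir, and
an equivalent net deposition therefore corresponds to a smaller effective
settling velocity.

**Joint infeasibility of the threshold set.**  Two fixture entries cannot
be satisfied by *any* parameter pair — not because the grid is too
coarse, but structurally.  Deposition here is linear in SSC and
non-increasing in bed elevation.  Under the low SLR curve
(E(60 yr) = 0.235 m) with OM at 3 mm/yr, losing elevation (after 10-cm
rounding) by year 60 from a −0.5 m start requires the cumulative mineral
gain at 25 mg/L to stay below about 5 mm — i.e. mean deposition below
0.1 mm/yr at marsh elevations, hence below about 1.2 mm/yr at 300 mg/L by
linearity.  But holding a 0 m MHHW start within rounding of its elevation
until year 80 under the high curve requires of order 10–25 mm/yr at the
same elevations and concentration.  Both statements cannot hold at once,
so the low-SSC sustainability cap is necessarily exceeded whenever the
high-SSC mid-marsh duration is matched.  A second, softer conflict ties
the 20-yr subtidal restoration time at 300 mg/L (low SLR) to the
requirement that 200 mg/L *not* restore subtidal flats under high SLR:
parameter pairs exist for either, not both, and the shipped objective
resolves the trade-off in favour of overall agreement.  The calibration
report carries the measured value of every entry so the residual
disagreements are visible, and `calibrate(..., require_all=True)` raises
with the best-achieved agreement rather than silently accepting it.

At the frozen pair, widening the tidal range from 1.8 m to 2.8 m lowers
century-end elevations relative to MHHW by at most 0.13 m over the
moderate-to-high SSC cases, but the largest such deficit amounts to about
8 % of that run's total predicted accretion, above the 5 % figure the
fixture encodes — the one sensitivity bound this implementation does not
reproduce.

## Response tables

For each scenario (SSC, OM, SLR), anchor runs start at −2.4, −0.5 and
0.0 m MHHW.  The projection for an arbitrary starting elevation x at
checkpoint t is linear interpolation between the bracketing anchors,
extended continuously to two boundary rules: below −4.0 m the bed keeps
pace with SLR (projection = x), and above the scenario upper bound
(1.7 m MHHW for high SLR, 0.6 m for low — the limit of future tidal
inundation) the bed simply subsides by the cumulative SLR.  Between the
0.0 m anchor and the upper bound the table blends linearly into the
no-accretion rule, and between −4.0 m and the −2.4 m anchor into the
keep-pace rule; both bounds are therefore continuous, and a running
maximum enforces monotonicity of projections in the starting elevation.
Starting elevations are snapped to the 10-cm grid before lookup, so a
raster projection is a small per-decimeter table per subregion rather
than a per-pixel model run.  Projections below the lowest anchor are a
construction of the boundary rule, not model output, and should be read
as unreliable.

## Spatial pipeline

Rasters are numpy grids with an upper-left-anchored, half-open cell
geometry; polygon attribution is by cell-center containment
(`shapely.contains_xy`).  I/O is deliberately text-based: ESRI ASCII
grids for rasters, GeoJSON for vectors, CSV for tables.

* **Datum referencing.**  Gauge values are interpolated to 100-m offset
  surfaces by inverse-distance weighting with power exactly 2, using all
  points and no neighborhood cutoff; a cell coincident with a gauge takes
  its value.  The surfaces are bilinearly resampled to the 5-m elevation
  grid and combined as NAVD88 + MLLW offset − MHHW offset = MHHW
  elevation.
* **Vegetation correction.**  Per-class additive offsets remove canopy
  bias from the lidar-like surface; unmapped classes are left unchanged
  with a logged warning.
* **Habitat bands** (m MHHW): upland > 0.3; high marsh 0.2–0.3; mid
  marsh −0.2–0.1; low marsh −0.5 to −0.3; mudflat −1.8 to −0.6; subtidal
  < −1.8.  The printed band edges leave 10-cm gaps that vanish once
  elevations are rounded to the decimeter grid, so classification rounds
  first and the bands tile the axis exactly.
* **Area accounting.**  Land-status precedence is urban > diked > tidal;
  one 5-m pixel is 0.0025 ha; per-status class totals are conservative by
  construction and tested to the pixel.  Diked areas are projected as if
  all barriers to inundation were removed at the epoch — the diked mask
  only separates "restoration potential" from existing tidal habitat in
  the summaries, with urban areas reported as un-restorable.

## Synthetic toy bay

The spatial stages are exercised on a fully synthetic 1 km² embayment
(200 × 200 cells at 5 m): a west–east ramp from −3 to +2 m MHHW, a
subtidal channel, a subsided diked rectangle at −1.5 m, an urban
rectangle on the upland, two biogeomorphic subregions with SSC/OM
attributes on the tested grids, and a 5 × 5 gauge array sampling gently
varying datum fields (range 1.8 ± 0.03 m, MLLW-in-NAVD 0.15 ± 0.015 m).
Elevation noise is i.i.d. Gaussian with σ = 0.05 m, the vertical-error
scale of airborne lidar; a seed fully determines every output.

What the toy bay does *not* emulate: spatially correlated lidar error,
real shoreline geometry and channel networks, datum fields with
non-linear structure, wave-exposed margins, and the areal proportions of
a real estuary.  Tests passing on it demonstrate that the pipeline's
arithmetic, registration, rounding and accounting are correct — not that
projections for any real bay are accurate, which depends on input data
quality and on the process assumptions above.

## Numerical choices and degenerate inputs

* Rounding to the decimeter grid is half-away-from-zero, applied
  identically in sustainability decisions, reach decisions, band
  classification and table snapping.
* Checkpoint elevations are linearly interpolated between month
  boundaries, so OM-only arithmetic is exact at checkpoints.
* A flat tide (all amplitudes zero) cannot be rescaled and is rejected;
  series shorter than one lunar day have no datums; a bed above all water
  yields zero cycles and zero deposition; horizons must be multiples of
  the checkpoint step.
* The deposition lookup tabulates bed elevations from −8 to +4 m at 2 cm;
  outside that range deposition is clamped to the curve ends (0 above the
  highest water).

## Problem sizes

Default runs use the 28-day month at 0.1 h (6,720 samples), ~1,300 months
per century run.  The calibration sweep evaluates 70 parameter pairs ×
~60 runs each through the unit-concentration lookup, and the acceptance
computation re-runs the calibration plus ~120 measured runs; the full
factorial toy-bay pipeline (8 scenarios × 6 checkpoints) completes in a
few seconds.  These sizes are the package's chosen defaults; every grid
and duration is configurable.

## Known limitations

* No wave erosion, sediment transport, or vegetation-productivity
  feedback on OM; projected habitat areas are optimistic for exposed low
  marsh and pessimistic for storm-deposited high marsh.
* One tidal month and one tide range force the whole domain; tidal
  amplification along an estuary is reflected only through the
  sensitivity analysis.
* The printed threshold set used for calibration is not jointly
  satisfiable in this model class (see above); two thresholds and one
  sensitivity percentage are knowingly unmet at the frozen defaults.
* SLR curves are defined on 2010–2110 only; no probabilistic ensembles.
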