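# tidemarsh

Tide-resolving tidal-marsh accretion simulation and spatially explicit
sea-level-rise (SLR) habitat projection.

Tidal marshes persist in a narrow elevation band around mean higher high
water (MHHW).  Whether a marsh keeps up with accelerating sea-level rise
depends on the suspended sediment concentration (SSC) of its flooding
water, organic matter (OM) accumulation, and its starting elevation.
`tidemarsh` is aimed at coastal scientists and restoration planners who
need estuary-scale, per-pixel answers to questions like *"will this marsh
plain still be vegetated in 2110?"* and *"from how deep can a breached
dike site build to a marsh plain, and how fast?"* — without running a
hydrodynamic model per pixel.

## The model

At the core is a Krone-type sediment mass balance driven by a repeating
synthetic tidal month (mixed semidiurnal, spring–neap modulated, rescaled
to a 1.8-m great diurnal range).  During each tidal inundation of a bed
at elevation z:

- while water rises, flood water holds the ambient concentration C₀ and
  sediment settles at the flux w_s·C₀ (w_s = floc settling velocity);
- after local high water the column of depth h(t) depletes,
  dC/dt = −w_s·C/h, settling h·C·(1 − e^(−w_s·Δt/h)) per step;
- settled mass ÷ dry bulk density ρ_dry = bed-elevation gain, plus a
  constant organic accretion rate (mm/yr).

Sea level follows accelerating quadratic trajectories
E(t) = 0.002·t + b·t² anchored to 0.52 m (low) or 1.65 m (high) of rise
over 2010–2110.  Elevations are tracked relative to the contemporaneous
MHHW, so the drowning race between deposition and SLR is explicit, with
the characteristic feedback: a falling marsh floods longer and catches
more sediment.

Century trajectories from three anchor starts (−2.4, −0.5, 0.0 m MHHW)
are linearly interpolated into response tables over starting elevations
on a 10-cm grid, then applied per pixel to an MHHW-referenced elevation
raster attributed by biogeomorphic subregion (each with low/high SSC and
OM), classified into habitat bands (subtidal, mudflat, low/mid/high
marsh, upland) and summarized in hectares by subregion and land status
(tidal / diked / urban).  The two free physical constants (w_s, ρ_dry)
are chosen by a grid-search calibration against qualitative
sustainability and restoration thresholds; see `docs/methods.md` for the
model's assumptions, the calibration, and its documented residual
disagreements.

## Worked example

A low marsh (−0.5 m MHHW) in a sediment-rich subregion (250 mg/L, OM
2 mm/yr) under the high SLR curve:

```sh
$ tidemarsh simulate --ssc 250 --om 2 --slr high --start -0.5
year  elev_m_MHHW
    0    -0.500
   20    -0.086
   40     0.006
   60    -0.033
   80    -0.127
  100    -0.246
total accretion: 1.905 m
```

The marsh builds to the marsh-plain elevation (≈ MHHW) within 40 years
while SLR is still slow, then loses ground as the rise accelerates,
ending the century 25 cm below MHHW — back at low-marsh elevation despite
nearly 2 m of accretion.  Rounded to the 10-cm convention, its elevation
first drops below the start at year 100, i.e. it sustains its elevation
for 80 years.

The full spatial pipeline on the built-in synthetic bay:

```sh
tidemarsh all --fixtures --seed 0 --outdir outputs
```

writes, per scenario (2 SSC × 2 OM × 2 SLR levels) and 20-yr checkpoint,
projected-elevation and habitat rasters (ESRI ASCII), an `areas.csv` of
hectares by subregion × land status × habitat class, and a reproducibility
manifest.  `tidemarsh fixtures` materializes the synthetic inputs;
`tidemarsh tables` exports the sustainability-duration and
minimum-starting-elevation analysis grids.

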