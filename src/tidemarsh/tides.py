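"""Synthetic tidal forcing and tidal datums.

The simulator is driven by a single repeating "tidal month": a ~28-day
water-level record synthesized as a sum of sinusoidal constituents and
rescaled so its great diurnal range (MHHW - MLLW) matches a target value.
Datums are extracted from per-tidal-day (24.84 h) extrema, following the
standard definitions: MHHW is the mean of daily higher-high waters, MLLW
the mean of daily lower-low waters, and MTL the mean of all tidal high
and low waters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TideConstituent",
    "TideSeries",
    "TidalDatums",
    "DEFAULT_CONSTITUENTS",
    "TIDAL_DAY_HOURS",
    "generate_tidal_month",
    "compute_datums",
    "inundation_cycles",
]

#: Length of one lunar (tidal) day in hours, the window used for datum extraction.
TIDAL_DAY_HOURS = 24.84


@dataclass(frozen=True)
class TideConstituent:
    """One sinusoidal tidal constituent.

    Parameters
    ----------
    name : str
        Label (e.g. ``"M2"``).
    amplitude : float
        Amplitude in metres (>= 0).
    period : float
        Period in hours (> 0).
    phase : float
        Phase in radians.
    """

    name: str
    amplitude: float
    period: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError(f"constituent {self.name}: amplitude must be >= 0")
        if self.period <= 0:
            raise ValueError(f"constituent {self.name}: period must be > 0")


#: Mixed semidiurnal constituent set (amplitude ratios typical of a Pacific
#: coast estuary mouth; M2/S2 beat supplies spring-neap modulation, K1/O1 the
#: diurnal inequality).  Amplitudes are rescaled to the target range by
#: :func:`generate_tidal_month`, so only the ratios matter.
DEFAULT_CONSTITUENTS: tuple[TideConstituent, ...] = (
    TideConstituent("M2", 0.56, 12.4206, 0.0),
    TideConstituent("S2", 0.13, 12.0000, 0.0),
    TideConstituent("K1", 0.37, 23.9345, 0.0),
    TideConstituent("O1", 0.23, 25.8193, 0.0),
)


@dataclass
class TideSeries:
    """Uniformly sampled water-level series.

    ``times`` are hours from the series epoch with constant step ``step``
    (hours); ``levels`` are metres in a local (NAVD-like) datum.
    """

    times: np.ndarray
    levels: np.ndarray
    step: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.times.shape != self.levels.shape:
            raise ValueError("times and levels must have the same shape")
        if self.times.size < 2:
            raise ValueError("series needs at least two samples")
        steps = np.diff(self.times)
        if not np.allclose(steps, self.step, rtol=0, atol=1e-9):
            raise ValueError("times must be uniformly spaced at `step`")

    @property
    def duration_hours(self) -> float:
        return self.times[-1] - self.times[0] + self.step

    def tile(self, k: int) -> "TideSeries":
        """Repeat the series ``k`` times end to end."""
        if k < 1:
            raise ValueError("k must be >= 1")
        n = self.times.size
        times = self.times[0] + np.arange(n * k) * self.step
        return TideSeries(times, np.tile(self.levels, k), self.step)

    def shifted(self, offset: float) -> "TideSeries":
        """Return a copy with all levels raised by ``offset`` metres."""
        return TideSeries(self.times.copy(), self.levels + offset, self.step)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"time_h": self.times, "level_m": self.levels}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class TidalDatums:
    """Tidal datums of a series (all metres, same datum as the series)."""

    mhhw: float
    mllw: float
    mtl: float

    def __post_init__(self) -> None:
        if self.mhhw < self.mllw:
            raise ValueError("mhhw must be >= mllw")

    @property
    def range(self) -> float:
        """Great diurnal range, MHHW - MLLW."""
        return self.mhhw - self.mllw


def _synthesize(constituents, times: np.ndarray) -> np.ndarray:
    levels = np.zeros_like(times)
    for c in constituents:
        levels += c.amplitude * np.cos(2.0 * np.pi * times / c.period - c.phase)
    return levels


def generate_tidal_month(
    constituents=DEFAULT_CONSTITUENTS,
    target_range: float = 1.8,
    duration_days: int = 28,
    step_hours: float = 0.1,
) -> TideSeries:
    """Synthesize the repeating tidal-month boundary condition.

    The sum-of-sinusoids series is rescaled (a single multiplicative factor
    on the levels, which scales every extremum and hence every datum
    linearly) so that its computed MHHW - MLLW equals ``target_range``.

    Parameters
    ----------
    constituents : sequence of TideConstituent
    target_range : float
        Desired great diurnal range (m), > 0.
    duration_days : int
        Series length in whole days, >= 28 so a full spring-neap cycle is
        covered.
    step_hours : float
        Sample interval (h), <= 0.5.
    """
    if not constituents:
        raise ValueError("constituent list is empty")
    if target_range <= 0:
        raise ValueError("target_range must be > 0")
    if duration_days < 28:
        raise ValueError("duration must cover at least 28 days")
    if step_hours > 0.5:
        raise ValueError("step must be <= 0.5 h")

    n = int(round(duration_days * 24.0 / step_hours))
    times = np.arange(n) * step_hours
    levels = _synthesize(constituents, times)

    raw = compute_datums(TideSeries(times, levels, step_hours))
    if raw.range <= 0:
        raise ValueError("flat series has zero range and cannot be rescaled")
    # Datums are means of extrema, so they scale exactly with the levels:
    # one rescale lands the range on target.
    levels *= target_range / raw.range
    return TideSeries(times, levels, step_hours)


def compute_datums(series: TideSeries) -> TidalDatums:
    """Extract MHHW / MLLW / MTL from per-tidal-day extrema.

    The series is partitioned into consecutive 24.84-h windows (a trailing
    partial window is dropped); MHHW is the mean of window maxima and MLLW
    the mean of window minima.  MTL is the mean of tidal high and low
    waters (local extrema of the series).
    """
    per_day = int(round(TIDAL_DAY_HOURS / series.step))
    n_days = series.levels.size // per_day
    if n_days < 1:
        raise ValueError("series shorter than one tidal day")
    trimmed = series.levels[: n_days * per_day].reshape(n_days, per_day)
    mhhw = float(trimmed.max(axis=1).mean())
    mllw = float(trimmed.min(axis=1).mean())

    x = series.levels
    interior = x[1:-1]
    highs = interior[(interior >= x[:-2]) & (interior > x[2:])]
    lows = interior[(interior <= x[:-2]) & (interior < x[2:])]
    if highs.size and lows.size:
        mtl = float((highs.mean() + lows.mean()) / 2.0)
    else:  # constant series: no interior extrema
        mtl = float(x.mean())
    return TidalDatums(mhhw=mhhw, mllw=mllw, mtl=mtl)


def inundation_cycles(series: TideSeries, bed_elevation: float):
    """Maximal contiguous intervals with water above the bed.

    Returns a list of ``(start_h, end_h, peak_depth_m)`` tuples, ordered
    and non-overlapping.  ``end_h`` is the time of the last wet sample plus
    one step (half-open interval).  A bed above all water yields an empty
    list.
    """
    wet = series.levels > bed_elevation
    if not wet.any():
        return []
    w = wet.astype(np.int8)
    starts = np.flatnonzero(np.diff(w, prepend=0) == 1)
    ends = np.flatnonzero(np.diff(w, append=0) == -1)
    out = []
    for s, e in zip(starts, ends):
        depth = float(series.levels[s : e + 1].max() - bed_elevation)
        out.append(
            (float(series.times[s]), float(series.times[e] + series.step), depth)
        )
    return out
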