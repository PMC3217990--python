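"""Nonlinear cumulative sea-level-rise trajectories.

Two accelerating century curves are used, patterned on the National
Research Council scenario family as extrapolated in US Army Corps of
Engineers guidance: a quadratic

    E(t) = a * t + b * t**2,   t in years since the 2010 epoch,

with ``a`` the present linear trend (default 0.002 m/yr) and ``b`` solved
so that E(100) equals the prescribed century total (0.52 m for the low,
NRC-I-like curve; 1.65 m for the high, NRC-III-like curve).  Both curves
are convex, so most of the rise falls in the second half of the century.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SLRCurve", "LOW", "HIGH", "slr_elevation", "slr_increment"]


@dataclass(frozen=True)
class SLRCurve:
    """Quadratic cumulative sea-level offset as a function of years since 2010."""

    label: str
    initial_rate: float = 0.002  # m/yr, linear term a
    century_total: float = 0.52  # m, E(100)

    @property
    def quad_coeff(self) -> float:
        """Quadratic coefficient b = (E(100) - 100 a) / 100**2 (1/yr^2 scale)."""
        return (self.century_total - 100.0 * self.initial_rate) / 1.0e4

    def elevation(self, t):
        return slr_elevation(self, t)

    def rate(self, t):
        """Instantaneous rate dE/dt (m/yr)."""
        t = np.asarray(t, dtype=float)
        out = self.initial_rate + 2.0 * self.quad_coeff * t
        return float(out) if out.ndim == 0 else out

    def to_csv(self, path, step_years: float = 1.0) -> None:
        import pandas as pd

        years = np.arange(0.0, 100.0 + step_years / 2, step_years)
        pd.DataFrame({"year": years, "slr_m": self.elevation(years)}).to_csv(
            path, index=False
        )


#: Low (modified NRC-I) trajectory: 0.52 m of rise 2010-2110.
LOW = SLRCurve("low", 0.002, 0.52)
#: High (modified NRC-III) trajectory: 1.65 m of rise 2010-2110.
HIGH = SLRCurve("high", 0.002, 1.65)

CURVES = {"low": LOW, "high": HIGH}


def slr_elevation(curve: SLRCurve, t):
    """Cumulative sea-level offset (m) at ``t`` years since 2010, 0 <= t <= 100."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 100):
        raise ValueError("t must lie in [0, 100] years")
    out = curve.initial_rate * t + curve.quad_coeff * t**2
    return float(out) if out.ndim == 0 else out


def slr_increment(curve: SLRCurve, t0: float, t1: float) -> float:
    """Rise between ``t0`` and ``t1`` (years); additive over adjacent intervals."""
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    return float(slr_elevation(curve, t1) - slr_elevation(curve, t0))
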