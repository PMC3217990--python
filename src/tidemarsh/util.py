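"""Small shared numeric helpers."""

from __future__ import annotations

import numpy as np

__all__ = ["round_decimeter", "decimeter_index"]


def round_decimeter(x):
    """Round elevations to the nearest 10 cm, halves away from zero.

    All habitat bands, sustainability decisions and lookup-table grids
    operate on this 10-cm grid, so the rounding rule must be deterministic
    and direction-free; half-away-from-zero avoids the bias of banker's
    rounding on the exact 5-cm ties that the arithmetic occasionally
    produces.
    """
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * 10.0 + 0.5) / 10.0
    out = out + 0.0  # normalize -0.0
    return float(out) if out.ndim == 0 else out


def decimeter_index(x):
    """Elevation expressed as an integer count of decimeters after rounding."""
    x = np.asarray(x, dtype=float)
    out = (np.sign(x) * np.floor(np.abs(x) * 10.0 + 0.5)).astype(np.int64)
    return int(out) if out.ndim == 0 else out
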