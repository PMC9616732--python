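"""Circular statistics for SO-phase coupling (angles in degrees)."""

from __future__ import annotations

import numpy as np


def _to_rad(deg) -> np.ndarray:
    a = np.asarray(deg, dtype=float)
    return np.radians(a[np.isfinite(a)])


def circ_mean_deg(phases_deg) -> float:
    """Circular mean direction, degrees in (-180, 180]."""
    a = _to_rad(phases_deg)
    if a.size == 0:
        return float("nan")
    return float(np.degrees(np.angle(np.exp(1j * a).mean())))


def circ_r(phases_deg) -> float:
    """Mean resultant length in [0, 1]."""
    a = _to_rad(phases_deg)
    if a.size == 0:
        return float("nan")
    return float(np.abs(np.exp(1j * a).mean()))


def rayleigh_p(phases_deg) -> float:
    """Rayleigh test p-value for non-uniformity of circular data.

    Uses the standard Zar approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) with R = n * rbar,
    accurate for n as small as 10.
    """
    a = _to_rad(phases_deg)
    n = a.size
    if n == 0:
        return float("nan")
    big_r = n * circ_r(np.degrees(a))
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n ** 2 - big_r ** 2)) - (1 + 2 * n))
    return float(min(p, 1.0))
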