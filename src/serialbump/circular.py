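"""Circular (angular) helper functions.

All angles in this package are in degrees on the ring [0°, 360°).  Signed
differences are wrapped to the half-open interval (-180°, 180°], so that a
difference of exactly half the circle maps to +180°.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "wrap_360", "circular_distance"]


def wrap_deg(angle):
    """Wrap a signed angular difference (deg) to (-180, 180].

    Works elementwise on arrays and on scalars.
    """
    w = np.mod(angle, 360.0)
    out = np.where(w > 180.0, w - 360.0, w)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(out)
    return out


def wrap_360(angle):
    """Wrap an angle (deg) to [0, 360)."""
    out = np.mod(angle, 360.0)
    # np.mod of a tiny negative angle can round to exactly 360.0
    out = np.where(out == 360.0, 0.0, out)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return float(out)
    return out


def circular_distance(a, b):
    """Minimal unsigned circular distance |a - b| (deg), in [0, 180]."""
    return np.abs(wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
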