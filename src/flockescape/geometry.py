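"""Planar angle and vector helpers shared by the simulator and detectors.

Headings are degrees counter-clockwise from +x; positive angular
velocity is a left turn.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_deg", "norm_heading", "heading_unit", "angle_of", "unit", "cross2"]


def wrap_deg(angle):
    """Wrap an angle difference into (-180, 180] degrees."""
    a = np.asarray(angle, dtype=float)
    out = -((-a + 180.0) % 360.0 - 180.0)
    return out.item() if np.isscalar(angle) or a.ndim == 0 else out


def norm_heading(angle):
    """Normalize a heading into [0, 360) degrees."""
    a = np.asarray(angle, dtype=float) % 360.0
    # a negative denormal wraps to exactly 360.0 under float rounding
    a = np.where(a >= 360.0, 0.0, a)
    return a.item() if np.isscalar(angle) or a.ndim == 0 else a


def heading_unit(heading_deg):
    """Unit vector(s) for heading(s) in degrees; shape (..., 2)."""
    r = np.radians(heading_deg)
    return np.stack([np.cos(r), np.sin(r)], axis=-1)


def angle_of(vec) -> float:
    """Heading in degrees of a 2-D vector (undefined for the zero vector)."""
    v = np.asarray(vec, dtype=float)
    return float(norm_heading(np.degrees(np.arctan2(v[1], v[0]))))


def unit(vec):
    """Normalize a 2-D vector; the zero vector maps to itself."""
    v = np.asarray(vec, dtype=float)
    n = np.linalg.norm(v)
    return v if n == 0.0 else v / n


def cross2(a, b) -> float:
    """z-component of the cross product of two 2-D vectors."""
    return float(a[0] * b[1] - a[1] * b[0])
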