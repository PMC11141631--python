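"""Angle conventions and wrapping helpers.

All angles in this package are in degrees, measured counter-clockwise from
the image x-axis (columns) with the y-axis pointing *up* (i.e. the array row
axis points along -y).  Nematic (axial) angles live in the half-open
interval (-90, 90]; directional angles in (-180, 180].

A direction at angle ``theta`` therefore corresponds to the array step
``(drow, dcol) = (-sin(theta), cos(theta))``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_nematic",
    "wrap_directional",
    "nematic_difference",
    "direction_to_array_step",
]


def wrap_nematic(theta_deg):
    """Wrap angles (degrees) to the nematic range (-90, 90]."""
    t = np.asarray(theta_deg, dtype=float) % 180.0
    t = np.where(t > 90.0, t - 180.0, t)
    if np.ndim(theta_deg) == 0:
        return float(t)
    return t


def wrap_directional(theta_deg):
    """Wrap angles (degrees) to the directional range (-180, 180]."""
    t = np.asarray(theta_deg, dtype=float) % 360.0
    t = np.where(t > 180.0, t - 360.0, t)
    if np.ndim(theta_deg) == 0:
        return float(t)
    return t


def nematic_difference(a_deg, b_deg):
    """Signed nematic angle difference a - b mapped to (-90, 90]."""
    d = np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)
    # map to (-90, 90]: negate, wrap to [-90, 90), negate back
    out = -((-d + 90.0) % 180.0 - 90.0)
    if np.ndim(d) == 0:
        return float(out)
    return out


def direction_to_array_step(theta_deg):
    """Unit step (drow, dcol) for a direction given in the y-up convention."""
    t = np.deg2rad(theta_deg)
    return -np.sin(t), np.cos(t)
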