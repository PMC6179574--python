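"""Orientation-angle bookkeeping.

Grating orientation is periodic over 180 deg (a grating rotated by 180 deg is
the same grating), measured clockwise from vertical on the half-open interval
[0, 180).  All circular statistics operate on the *doubled* angle, which maps
the orientation half-circle onto the full circle so that standard directional
formulas apply.  Every conversion between the two spaces goes through this
module so the doubling convention lives in exactly one place.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_orientation",
    "to_doubled_radians",
    "from_doubled_radians",
    "orientation_difference",
]


def wrap_orientation(deg):
    """Wrap orientations (degrees) into [0, 180)."""
    return np.asarray(deg, dtype=float) % 180.0


def to_doubled_radians(deg):
    """Map orientation in degrees to doubled-angle radians in [0, 2*pi)."""
    return np.deg2rad(2.0 * np.asarray(deg, dtype=float))


def from_doubled_radians(rad):
    """Map doubled-angle radians back to orientation degrees in [0, 180)."""
    return (np.rad2deg(np.asarray(rad, dtype=float)) / 2.0) % 180.0


def orientation_difference(a_deg, b_deg):
    """Signed acute difference a - b on the orientation circle, in (-90, 90]."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.where(d > 90.0, d - 180.0, d)
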