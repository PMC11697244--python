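"""Angle wrapping and circular statistics for director (mod-180) quantities.

Fiber orientations are directors: an optic axis at phi and at phi + 180 deg
is the same physical axis, so all orientation arithmetic lives on a circle of
period 180 deg.  Harmonic phases of the polarization sweep live on the
*doubled*-angle circle (period 360 deg there), since the signal is a function
of cos 2(theta - phi) only.  Conventions used throughout the package:

* orientation domain: (-90, 90] degrees
* doubled-angle domain: (-180, 180] degrees
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_orientation",
    "wrap_doubled",
    "wrap_pi",
    "orientation_diff",
    "doubled_diff",
    "circular_mean_orientation",
    "orientation_resultant",
]


def wrap_orientation(angle_deg):
    """Wrap angles (degrees) to the director domain (-90, 90]."""
    w = np.asarray(angle_deg, dtype=float) % 180.0
    out = np.where(w > 90.0, w - 180.0, w)
    return out if out.ndim else float(out)


def wrap_doubled(angle_deg):
    """Wrap doubled-angle phases (degrees) to (-180, 180]."""
    w = np.asarray(angle_deg, dtype=float) % 360.0
    out = np.where(w > 180.0, w - 360.0, w)
    return out if out.ndim else float(out)


def wrap_pi(angle_rad):
    """Wrap radians to [-pi, pi); used for squared phase residuals."""
    return (np.asarray(angle_rad, dtype=float) + np.pi) % (2.0 * np.pi) - np.pi


def orientation_diff(a_deg, b_deg):
    """Signed director difference a - b wrapped to (-90, 90] degrees."""
    return wrap_orientation(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def doubled_diff(a_deg, b_deg):
    """Signed doubled-angle difference a - b wrapped to (-180, 180] degrees."""
    return wrap_doubled(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float))


def orientation_resultant(phi_deg, weights=None):
    """Mean resultant vector of orientations on the doubled circle.

    Returns the complex mean of exp(2i*phi); its modulus in [0, 1] measures
    concentration (1 = all parallel, 0 = isotropic or antipodal mixture).
    """
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    z = np.exp(2j * phi)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        return np.sum(w * z) / np.sum(w)
    return np.mean(z)


def circular_mean_orientation(phi_deg, weights=None, min_resultant=1e-6):
    """Circular mean of director angles, in (-90, 90] degrees.

    Computed on the doubled circle and halved.  Returns ``nan`` when the
    resultant length is below ``min_resultant`` (e.g. an equal mix of two
    perpendicular orientations), since the mean direction is then undefined.
    """
    r = orientation_resultant(phi_deg, weights)
    if np.abs(r) < min_resultant:
        return float("nan")
    return float(wrap_orientation(np.rad2deg(np.angle(r)) / 2.0))
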