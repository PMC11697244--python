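"""Orientation statistics, error metrics and figure-style outputs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import (
    circular_mean_orientation,
    orientation_diff,
    orientation_resultant,
    wrap_orientation,
)

__all__ = [
    "OrientationSummary",
    "orientation_histogram",
    "angular_error",
    "depth_profile_figure",
]


@dataclass
class OrientationSummary:
    """Histogram and circular statistics of a fiber-orientation map ROI.

    Circular statistics are computed on doubled angles (directors) and
    halved; ``circular_mean`` is NaN when the resultant vanishes (e.g. equal
    amounts of two perpendicular orientations).
    """

    counts: np.ndarray
    bin_edges: np.ndarray  # deg, spanning (-90, 90]
    circular_mean: float  # deg
    circular_std: float  # deg
    resultant: float  # |mean exp(2i*phi)| in [0, 1]
    roi: tuple | None
    n_pixels: int


def orientation_histogram(phi_map, mask=None, roi=None, bin_width: float = 5.0) -> OrientationSummary:
    """Histogram of unmasked orientations in an ROI with circular summary stats.

    ``roi`` is a pair of slices (depth, lateral) in grid indices; ``bin_width``
    (degrees) must divide 180.
    """
    if abs(180.0 / bin_width - round(180.0 / bin_width)) > 1e-9:
        raise ValueError("bin_width must divide 180 deg")
    phi = np.asarray(phi_map, dtype=float)
    sel = np.isfinite(phi)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    region = np.zeros_like(sel)
    if roi is None:
        region[:] = True
    else:
        region[roi] = True
    vals = wrap_orientation(phi[sel & region])
    if vals.size == 0:
        raise ValueError("no unmasked pixels in the ROI")
    edges = np.arange(-90.0, 90.0 + bin_width / 2, bin_width)
    # (-90, 90]: put exact -90 (impossible after wrap) aside; top edge inclusive
    counts, _ = np.histogram(vals, bins=edges)
    r = orientation_resultant(vals)
    rr = float(np.abs(r))
    mean = circular_mean_orientation(vals)
    # doubled-angle circular std, halved back to orientation degrees
    std = float(np.rad2deg(np.sqrt(max(-2.0 * np.log(max(rr, 1e-300)), 0.0))) / 2.0)
    return OrientationSummary(
        counts=counts,
        bin_edges=edges,
        circular_mean=mean,
        circular_std=std,
        resultant=rr,
        roi=roi,
        n_pixels=int(vals.size),
    )


def angular_error(phi_est_map, phi_true_map, mask=None) -> float:
    """Root-mean-square director error [deg], differences wrapped to (-90, 90]."""
    est = np.asarray(phi_est_map, dtype=float)
    true = np.asarray(phi_true_map, dtype=float)
    if est.shape != true.shape:
        raise ValueError("maps must share a grid")
    sel = np.isfinite(est) & np.isfinite(true)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    if not sel.any():
        raise ValueError("no overlapping unmasked pixels")
    d = orientation_diff(est[sel], true[sel])
    return float(np.sqrt(np.mean(np.square(d))))


def depth_profile_figure(spectral, estimates, column: int, grid=None, truth=None):
    """Depth profiles of eta, phi, psi (top) and xi, alpha, beta (bottom).

    Mirrors the single-A-line diagnostic view: raw harmonic phase vs the
    recovered absorption and fluence phases, and the corresponding
    modulation amplitudes.  Returns a matplotlib Figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nz = spectral.h1_phase.shape[0]
    z = grid.z_centers * 10.0 if grid is not None else np.arange(nz)  # mm
    zlabel = "depth [mm]" if grid is not None else "depth [cells]"

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 7), sharex=True)
    ax1.plot(z, wrap_orientation(spectral.h1_phase[:, column] / 2.0), ".-", label="raw H1 phase / 2")
    ax1.plot(z, estimates.phi_map[:, column], ".-", label="phi (optic axis)")
    ax1.plot(z, estimates.psi_map[:, column], ".-", label="psi (fluence)")
    if truth is not None:
        ax1.plot(z, truth.phi_map[:, column], "k--", lw=1, label="true phi")
    ax1.set_ylabel("orientation [deg]")
    ax1.legend(fontsize=8)

    ax2.plot(z, spectral.xi[:, column], ".-", label="xi (H1/DC)")
    ax2.plot(z, estimates.alpha_map[:, column], ".-", label="alpha (fluence)")
    ax2.plot(z, estimates.beta_map[:, column], ".-", label="beta (dichroism)")
    ax2.set_xlabel(zlabel)
    ax2.set_ylabel("modulation")
    ax2.legend(fontsize=8)
    fig.tight_layout()
    return fig
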