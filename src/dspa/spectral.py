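"""Harmonic demodulation of polarization sweeps.

A dichroic pixel's pressure as a function of the polarization angle theta is
the product of two cosine modulations and therefore decomposes into a DC
term, a fundamental at cos 2*theta (H1) and a second harmonic at cos 4*theta
(H2):

    p_DC = p_bar * (1 + (alpha*beta/2) cos 2(phi - psi))
    p_H1 = p_bar * [beta cos(2 phi - 2 theta) + alpha cos(2 psi - 2 theta)]
    p_H2 = p_bar * (alpha*beta/2) cos(2(phi + psi) - 4 theta)

The estimator consumes the normalized fundamental observables

    xi  = |H1| / p_mean          (p_mean: the DC estimate of p_bar)
    eta = phase of H1            (doubled-angle degrees, (-180, 180])

xi equals the continuous-transform amplitude of the fundamental divided by
pi*p_bar, up to the O(alpha*beta/2) bias of using the DC term for p_bar.

Demodulation is a per-pixel FFT over an integer number of modulation
periods: when the sweep's end angle duplicates the start modulo 180 deg
(e.g. 0-1080 deg inclusive), the final sample is dropped (109 -> 108
samples, fundamental bin 6), which makes the single-bin estimates leakage
free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import wrap_doubled, wrap_orientation
from .forward import SweepStack
from .phantom import GridSpec

__all__ = [
    "SpectralMaps",
    "energy_correct",
    "polarization_spectrum",
    "h1_closed_form",
]


@dataclass
class SpectralMaps:
    """Per-pixel DC/H1/H2 amplitudes and phases of the polarization sweep.

    Phases follow the convention that a component is A*cos(2*theta - delta)
    (H1) or A*cos(4*theta - delta2) (H2); ``h1_phase`` stores delta in the
    doubled-angle domain (-180, 180], ``h2_phase`` stores delta2/2 wrapped to
    the orientation director domain (comparable to phi + psi mod 180).
    """

    p_mean: np.ndarray
    h1_amp: np.ndarray
    h1_phase: np.ndarray  # eta, doubled-angle deg
    h2_amp: np.ndarray
    h2_phase: np.ndarray  # deg, director domain
    xi: np.ndarray
    n_cycles: int
    grid: GridSpec | None = None

    @property
    def eta(self) -> np.ndarray:
        return self.h1_phase


def energy_correct(stack: SweepStack) -> SweepStack:
    """Divide each acquisition by its recorded pulse energy; energies reset to 1.

    Exactly inverts the multiplicative jitter of the acquisition model.
    """
    if np.any(stack.energies <= 0):
        raise ValueError("cannot correct with nonpositive pulse energies")
    out = stack.copy()
    out.data = out.data / out.energies[None, None, :]
    out.energies = np.ones_like(out.energies)
    return out


def _integer_period_window(thetas: np.ndarray) -> tuple[int, float]:
    """Number of samples to keep and the uniform step, or raise."""
    if thetas.size < 2:
        raise ValueError("need at least 2 acquisitions")
    steps = np.diff(thetas)
    step = steps[0]
    if not np.allclose(steps, step, rtol=0, atol=1e-9 * max(1.0, abs(step))):
        raise ValueError("polarization angles must be uniformly spaced")
    if step <= 0:
        raise ValueError("polarization angles must be increasing")
    if step > 90.0:
        raise ValueError(
            f"theta step {step} deg gives fewer than 2 samples per 180 deg "
            "modulation period (aliasing)"
        )
    n = thetas.size
    while n > 0 and abs((n * step) % 180.0) > 1e-9 and abs((n * step) % 180.0 - 180.0) > 1e-9:
        n -= 1
    if n * step < 180.0 - 1e-9:
        raise ValueError("sweep does not span a full 180 deg modulation period")
    return n, step


def polarization_spectrum(stack: SweepStack) -> SpectralMaps:
    """Per-pixel DC, fundamental and second-harmonic amplitude/phase via FFT.

    Requires uniformly spaced angles; trims the window to an integer number
    of 180 deg modulation periods (dropping duplicate endpoint samples) so
    the fundamental falls exactly on one FFT bin.
    """
    n, step = _integer_period_window(stack.thetas)
    data = stack.data[:, :, :n]
    thetas = stack.thetas[:n]
    k = int(round(n * step / 180.0))  # fundamental cycle count = bin index

    spec = np.fft.fft(data, axis=2) / n
    p_mean = spec[:, :, 0].real
    theta0 = thetas[0]

    c1 = spec[:, :, k]
    h1_amp = 2.0 * np.abs(c1)
    # component A cos(2 theta_t - delta): FFT bin carries e^{-i(delta - 2 theta0)}
    h1_phase = wrap_doubled(-np.rad2deg(np.angle(c1)) + 2.0 * theta0)

    if 2 * k < n - (n % 2 == 0):  # H2 bin must be below (or at) Nyquist
        c2 = spec[:, :, 2 * k]
        h2_amp = 2.0 * np.abs(c2)
        delta2 = -np.rad2deg(np.angle(c2)) + 4.0 * theta0
    else:
        h2_amp = np.zeros_like(h1_amp)
        delta2 = np.zeros_like(h1_amp)
    h2_phase = wrap_orientation(delta2 / 2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        xi = np.where(p_mean > 0, h1_amp / np.where(p_mean > 0, p_mean, 1.0), 0.0)
    return SpectralMaps(
        p_mean=p_mean,
        h1_amp=h1_amp,
        h1_phase=h1_phase,
        h2_amp=h2_amp,
        h2_phase=h2_phase,
        xi=xi,
        n_cycles=k,
        grid=stack.grid,
    )


def h1_closed_form(alpha, beta, phi, psi, indeterminate_tol: float = 1e-12):
    """Model fundamental observables (xi, eta) from (alpha, beta, phi, psi).

    xi_model  = sqrt(alpha^2 + beta^2 + 2 alpha beta cos 2(phi - psi))
    eta_model = atan2(alpha sin 2psi + beta sin 2phi,
                      alpha cos 2psi + beta cos 2phi)   [doubled-angle deg]

    Angles in degrees (phi, psi orientation domain).  Where the two
    modulations cancel exactly (alpha = beta, phi - psi = +-90 deg) the
    amplitude is 0 and the phase is indeterminate: eta_model is NaN there.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(alpha < 0) or np.any(beta < 0):
        raise ValueError("alpha and beta must be nonnegative")
    v = alpha * np.exp(2j * np.deg2rad(psi)) + beta * np.exp(2j * np.deg2rad(phi))
    xi_model = np.abs(v)
    eta_model = np.where(
        xi_model > indeterminate_tol, wrap_doubled(np.rad2deg(np.angle(v))), np.nan
    )
    if np.ndim(xi_model) == 0:
        return float(xi_model), float(eta_model)
    return xi_model, eta_model
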