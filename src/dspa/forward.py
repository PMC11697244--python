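"""Forward model: polarization-dependent absorption, fluence, pressure, sweeps.

The initial photoacoustic pressure of a dichroic absorber illuminated with
linearly polarized light at angle theta is

    p(r, theta) = Gamma * eta_th * F(r, theta) * mu_a(r, theta),

with the anisotropic absorption

    mu_a(r, theta) = mu_a_bar(r) + (delta_mu_a(r)/2) * cos 2(theta - phi(r))

and the ballistic (scattering-free) fluence

    F(r, theta) = F0 * exp(-integral of mu_a(r', theta) along the beam path).

Expanding the dichroic part of the exponential to first order factorizes the
pressure into the product of two cosine modulations,

    p = p_bar * (1 + alpha cos(2 theta - 2 psi)) * (1 + beta cos(2 theta - 2 phi)),

where beta = delta_mu_a / (2 mu_a_bar) is the local dichroism ratio and
(alpha, psi) are the amplitude and phase of the *accumulated* fluence
modulation.  alpha is kept nonnegative; the expansion's minus sign is
absorbed into psi, so in a homogeneous medium phi = psi + 90 deg (fluence and
absorption modulations in counter-phase).

Beams travel straight down the depth axis, one lateral column at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .angles import wrap_orientation
from .phantom import GridSpec, TissuePhantom

__all__ = [
    "SweepConfig",
    "NoiseConfig",
    "SweepStack",
    "absorption_map",
    "absorption_at",
    "fluence_exact",
    "fluence_approx",
    "accumulated_fluence_modulation",
    "p_bar_map",
    "pressure_map",
    "acquire_sweep",
    "calibrate_additive_sigma",
]


@dataclass(frozen=True)
class SweepConfig:
    """Polarization-sweep protocol.

    Defaults follow the acquisition used throughout: three full half-wave
    plate revolutions, 0 to 1080 deg in 10 deg steps (109 acquisitions),
    40-frame averaging, 5 mJ/cm^2 surface fluence.
    """

    theta_start: float = 0.0
    theta_end: float = 1080.0
    theta_step: float = 10.0
    n_averages: int = 40
    fluence_0: float = 5.0  # mJ/cm^2

    def __post_init__(self):
        if self.theta_step <= 0:
            raise ValueError("theta_step must be positive")
        span = self.theta_end - self.theta_start
        n = span / self.theta_step
        if abs(n - round(n)) > 1e-9 or n < 0:
            raise ValueError("(theta_end - theta_start) must be a nonnegative multiple of theta_step")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")

    @property
    def n_acquisitions(self) -> int:
        return int(round((self.theta_end - self.theta_start) / self.theta_step)) + 1

    @property
    def thetas(self) -> np.ndarray:
        return self.theta_start + self.theta_step * np.arange(self.n_acquisitions)


@dataclass(frozen=True)
class NoiseConfig:
    """Additive per-frame noise and multiplicative pulse-energy jitter.

    ``additive_sigma`` is the std of the white noise on a *single* frame in
    pressure units; frame averaging divides it by sqrt(n_averages).
    ``energy_jitter_cv`` is the coefficient of variation of the recorded
    pulse energy (mean 1); the jitter multiplies the whole frame, matching a
    global pulse-energy fluctuation.
    """

    additive_sigma: float = 0.0
    energy_jitter_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.additive_sigma < 0 or self.energy_jitter_cv < 0:
            raise ValueError("noise parameters must be nonnegative")


@dataclass
class SweepStack:
    """Acquired (or simulated) polarization sweep.

    data has shape (n_depth, n_lateral, T); thetas and energies have length T.
    """

    data: np.ndarray
    thetas: np.ndarray
    energies: np.ndarray
    grid: GridSpec
    ground_truth: TissuePhantom | None = None
    sweep: SweepConfig | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_depth, n_lateral, T)")
        t = self.data.shape[2]
        if self.thetas.shape != (t,) or self.energies.shape != (t,):
            raise ValueError("thetas/energies length must match the acquisition axis")
        if np.any(self.energies <= 0):
            raise ValueError("recorded pulse energies must be positive")

    @property
    def n_acquisitions(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "SweepStack":
        return replace(self, data=self.data.copy(), energies=self.energies.copy())


# ---------------------------------------------------------------------------
# absorption and fluence
# ---------------------------------------------------------------------------

def absorption_map(phantom: TissuePhantom, theta: float) -> np.ndarray:
    """mu_a(r, theta) over the whole grid, in 1/cm."""
    phi = np.nan_to_num(phantom.phi_map, nan=0.0)  # water has delta_mu_a = 0
    ang = np.deg2rad(2.0 * (theta - phi))
    return phantom.mu_a_mean_map + 0.5 * phantom.delta_mu_a_map * np.cos(ang)


def absorption_at(phantom: TissuePhantom, pixel: tuple[int, int], theta: float) -> float:
    """Anisotropic absorption coefficient at one pixel for polarization theta."""
    i, j = pixel
    nz, nx = phantom.grid.shape
    if not (0 <= i < nz and 0 <= j < nx):
        raise IndexError(f"pixel {pixel} outside grid {phantom.grid.shape}")
    return float(absorption_map(phantom, theta)[i, j])


def _cumulative_path_integral(integrand: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Cumulative line integral from the surface to each depth-cell center.

    Trapezoid rule over [0, z_0, ..., z_{n-1}] per column, with the surface
    sample taken equal to the first cell's value (the beam enters the medium
    at the top of cell 0).
    """
    z = np.concatenate(([0.0], grid.z_centers))
    vals = np.vstack([integrand[:1, :], integrand])
    return cumulative_trapezoid(vals, x=z, axis=0)


def fluence_exact(phantom: TissuePhantom, theta: float, f0: float, mu_s_prime: float = 0.0) -> np.ndarray:
    """Ballistic fluence map with the full dichroic exponential.

    ``mu_s_prime`` optionally adds a reduced-scattering term to the
    attenuation (effective-attenuation substitution); it affects fluence
    decay only, not the local absorption that generates pressure.
    """
    mu = absorption_map(phantom, theta) + mu_s_prime
    return f0 * np.exp(-_cumulative_path_integral(mu, phantom.grid))


def accumulated_fluence_modulation(phantom: TissuePhantom) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel accumulated fluence-modulation amplitude alpha and phase psi.

    alpha(z) >= 0 is the magnitude of the path integral of
    (delta_mu_a/2) * cos 2(theta - phi); psi [deg, (-90, 90]] is its phase in
    the orientation domain, with the expansion's minus sign absorbed (so a
    homogeneous layer gives psi = phi + 90 deg).
    """
    phi = np.nan_to_num(phantom.phi_map, nan=0.0)
    w = 0.5 * phantom.delta_mu_a_map
    c = _cumulative_path_integral(w * np.cos(np.deg2rad(2 * phi)), phantom.grid)
    s = _cumulative_path_integral(w * np.sin(np.deg2rad(2 * phi)), phantom.grid)
    d = c + 1j * s
    alpha = np.abs(d)
    # modulation is -|d| cos(2 theta - arg d) = |d| cos(2 theta - (arg d + pi))
    psi = wrap_orientation((np.rad2deg(np.angle(d)) + 180.0) / 2.0)
    return alpha, psi


def fluence_approx(
    phantom: TissuePhantom, theta: float, f0: float, mu_s_prime: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First-order (truncated Maclaurin) fluence and its (alpha, psi) maps.

    Returns ``F0 * exp(-int mu_a_bar) * (1 + alpha cos(2 theta - 2 psi))``
    together with the accumulated modulation amplitude and phase.
    """
    mean_att = _cumulative_path_integral(phantom.mu_a_mean_map + mu_s_prime, phantom.grid)
    alpha, psi = accumulated_fluence_modulation(phantom)
    mod = alpha * np.cos(np.deg2rad(2.0 * theta - 2.0 * psi))
    return f0 * np.exp(-mean_att) * (1.0 + mod), alpha, psi


def p_bar_map(phantom: TissuePhantom, f0: float, mu_s_prime: float = 0.0) -> np.ndarray:
    """Polarization-independent mean pressure Gamma*eta_th*mu_a_bar*F0*exp(-int mu_a_bar)."""
    mean_att = _cumulative_path_integral(phantom.mu_a_mean_map + mu_s_prime, phantom.grid)
    return phantom.grueneisen_eta * phantom.mu_a_mean_map * f0 * np.exp(-mean_att)


def pressure_map(
    phantom: TissuePhantom,
    theta: float,
    f0: float,
    mode: str = "approx",
    mu_s_prime: float = 0.0,
) -> np.ndarray:
    """Initial-pressure map p = Gamma*eta_th * F(theta) * mu_a(theta).

    mode='approx' uses the truncated fluence, which makes p identically the
    product of the two cosine modulations around p_bar; mode='exact' keeps
    the full dichroic exponential.
    """
    if mode == "exact":
        flu = fluence_exact(phantom, theta, f0, mu_s_prime)
    elif mode == "approx":
        flu = fluence_approx(phantom, theta, f0, mu_s_prime)[0]
    else:
        raise ValueError("mode must be 'exact' or 'approx'")
    return phantom.grueneisen_eta * flu * absorption_map(phantom, theta)


# ---------------------------------------------------------------------------
# sweep acquisition
# ---------------------------------------------------------------------------

def acquire_sweep(
    phantom: TissuePhantom,
    sweep: SweepConfig | None = None,
    noise: NoiseConfig | None = None,
    mode: str = "approx",
    mu_s_prime: float = 0.0,
) -> SweepStack:
    """Simulate a full polarization sweep with pulse-energy jitter and noise.

    Each acquisition t at angle theta_t is ``energies[t] * p(theta_t)`` plus
    the mean of ``n_averages`` additive white-noise draws (simulated as a
    single draw with std additive_sigma/sqrt(n_averages); distributionally
    identical to storing and averaging frames).  Energies are drawn once per
    acquisition from a lognormal with mean 1 and the configured CV, so they
    are always positive.  Fully reproducible from the seed.
    """
    sweep = sweep or SweepConfig()
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(noise.seed)
    thetas = sweep.thetas
    t_count = thetas.size

    if noise.energy_jitter_cv > 0:
        sigma_ln = np.sqrt(np.log1p(noise.energy_jitter_cv**2))
        energies = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=t_count)
    else:
        energies = np.ones(t_count)

    data = np.empty(phantom.grid.shape + (t_count,))
    for t, theta in enumerate(thetas):
        data[:, :, t] = energies[t] * pressure_map(
            phantom, theta, sweep.fluence_0, mode=mode, mu_s_prime=mu_s_prime
        )
    if noise.additive_sigma > 0:
        scale = noise.additive_sigma / np.sqrt(sweep.n_averages)
        data += rng.normal(0.0, scale, size=data.shape)
    return SweepStack(
        data=data,
        thetas=thetas,
        energies=energies,
        grid=phantom.grid,
        ground_truth=phantom,
        sweep=sweep,
    )


def calibrate_additive_sigma(
    phantom: TissuePhantom,
    sweep: SweepConfig | None = None,
    target_surface_snr: float = 20.0,
    mode: str = "approx",
) -> float:
    """Per-frame additive sigma giving a target surface H1 amplitude / noise ratio.

    The background H1 amplitude of a pure-noise pixel is Rayleigh distributed
    with scale s*sqrt(2/N) (s the averaged per-frame noise std, N the number
    of demodulated samples), hence std s*sqrt(2/N)*sqrt(2 - pi/2).  The
    surface H1 amplitude is p_bar_surface * (beta - alpha_surface).  Solving
    amplitude = target_snr * background_std for the single-frame sigma.
    """
    sweep = sweep or SweepConfig()
    # largest integer-period window the demodulator will use
    t_total = sweep.n_acquisitions
    n = t_total
    while n > 0 and (n * sweep.theta_step) % 180.0 != 0:
        n -= 1
    if n == 0:
        raise ValueError("sweep span does not cover an integer number of modulation periods")
    pbar = p_bar_map(phantom, sweep.fluence_0)
    alpha, _ = accumulated_fluence_modulation(phantom)
    beta = phantom.beta_map
    tissue_rows = np.where(phantom.tissue_mask.any(axis=1))[0]
    surf = tissue_rows[0]
    amp = np.median(pbar[surf] * np.abs(beta[surf] - alpha[surf]))
    rayleigh_std_factor = np.sqrt(2.0 / n) * np.sqrt(2.0 - np.pi / 2.0)
    s_frame_avg = amp / (target_surface_snr * rayleigh_std_factor)
    return float(s_frame_avg * np.sqrt(sweep.n_averages))
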