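"""Depth-sequential constrained inversion of (xi, eta) into (phi, psi, alpha, beta).

Per pixel the fundamental observables obey

    eta = atan2(alpha sin 2psi + beta sin 2phi, alpha cos 2psi + beta cos 2phi)
    xi  = sqrt(alpha^2 + beta^2 + 2 alpha beta cos 2(phi - psi)),

two equations in four unknowns.  The system is closed by physics:

* at the tissue surface the fluence modulation is negligible, so phi = eta/2
  and beta = xi there;
* beta (the dichroism ratio) is assumed constant along a column;
* alpha and psi accumulate along the beam and can only evolve smoothly, so
  each depth is fitted seeded and box-constrained by the previous depth;
* abrupt *simultaneous* changes of eta and xi can only come from a change of
  the optic axis phi (a new layer), at which point phi is re-seeded from the
  current eta and released;
* a near-180 deg (doubled-angle) eta flip while alpha is within tolerance of
  beta is the fluence modulation overcoming the absorption modulation -- phi
  is held fixed and the flip is attributed to the fluence term;
* if alpha returns to ~0 below the surface the accumulated fluence vector
  has passed through zero and psi advances by 90 deg.

The per-pixel fit minimizes the squared residual

    eps = wrap(eta_obs - eta_model)^2 + (xi_obs - xi_model)^2

(phase residual wrapped on the doubled-angle circle, in radians) with a
bound-constrained quasi-Newton solver using analytic gradients, stopping at
first-order (projected-gradient) optimality <= optimality_tol.

Low-modulation pixels are masked beforehand by the Rose detectability
criterion (amplitude < rose_k standard deviations of the background noise),
with an exception for cancellation points: a depth-local amplitude minimum
whose neighbouring phases differ by ~180 deg (doubled angle) is kept, since
alpha ~ beta there and the pixel carries information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .angles import wrap_doubled, wrap_orientation, wrap_pi
from .phantom import GridSpec
from .spectral import SpectralMaps, h1_closed_form

__all__ = [
    "FitConfig",
    "EstimateMaps",
    "SCENARIO",
    "rose_mask",
    "objective",
    "estimate_aline",
    "estimate_image",
    "interpolate_masked",
]

# scenario codes written into EstimateMaps.scenario_map
SCENARIO = {
    "masked": 0,
    "surface": 1,
    "continuity": 2,
    "fluence_flip": 3,
    "layer_change": 4,
    "psi_advance": 5,
    "failed": -1,
}


@dataclass(frozen=True)
class FitConfig:
    """All inversion knobs.

    noise_sigma_source: explicit background std (float) or a background
    region ((row0, row1), (col0, col1)) of the maps from which the std of
    the H1 amplitude is measured.  Continuity bounds are per depth step;
    angles in degrees.
    """

    rose_k: float = 5.0
    noise_sigma_source: float | tuple | None = None
    beta_mode: str = "per-column-surface"  # or "fixed-from-surface" (global)
    continuity_alpha: float = 0.01
    continuity_psi: float = 15.0
    continuity_phi: float = 2.0
    abrupt_eta_thresh: float = 60.0  # doubled-angle deg
    abrupt_xi_relthresh: float = 0.2
    alpha_beta_tie_tol: float = 0.1  # relative
    optimality_tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self):
        for name in (
            "rose_k",
            "continuity_alpha",
            "continuity_psi",
            "continuity_phi",
            "abrupt_eta_thresh",
            "abrupt_xi_relthresh",
            "alpha_beta_tie_tol",
            "optimality_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta_mode not in ("per-column-surface", "fixed-from-surface"):
            raise ValueError("beta_mode must be 'per-column-surface' or 'fixed-from-surface'")


@dataclass
class EstimateMaps:
    """Recovered per-pixel parameters plus diagnostics.

    phi/psi in degrees (director domain); mask is True where an estimate was
    produced; scenario_map records which sequential rule fired (see SCENARIO).
    """

    phi_map: np.ndarray
    psi_map: np.ndarray
    alpha_map: np.ndarray
    beta_map: np.ndarray
    mask: np.ndarray
    objective_map: np.ndarray
    scenario_map: np.ndarray
    grid: GridSpec | None = None
    phi_interp: np.ndarray | None = None


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def background_sigma(spectral: SpectralMaps, cfg: FitConfig) -> float:
    src = cfg.noise_sigma_source
    if src is None:
        raise ValueError(
            "FitConfig.noise_sigma_source must give an explicit background std "
            "or a background region ((row0,row1),(col0,col1))"
        )
    if np.isscalar(src):
        return float(src)
    (r0, r1), (c0, c1) = src
    region = spectral.h1_amp[r0:r1, c0:c1]
    if region.size == 0:
        raise ValueError("background region is empty")
    return float(np.std(region))


def rose_mask(spectral: SpectralMaps, cfg: FitConfig) -> np.ndarray:
    """Validity mask: True where the modulation is detectable.

    A pixel fails the Rose criterion when h1_amp < rose_k * sigma_background.
    Exception: a depth-local amplitude minimum whose adjacent (above/below)
    phases differ by ~180 deg doubled-angle is retained -- the signal vanishes
    there because the fluence and absorption modulations cancel (alpha ~ beta
    in counter-phase), not because there is no tissue.
    """
    sigma = background_sigma(spectral, cfg)
    amp = spectral.h1_amp
    eta = spectral.h1_phase
    valid = amp >= cfg.rose_k * sigma
    nz, nx = amp.shape
    # Exception pass.  The cancellation dip can span several cells, inside
    # which both amplitude and phase are noise; the flip is therefore judged
    # between the nearest *detectable* phases above and below the candidate
    # pixel, and only the dip's amplitude minimum is retained.
    for j in range(nx):
        col_valid = np.where(valid[:, j])[0]
        if col_valid.size < 2:
            continue
        # masked runs strictly between detectable pixels
        for lo, hi in zip(col_valid[:-1], col_valid[1:]):
            if hi - lo < 2:
                continue
            flip = abs(wrap_doubled(eta[hi, j] - eta[lo, j]))
            if abs(flip) < 180.0 - cfg.abrupt_eta_thresh:
                continue
            run = np.arange(lo + 1, hi)
            valid[run[np.argmin(amp[run, j])], j] = True
    return valid


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def objective(alpha, psi, phi, beta, eta_obs, xi_obs) -> float:
    """Squared model-data mismatch eps at one pixel.

    Angles in degrees (psi, phi orientation; eta_obs doubled-angle).  The
    phase residual is wrapped on the doubled-angle circle and squared in
    radians so both terms share the same scale.
    """
    eps, _ = _eps_and_grad(
        np.array([alpha, np.deg2rad(psi), np.deg2rad(phi)]),
        beta,
        np.deg2rad(eta_obs),
        xi_obs,
    )
    return float(eps)


def _eps_and_grad(x: np.ndarray, beta: float, eta_obs_rad: float, xi_obs: float):
    """eps and its gradient wrt (alpha, psi_rad, phi_rad); angles orientation rad."""
    a, psi, phi = x
    e_psi = np.exp(2j * psi)
    e_phi = np.exp(2j * phi)
    v = a * e_psi + beta * e_phi
    m2 = max(v.real * v.real + v.imag * v.imag, 1e-300)
    xi_m = np.sqrt(m2)
    eta_m = np.arctan2(v.imag, v.real)
    r1 = wrap_pi(eta_obs_rad - eta_m)
    r2 = xi_obs - xi_m
    eps = r1 * r1 + r2 * r2

    cv = v.conjugate()

    def partial(dv):
        z = cv * dv
        d_xi = z.real / xi_m
        d_eta = z.imag / m2
        return -2.0 * r1 * d_eta - 2.0 * r2 * d_xi

    grad = np.array([partial(e_psi), partial(2j * a * e_psi), partial(2j * beta * e_phi)])
    return eps, grad


# ---------------------------------------------------------------------------
# sequential A-line estimation
# ---------------------------------------------------------------------------

@dataclass
class _AlineResult:
    phi: np.ndarray
    psi: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    scenario: np.ndarray
    objective: np.ndarray
    valid: np.ndarray


def _fit_pixel(cfg, beta, eta_obs_deg, xi_obs, a0, psi0, phi0, bounds):
    res = minimize(
        _eps_and_grad,
        np.array([a0, psi0, phi0]),
        args=(beta, np.deg2rad(eta_obs_deg), xi_obs),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": cfg.max_iter, "ftol": 1e-15, "gtol": cfg.optimality_tol},
    )
    return res


def estimate_aline(
    xi_profile, eta_profile, mask_profile, cfg: FitConfig, beta_fixed=None, xi_sigma=None
):
    """Sequential surface-to-depth inversion of one A-line.

    Parameters are the demodulated xi (normalized H1 amplitude), eta (H1
    phase, doubled-angle degrees) and validity-mask profiles ordered from the
    illuminated surface downward.  ``beta_fixed`` overrides the per-column
    surface estimate of the dichroism ratio.  ``xi_sigma`` (scalar or
    per-depth) is the 1-sigma measurement uncertainty of xi; when given, an
    eta/xi variation only counts as abrupt if it is also significant at
    rose_k sigma, so noise cannot fake a layer change.

    Returns per-depth (phi, psi, alpha, beta, scenario, objective, valid)
    arrays; masked or failed depths carry NaN parameters.
    """
    xi = np.asarray(xi_profile, dtype=float)
    eta = np.asarray(eta_profile, dtype=float)
    valid_in = np.asarray(mask_profile, dtype=bool)
    n = xi.size
    if xi_sigma is None:
        sig = np.zeros(n)
    else:
        sig = np.broadcast_to(np.asarray(xi_sigma, dtype=float), (n,))
    out = _AlineResult(
        phi=np.full(n, np.nan),
        psi=np.full(n, np.nan),
        alpha=np.full(n, np.nan),
        beta=np.full(n, np.nan),
        scenario=np.zeros(n, dtype=int),
        objective=np.full(n, np.nan),
        valid=np.zeros(n, dtype=bool),
    )
    if not valid_in.any():
        return out

    c_alpha = cfg.continuity_alpha
    c_psi = np.deg2rad(cfg.continuity_psi)
    c_phi = np.deg2rad(cfg.continuity_phi)

    state = None  # (alpha, psi_rad, phi_rad) unwrapped
    beta = beta_fixed
    flu_prev = None  # accumulated fluence vector alpha*exp(2j*psi) at last fit
    flu_step = None  # per-depth-step increment of the fluence vector
    i_last = None
    for i in range(n):
        if not valid_in[i]:
            out.scenario[i] = SCENARIO["masked"]
            continue
        if state is None:
            # S1: surface pixel -- fluence modulation negligible
            phi0 = np.deg2rad(wrap_orientation(eta[i] / 2.0))
            if beta is None:
                beta = float(xi[i])
            state = (0.0, phi0 + np.pi / 2.0, phi0)
            out.phi[i], out.psi[i], out.alpha[i] = np.rad2deg(phi0), np.rad2deg(phi0) + 90.0, 0.0
            out.scenario[i] = SCENARIO["surface"]
            out.objective[i] = objective(
                0.0, np.rad2deg(phi0) + 90.0, np.rad2deg(phi0), beta, eta[i], xi[i]
            )
            out.beta[i] = beta
            out.valid[i] = True
            flu_prev = 0.0 + 0.0j
            i_last = i
            continue

        a_prev, psi_prev, phi_prev = state
        gap = i - i_last  # 1 plus any masked run the march skipped over

        # Seed the fluence state by linear extrapolation of the accumulated
        # fluence vector: its per-step increment is set by the local layer
        # properties and is smooth inside a layer, which closes the otherwise
        # underdetermined (2 observables, 3 unknowns) per-pixel problem and
        # carries the state across masked runs (including the alpha = beta
        # cancellation, where the vector passes near the dichroism circle).
        flu_seed = flu_prev + (flu_step * gap if flu_step is not None else 0.0)
        a_seed = abs(flu_seed)
        if a_seed > 1e-12:
            # e^{2i(psi+pi)} == e^{2i psi}: unwrap the half-angle next to the
            # previous psi track
            psi_seed = 0.5 * np.angle(flu_seed)
            psi_seed += np.pi * np.round((psi_prev - psi_seed) / np.pi)
        else:
            psi_seed = psi_prev
        a_lo = max(0.0, min(a_seed, a_prev) - c_alpha * gap)
        a_hi = max(a_seed, a_prev) + c_alpha * gap

        # classify the pixel against the *predicted* observables, so smooth
        # fluence evolution (even across masked gaps) never looks abrupt
        xi_pred, eta_pred = h1_closed_form(
            a_seed, beta, np.rad2deg(phi_prev), np.rad2deg(psi_seed)
        )
        if np.isnan(eta_pred):
            eta_pred = eta[i]
        # abruptness vs the predicted evolution, and vs the last valid
        # observation (a boundary hidden behind a masked run can leave the
        # predicted phase coincidentally right while the amplitude is not);
        # with a known measurement uncertainty, a variation must also be
        # significant at rose_k sigma to count as abrupt
        sig_eta_deg = np.rad2deg(sig[i] / max(xi[i], 1e-12))  # doubled-angle

        def eta_abrupt(de):
            return de > max(cfg.abrupt_eta_thresh, cfg.rose_k * sig_eta_deg)

        def xi_abrupt(dx_abs, ref):
            return dx_abs > max(cfg.abrupt_xi_relthresh * max(ref, 1e-12), cfg.rose_k * sig[i])

        d_eta = abs(wrap_doubled(eta[i] - eta_pred))
        d_xi = abs(xi[i] - xi_pred)
        d_eta_obs = abs(wrap_doubled(eta[i] - eta[i_last]))
        d_xi_obs = abs(xi[i] - xi[i_last])

        # alpha ~ beta, either predicted by the extrapolated state or evident
        # in the data: with phi held, the fluence magnitude required to
        # explain the observation is |V - beta e^{2i phi}|, and a value close
        # to beta marks the cancellation point where the phase flips and is
        # otherwise ill-determined
        v_obs = xi[i] * np.exp(1j * np.deg2rad(eta[i]))
        a_cf_held = abs(v_obs - beta * np.exp(2j * phi_prev))
        # the alpha ~ beta band widens with the amplitude noise: within it the
        # phase is not trustworthy and holding phi is the only safe move
        tie_tol = max(cfg.alpha_beta_tie_tol * max(beta, 1e-12), cfg.rose_k * sig[i])
        tie = abs(a_seed - beta) <= tie_tol or abs(a_cf_held - beta) <= tie_tol
        layer_change = not tie and (
            (eta_abrupt(d_eta) and xi_abrupt(d_xi, xi_pred))
            or (eta_abrupt(d_eta_obs) and xi_abrupt(d_xi_obs, xi[i_last]))
        )

        def run_branch(psi_center, phi0, phi_bounds):
            # With phi held, the remaining 2-unknown problem has the exact
            # solution F = V - beta*e^{2i phi} (V the observed vector);
            # project it into the continuity boxes and use it as the seed,
            # so phi only moves off its seed when the fluence terms alone
            # cannot explain the data.
            f_cf = v_obs - beta * np.exp(2j * phi0)
            a_cf = abs(f_cf)
            if a_cf > 1e-12:
                psi_cf = 0.5 * np.angle(f_cf)
                psi_cf += np.pi * np.round((psi_center - psi_cf) / np.pi)
            else:
                psi_cf = psi_center
            psi_box = (psi_center - c_psi * gap, psi_center + c_psi * gap)
            a0 = min(max(a_cf, a_lo), a_hi)
            psi0 = min(max(psi_cf, psi_box[0]), psi_box[1])
            return _fit_pixel(
                cfg, beta, eta[i], xi[i], a0, psi0, phi0, [(a_lo, a_hi), psi_box, phi_bounds]
            )

        def unexplained(res):
            # does the fitted model still miss the observation by more than
            # the abruptness margins (and significantly so, given the noise)?
            xi_fit, eta_fit = h1_closed_form(
                res.x[0], beta, np.rad2deg(res.x[2]), np.rad2deg(res.x[1])
            )
            if np.isnan(eta_fit):
                return False
            de = abs(wrap_doubled(eta[i] - eta_fit))
            dx = abs(xi[i] - xi_fit)
            return eta_abrupt(de) or xi_abrupt(dx, xi_fit)

        if tie:
            # S3: alpha within tolerance of beta -- near-cancellation, the
            # phase is ill-determined and any flip belongs to the fluence
            # term; hold phi
            best = run_branch(psi_seed, phi_prev, (phi_prev, phi_prev))
            best_scn = SCENARIO["fluence_flip"]
        else:
            best = run_branch(psi_seed, phi_prev, (phi_prev - c_phi, phi_prev + c_phi))
            best_scn = SCENARIO["continuity"]
            if (
                flu_step is None
                and a_prev <= cfg.alpha_beta_tie_tol * max(beta, 1e-12)
                and unexplained(best)
            ):
                # no increment history yet and the fluence vector is near
                # zero: it may have passed through the origin (psi advances
                # by 90 deg)
                alt = run_branch(
                    psi_seed + np.pi / 2.0, phi_prev, (phi_prev - c_phi, phi_prev + c_phi)
                )
                if alt.fun < best.fun:
                    best, best_scn = alt, SCENARIO["psi_advance"]
            if layer_change and unexplained(best):
                # S4: new layer -- the data are abrupt AND the constrained
                # continuity fit cannot explain them.  phi is re-seeded from
                # the current observation and released: the observed vector
                # is the sum of the (continuous, hence predictable) fluence
                # vector and the local dichroism term beta*e^{2i phi}, so
                # the remainder after subtracting the extrapolated fluence
                # vector points at 2*phi.
                resid = v_obs - flu_seed
                if abs(resid) > 1e-12:
                    phi_seed = 0.5 * np.angle(resid)
                else:
                    phi_seed = np.deg2rad(wrap_orientation(eta[i] / 2.0))
                alt = run_branch(
                    psi_seed, phi_seed, (phi_seed - np.pi / 2.0, phi_seed + np.pi / 2.0)
                )
                if alt.fun < best.fun:
                    best, best_scn = alt, SCENARIO["layer_change"]
        if best is None or not np.all(np.isfinite(best.x)):
            out.scenario[i] = SCENARIO["failed"]
            continue

        a_new, psi_new, phi_new = best.x
        state = (float(a_new), float(psi_new), float(phi_new))
        flu_new = a_new * np.exp(2j * psi_new)
        if i_last is not None and i > i_last:
            flu_step = (flu_new - flu_prev) / (i - i_last)
        flu_prev = flu_new
        i_last = i
        out.phi[i] = np.rad2deg(phi_new)
        out.psi[i] = np.rad2deg(psi_new)
        out.alpha[i] = a_new
        out.beta[i] = beta
        out.scenario[i] = best_scn
        out.objective[i] = float(best.fun)
        out.valid[i] = True

    out.phi = np.where(out.valid, wrap_orientation(out.phi), np.nan)
    out.psi = np.where(out.valid, wrap_orientation(out.psi), np.nan)
    return out


def estimate_image(spectral: SpectralMaps, mask: np.ndarray, cfg: FitConfig) -> EstimateMaps:
    """Column-wise application of the sequential A-line estimator.

    Columns are independent (no lateral regularization); deterministic given
    inputs and config.
    """
    nz, nx = spectral.h1_amp.shape
    mask = np.asarray(mask, dtype=bool)
    maps = EstimateMaps(
        phi_map=np.full((nz, nx), np.nan),
        psi_map=np.full((nz, nx), np.nan),
        alpha_map=np.full((nz, nx), np.nan),
        beta_map=np.full((nz, nx), np.nan),
        mask=np.zeros((nz, nx), dtype=bool),
        objective_map=np.full((nz, nx), np.nan),
        scenario_map=np.zeros((nz, nx), dtype=int),
        grid=spectral.grid,
    )

    # per-pixel xi uncertainty from the background noise level, used to keep
    # noise-driven variations from counting as abrupt
    try:
        sigma_bg = background_sigma(spectral, cfg)
    except ValueError:
        sigma_bg = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        xi_sigma = np.where(spectral.p_mean > 0, sigma_bg / np.where(spectral.p_mean > 0, spectral.p_mean, 1.0), 0.0)

    beta_fixed = None
    if cfg.beta_mode == "fixed-from-surface":
        surface_betas = []
        for j in range(nx):
            col_valid = np.where(mask[:, j])[0]
            if col_valid.size:
                surface_betas.append(spectral.xi[col_valid[0], j])
        if not surface_betas:
            return maps
        beta_fixed = float(np.median(surface_betas))

    for j in range(nx):
        res = estimate_aline(
            spectral.xi[:, j],
            spectral.h1_phase[:, j],
            mask[:, j],
            cfg,
            beta_fixed=beta_fixed,
            xi_sigma=xi_sigma[:, j],
        )
        maps.phi_map[:, j] = res.phi
        maps.psi_map[:, j] = res.psi
        maps.alpha_map[:, j] = res.alpha
        maps.beta_map[:, j] = res.beta
        maps.mask[:, j] = res.valid
        maps.objective_map[:, j] = res.objective
        maps.scenario_map[:, j] = res.scenario
    return maps


def interpolate_masked(phi_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Fill masked orientations by circular-safe linear interpolation along depth.

    Interpolation runs on doubled-angle unit vectors (so 89 deg and -89 deg
    interpolate near +-90 deg, not 0 deg) and re-wraps to (-90, 90].  Masked
    runs touching the top or bottom take the nearest valid value.  Columns
    with no valid pixel stay NaN.
    """
    phi = np.asarray(phi_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = phi.copy()
    nz, nx = phi.shape
    idx = np.arange(nz)
    for j in range(nx):
        good = mask[:, j] & np.isfinite(phi[:, j])
        if not good.any():
            continue
        if good.all():
            continue
        ang = np.deg2rad(2.0 * phi[good, j])
        cos_i = np.interp(idx, idx[good], np.cos(ang))
        sin_i = np.interp(idx, idx[good], np.sin(ang))
        filled = wrap_orientation(np.rad2deg(np.arctan2(sin_i, cos_i)) / 2.0)
        out[~good, j] = filled[~good]
    return out
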