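import numpy as np
import pytest

from dspa.angles import orientation_diff, wrap_orientation
from dspa.estimate import (
    SCENARIO,
    FitConfig,
    estimate_aline,
    estimate_image,
    interpolate_masked,
    objective,
    rose_mask,
)
from dspa.forward import NoiseConfig, SweepConfig, acquire_sweep, calibrate_additive_sigma
from dspa.phantom import GridSpec, tendon_presets
from dspa.spectral import SpectralMaps, energy_correct, polarization_spectrum


def synthetic_spectral(h1_amp, h1_phase):
    h1_amp = np.asarray(h1_amp, dtype=float)
    h1_phase = np.asarray(h1_phase, dtype=float)
    ones = np.ones_like(h1_amp)
    return SpectralMaps(
        p_mean=ones,
        h1_amp=h1_amp,
        h1_phase=h1_phase,
        h2_amp=np.zeros_like(h1_amp),
        h2_phase=np.zeros_like(h1_amp),
        xi=h1_amp,
        n_cycles=6,
    )


class TestRoseMask:
    def test_below_threshold_masked_above_kept(self):
        amp = np.array([[6.0], [4.0], [6.0], [7.0]])
        eta = np.zeros_like(amp)
        sp = synthetic_spectral(amp, eta)
        cfg = FitConfig(noise_sigma_source=1.0)
        mask = rose_mask(sp, cfg)
        np.testing.assert_array_equal(mask[:, 0], [True, False, True, True])

    def test_cancellation_minimum_with_phase_flip_kept(self):
        # amplitude dips to 2 sigma while the phase flips by 180 deg
        # (doubled angle) across the dip: the alpha=beta point is retained
        amp = np.array([[8.0], [2.0], [8.0]])
        eta = np.array([[10.0], [55.0], [-170.0]])
        sp = synthetic_spectral(amp, eta)
        mask = rose_mask(sp, FitConfig(noise_sigma_source=1.0))
        np.testing.assert_array_equal(mask[:, 0], [True, True, True])

    def test_dip_without_flip_stays_masked(self):
        amp = np.array([[8.0], [2.0], [8.0]])
        eta = np.array([[10.0], [55.0], [12.0]])
        sp = synthetic_spectral(amp, eta)
        mask = rose_mask(sp, FitConfig(noise_sigma_source=1.0))
        np.testing.assert_array_equal(mask[:, 0], [True, False, True])

    def test_only_dip_minimum_kept_in_wide_run(self):
        amp = np.array([[9.0], [4.0], [1.0], [3.0], [9.0]])
        eta = np.array([[0.0], [20.0], [90.0], [150.0], [180.0]])
        sp = synthetic_spectral(amp, eta)
        mask = rose_mask(sp, FitConfig(noise_sigma_source=1.0))
        np.testing.assert_array_equal(mask[:, 0], [True, False, True, False, True])

    def test_background_region_source(self):
        rng = np.random.default_rng(0)
        amp = np.full((20, 4), 10.0)
        amp[15:, :] = np.abs(rng.normal(0.0, 1.0, (5, 4)))
        sp = synthetic_spectral(amp, np.zeros_like(amp))
        cfg = FitConfig(noise_sigma_source=((15, 20), (0, 4)))
        mask = rose_mask(sp, cfg)
        assert mask[:15].all()

    def test_missing_sigma_rejected(self):
        sp = synthetic_spectral(np.ones((3, 1)), np.zeros((3, 1)))
        with pytest.raises(ValueError, match="noise_sigma_source"):
            rose_mask(sp, FitConfig())


class TestObjective:
    def test_zero_at_generating_parameters(self):
        from dspa.spectral import h1_closed_form

        xi, eta = h1_closed_form(0.12, 0.05, 35.0, 125.0)
        assert objective(0.12, 125.0, 35.0, 0.05, eta, xi) == pytest.approx(0.0, abs=1e-20)

    def test_surface_case_zero(self):
        # alpha = 0: observations eta = 2 phi, xi = beta fit exactly
        assert objective(0.0, 90.0, 20.0, 0.06, 40.0, 0.06) == pytest.approx(0.0, abs=1e-20)

    def test_pi_wrapped_phase_residual(self):
        # model phase is 180 deg (doubled), observed 0: residual pi in radians
        eps = objective(0.1, 90.0, 0.0, 0.05, 0.0, 0.05)
        assert eps == pytest.approx(np.pi**2, rel=1e-12)

    def test_local_minimum_at_fit_solution(self, noiseless_spectral, noiseless_fit_cfg):
        """Perturbing any single recovered parameter by +-10% does not reduce eps."""
        sp = noiseless_spectral
        mask = rose_mask(sp, noiseless_fit_cfg)
        res = estimate_aline(sp.xi[:, 0], sp.h1_phase[:, 0], mask[:, 0], noiseless_fit_cfg)
        for i in range(5, 30, 5):
            if not res.valid[i]:
                continue
            base = objective(
                res.alpha[i], res.psi[i], res.phi[i], res.beta[i],
                sp.h1_phase[i, 0], sp.xi[i, 0],
            )
            for dp in (0.9, 1.1):
                assert objective(
                    res.alpha[i] * dp, res.psi[i], res.phi[i], res.beta[i],
                    sp.h1_phase[i, 0], sp.xi[i, 0],
                ) >= base - 1e-12
                assert objective(
                    res.alpha[i], res.psi[i] * dp, res.phi[i], res.beta[i],
                    sp.h1_phase[i, 0], sp.xi[i, 0],
                ) >= base - 1e-12
                assert objective(
                    res.alpha[i], res.psi[i], res.phi[i] * dp, res.beta[i],
                    sp.h1_phase[i, 0], sp.xi[i, 0],
                ) >= base - 1e-12


class TestEstimateAline:
    def test_surface_rule(self, noiseless_spectral, noiseless_fit_cfg):
        sp = noiseless_spectral
        mask = rose_mask(sp, noiseless_fit_cfg)
        for j in range(sp.xi.shape[1]):
            res = estimate_aline(sp.xi[:, j], sp.h1_phase[:, j], mask[:, j], noiseless_fit_cfg)
            assert res.scenario[0] == SCENARIO["surface"]
            assert res.phi[0] == pytest.approx(wrap_orientation(sp.h1_phase[0, j] / 2.0))
            assert res.beta[0] == pytest.approx(sp.xi[0, j])

    def test_homogeneous_recovery_through_phase_jump(self, single_phantom, noiseless_spectral, noiseless_fit_cfg):
        """The raw phase flips at z ~ 1/mu_a but the recovered phi never does."""
        sp = noiseless_spectral
        mask = rose_mask(sp, noiseless_fit_cfg)
        res = estimate_aline(sp.xi[:, 0], sp.h1_phase[:, 0], mask[:, 0], noiseless_fit_cfg)
        in_tissue = single_phantom.tissue_mask[:, 0] & res.valid
        raw_flips = np.abs(orientation_diff(sp.h1_phase[1:, 0] / 2, sp.h1_phase[:-1, 0] / 2))
        assert np.sum(raw_flips[in_tissue[1:]] > 45) == 1
        assert np.max(np.abs(orientation_diff(res.phi[in_tissue], 30.0))) < 0.5

    def test_perpendicular_two_layer_recovery(self, noiseless_fit_cfg):
        ph = tendon_presets("stacked_perpendicular", phi1=10.0, grid=GridSpec(36, 2, 0.01, 0.05))
        sp = polarization_spectrum(acquire_sweep(ph))
        mask = rose_mask(sp, noiseless_fit_cfg)
        res = estimate_aline(sp.xi[:, 0], sp.h1_phase[:, 0], mask[:, 0], noiseless_fit_cfg)
        in_tissue = ph.tissue_mask[:, 0] & res.valid
        err = orientation_diff(res.phi[in_tissue], np.nan_to_num(ph.phi_map[in_tissue, 0]))
        assert np.max(np.abs(err)) < 0.5
        # exactly one transition, at the layer boundary
        d = np.abs(orientation_diff(res.phi[in_tissue][1:], res.phi[in_tissue][:-1]))
        assert np.sum(d > 45) == 1


class TestEstimateImage:
    def test_homogeneous_map_constant(self, single_phantom, noiseless_spectral, noiseless_fit_cfg):
        sp = noiseless_spectral
        est = estimate_image(sp, rose_mask(sp, noiseless_fit_cfg), noiseless_fit_cfg)
        sel = single_phantom.tissue_mask & est.mask
        assert np.max(np.abs(orientation_diff(est.phi_map[sel], 30.0))) < 0.5

    def test_deterministic(self, noiseless_spectral, noiseless_fit_cfg):
        sp = noiseless_spectral
        mask = rose_mask(sp, noiseless_fit_cfg)
        e1 = estimate_image(sp, mask, noiseless_fit_cfg)
        e2 = estimate_image(sp, mask, noiseless_fit_cfg)
        np.testing.assert_array_equal(
            np.nan_to_num(e1.phi_map, nan=999), np.nan_to_num(e2.phi_map, nan=999)
        )

    def test_all_masked_column_stays_empty(self, noiseless_spectral, noiseless_fit_cfg):
        sp = noiseless_spectral
        mask = rose_mask(sp, noiseless_fit_cfg)
        mask[:, 3] = False
        est = estimate_image(sp, mask, noiseless_fit_cfg)
        assert not est.mask[:, 3].any()
        assert np.all(np.isnan(est.phi_map[:, 3]))

    def test_global_beta_mode(self, noiseless_spectral):
        cfg = FitConfig(noise_sigma_source=1e-12, beta_mode="fixed-from-surface")
        sp = noiseless_spectral
        est = estimate_image(sp, rose_mask(sp, cfg), cfg)
        betas = est.beta_map[est.mask]
        assert np.unique(betas).size == 1

    def test_noise_robust_recovery_at_snr20(self):
        """Surface H1 SNR ~ 20: recovered orientations stay close to truth."""
        sweep = SweepConfig()
        errs = []
        for seed, phi1 in [(99, -40.0), (100, 10.0), (101, 70.0)]:
            ph = tendon_presets("single", phi1=phi1, grid=GridSpec(36, 8, 0.01, 0.05))
            sigma = calibrate_additive_sigma(ph, sweep, 20.0)
            stack = acquire_sweep(ph, sweep, NoiseConfig(additive_sigma=sigma, seed=seed))
            sp = polarization_spectrum(energy_correct(stack))
            cfg = FitConfig(noise_sigma_source=((34, 36), (0, 8)))
            est = estimate_image(sp, rose_mask(sp, cfg), cfg)
            sel = ph.tissue_mask & est.mask
            errs.append(orientation_diff(est.phi_map[sel], phi1))
        err = np.concatenate(errs)
        assert np.sqrt(np.mean(err**2)) < 3.97


class TestInterpolateMasked:
    def test_constant_fill(self):
        phi = np.array([[30.0], [np.nan], [np.nan], [30.0]])
        mask = np.isfinite(phi)
        out = interpolate_masked(phi, mask)
        np.testing.assert_allclose(out[:, 0], 30.0)

    def test_circular_fill_across_director_wrap(self):
        phi = np.array([[89.0], [np.nan], [-89.0]])
        mask = np.isfinite(phi)
        out = interpolate_masked(phi, mask)
        # midpoint of 89 and -89 on the director circle is +-90, never 0
        assert abs(abs(out[1, 0]) - 90.0) < 1e-9

    def test_linear_midpoint(self):
        phi = np.array([[10.0], [np.nan], [20.0]])
        out = interpolate_masked(phi, np.isfinite(phi))
        assert out[1, 0] == pytest.approx(15.0, abs=1e-9)

    def test_edge_runs_nearest_filled(self):
        phi = np.array([[np.nan], [40.0], [50.0], [np.nan]])
        out = interpolate_masked(phi, np.isfinite(phi))
        assert out[0, 0] == pytest.approx(40.0)
        assert out[3, 0] == pytest.approx(50.0)

    def test_empty_column_left_nan(self):
        phi = np.full((4, 1), np.nan)
        out = interpolate_masked(phi, np.zeros_like(phi, dtype=bool))
        assert np.all(np.isnan(out))
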