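"""HDF5 serialization of sweep stacks, spectral maps and estimates.

Layout of a stack container:

    /data        (n_depth, n_lateral, T) PA amplitude
    /thetas      (T,) polarization angles [deg]
    /energies    (T,) relative pulse energies
    /truth/...   ground-truth phantom maps (when simulated)
    /spectral/...  demodulation products
    /estimate/...  recovered parameter maps
    attrs: grid geometry, sweep config, units
"""

from __future__ import annotations

import numpy as np
import h5py

from .estimate import EstimateMaps
from .forward import SweepConfig, SweepStack
from .phantom import GridSpec, TissuePhantom
from .spectral import SpectralMaps

__all__ = [
    "save_stack",
    "load_stack",
    "save_spectral",
    "load_spectral",
    "save_estimate",
    "load_estimate",
    "export_tiff",
]


def _write_grid(obj, grid: GridSpec):
    obj.attrs["n_depth"] = grid.n_depth
    obj.attrs["n_lateral"] = grid.n_lateral
    obj.attrs["dz_cm"] = grid.dz
    obj.attrs["dx_cm"] = grid.dx


def _read_grid(obj) -> GridSpec:
    return GridSpec(
        n_depth=int(obj.attrs["n_depth"]),
        n_lateral=int(obj.attrs["n_lateral"]),
        dz=float(obj.attrs["dz_cm"]),
        dx=float(obj.attrs["dx_cm"]),
    )


def save_stack(path, stack: SweepStack, mode: str = "w") -> None:
    with h5py.File(path, mode) as f:
        f.create_dataset("data", data=stack.data)
        f.create_dataset("thetas", data=stack.thetas)
        f.create_dataset("energies", data=stack.energies)
        f.attrs["angle_units"] = "deg"
        _write_grid(f, stack.grid)
        if stack.sweep is not None:
            f.attrs["n_averages"] = stack.sweep.n_averages
            f.attrs["fluence_0"] = stack.sweep.fluence_0
        if stack.ground_truth is not None:
            g = f.create_group("truth")
            ph = stack.ground_truth
            g.create_dataset("mu_a_mean", data=ph.mu_a_mean_map)
            g.create_dataset("delta_mu_a", data=ph.delta_mu_a_map)
            g.create_dataset("phi", data=ph.phi_map)
            g.attrs["grueneisen_eta"] = ph.grueneisen_eta
            _write_grid(g, ph.grid)


def load_stack(path) -> SweepStack:
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        truth = None
        if "truth" in f:
            g = f["truth"]
            truth = TissuePhantom(
                grid=_read_grid(g),
                mu_a_mean_map=g["mu_a_mean"][()],
                delta_mu_a_map=g["delta_mu_a"][()],
                phi_map=g["phi"][()],
                grueneisen_eta=float(g.attrs["grueneisen_eta"]),
            )
        sweep = None
        if "n_averages" in f.attrs:
            thetas = f["thetas"][()]
            sweep = SweepConfig(
                theta_start=float(thetas[0]),
                theta_end=float(thetas[-1]),
                theta_step=float(thetas[1] - thetas[0]) if thetas.size > 1 else 10.0,
                n_averages=int(f.attrs["n_averages"]),
                fluence_0=float(f.attrs["fluence_0"]),
            )
        return SweepStack(
            data=f["data"][()],
            thetas=f["thetas"][()],
            energies=f["energies"][()],
            grid=grid,
            ground_truth=truth,
            sweep=sweep,
        )


def save_spectral(path, spectral: SpectralMaps) -> None:
    with h5py.File(path, "a") as f:
        if "spectral" in f:
            del f["spectral"]
        g = f.create_group("spectral")
        for name in ("p_mean", "h1_amp", "h1_phase", "h2_amp", "h2_phase", "xi"):
            g.create_dataset(name, data=getattr(spectral, name))
        g.attrs["n_cycles"] = spectral.n_cycles
        g.attrs["phase_units"] = "deg"
        if spectral.grid is not None:
            _write_grid(g, spectral.grid)


def load_spectral(path) -> SpectralMaps:
    with h5py.File(path, "r") as f:
        if "spectral" not in f:
            raise FileNotFoundError(f"{path} has no /spectral group; run the analyze step first")
        g = f["spectral"]
        grid = _read_grid(g) if "n_depth" in g.attrs else None
        return SpectralMaps(
            p_mean=g["p_mean"][()],
            h1_amp=g["h1_amp"][()],
            h1_phase=g["h1_phase"][()],
            h2_amp=g["h2_amp"][()],
            h2_phase=g["h2_phase"][()],
            xi=g["xi"][()],
            n_cycles=int(g.attrs["n_cycles"]),
            grid=grid,
        )


def save_estimate(path, est: EstimateMaps) -> None:
    with h5py.File(path, "a") as f:
        if "estimate" in f:
            del f["estimate"]
        g = f.create_group("estimate")
        for name in ("phi_map", "psi_map", "alpha_map", "beta_map", "objective_map"):
            g.create_dataset(name, data=getattr(est, name))
        g.create_dataset("mask", data=est.mask.astype(np.uint8))
        g.create_dataset("scenario_map", data=est.scenario_map)
        if est.phi_interp is not None:
            g.create_dataset("phi_interp", data=est.phi_interp)
        g.attrs["angle_units"] = "deg"
        if est.grid is not None:
            _write_grid(g, est.grid)


def load_estimate(path) -> EstimateMaps:
    with h5py.File(path, "r") as f:
        if "estimate" not in f:
            raise FileNotFoundError(f"{path} has no /estimate group; run the recover step first")
        g = f["estimate"]
        grid = _read_grid(g) if "n_depth" in g.attrs else None
        return EstimateMaps(
            phi_map=g["phi_map"][()],
            psi_map=g["psi_map"][()],
            alpha_map=g["alpha_map"][()],
            beta_map=g["beta_map"][()],
            mask=g["mask"][()].astype(bool),
            objective_map=g["objective_map"][()],
            scenario_map=g["scenario_map"][()],
            grid=grid,
            phi_interp=g["phi_interp"][()] if "phi_interp" in g else None,
        )


def export_tiff(path, image: np.ndarray) -> None:
    """Flat 32-bit float TIFF export of a single map (xi, eta or phi)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
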