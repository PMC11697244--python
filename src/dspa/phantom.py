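"""Layered dichroic tissue phantoms.

A phantom is a 2-D (depth x lateral) grid of optical properties for a
uniaxial, fibrous, scattering-free absorber:

* ``mu_a_mean_map`` — mean absorption coefficient mu_a_bar = (mu_ao + mu_ae)/2
  [1/cm], averaging the ordinary (polarization perpendicular to the optic
  axis) and extraordinary (parallel) components;
* ``delta_mu_a_map`` — linear dichroism delta_mu_a = mu_ao - mu_ae [1/cm];
* ``phi_map`` — optic-axis (fiber) orientation phi [deg, (-90, 90]]; water or
  gap pixels carry NaN as the undefined-orientation marker.

Light enters at depth row 0 and propagates straight down one lateral column
at a time (ballistic model, no refraction at interfaces).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .angles import wrap_orientation

__all__ = [
    "GridSpec",
    "LayerSpec",
    "TissuePhantom",
    "build_layered_phantom",
    "tendon_presets",
    "phantom_config_to_yaml",
    "phantom_from_yaml",
]

PRESET_NAMES = ("single", "stacked_perpendicular", "stacked_30deg")


@dataclass(frozen=True)
class GridSpec:
    """Regular imaging grid; dz/dx are cell sizes in cm, depth axis first."""

    n_depth: int
    n_lateral: int
    dz: float
    dx: float

    def __post_init__(self):
        if self.n_depth < 1 or self.n_lateral < 1:
            raise ValueError("grid must have at least one cell per axis")
        if self.dz <= 0 or self.dx <= 0:
            raise ValueError("grid cell sizes dz, dx must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_depth, self.n_lateral)

    @property
    def z_centers(self) -> np.ndarray:
        """Depth of each cell center below the illuminated surface [cm]."""
        return (np.arange(self.n_depth) + 0.5) * self.dz

    @property
    def depth_extent(self) -> float:
        return self.n_depth * self.dz


@dataclass(frozen=True)
class LayerSpec:
    """One homogeneous layer, ordered from the illuminated surface down.

    ``|delta_mu_a| <= 2 * mu_a_mean`` keeps both polarization absorptions
    mu_ao = mu_a_mean + delta_mu_a/2 and mu_ae = mu_a_mean - delta_mu_a/2
    nonnegative.
    """

    thickness: float  # cm
    mu_a_mean: float  # 1/cm
    delta_mu_a: float  # 1/cm
    phi: float  # deg, director
    label: str = ""

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError(
                f"layer {self.label or '<unnamed>'}: thickness must be positive, "
                f"got {self.thickness}"
            )
        if self.mu_a_mean < 0:
            raise ValueError(f"layer {self.label or '<unnamed>'}: mu_a_mean must be >= 0")
        if abs(self.delta_mu_a) > 2.0 * self.mu_a_mean + 1e-12:
            raise ValueError(
                f"layer {self.label or '<unnamed>'}: |delta_mu_a| = {abs(self.delta_mu_a)} "
                f"exceeds 2*mu_a_mean = {2 * self.mu_a_mean}; a polarization component "
                "would have negative absorption"
            )

    @property
    def mu_a_ordinary(self) -> float:
        return self.mu_a_mean + 0.5 * self.delta_mu_a

    @property
    def mu_a_extraordinary(self) -> float:
        return self.mu_a_mean - 0.5 * self.delta_mu_a


@dataclass
class TissuePhantom:
    """Gridded maps of (mu_a_bar, delta_mu_a, phi) plus the Grueneisen scale.

    ``grueneisen_eta`` is the combined Grueneisen parameter times the
    thermal-conversion efficiency; it scales pressure globally and is
    dimensionless.
    """

    grid: GridSpec
    mu_a_mean_map: np.ndarray
    delta_mu_a_map: np.ndarray
    phi_map: np.ndarray
    grueneisen_eta: float = 1.0
    layers: tuple[LayerSpec, ...] = field(default_factory=tuple)

    def __post_init__(self):
        shape = self.grid.shape
        for name in ("mu_a_mean_map", "delta_mu_a_map", "phi_map"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != grid shape {shape}")
            setattr(self, name, arr)
        if np.any(np.abs(self.delta_mu_a_map) > 2.0 * self.mu_a_mean_map + 1e-12):
            raise ValueError("|delta_mu_a| exceeds 2*mu_a_mean somewhere in the phantom")

    @property
    def tissue_mask(self) -> np.ndarray:
        """True where there is absorbing tissue (water pixels excluded)."""
        return self.mu_a_mean_map > 0

    @property
    def beta_map(self) -> np.ndarray:
        """Local dichroism ratio beta = delta_mu_a / (2 mu_a_bar); 0 in water."""
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(
                self.mu_a_mean_map > 0,
                self.delta_mu_a_map / (2.0 * self.mu_a_mean_map),
                0.0,
            )
        return b

    def copy(self) -> "TissuePhantom":
        return replace(
            self,
            mu_a_mean_map=self.mu_a_mean_map.copy(),
            delta_mu_a_map=self.delta_mu_a_map.copy(),
            phi_map=self.phi_map.copy(),
        )


def build_layered_phantom(layers, grid: GridSpec, grueneisen_eta: float = 1.0) -> TissuePhantom:
    """Rasterize an ordered stack of layers onto a grid.

    Each cell takes the properties of the layer containing its depth-cell
    center; cells below the last layer are water (zero absorption, NaN
    orientation).  The stack must fit within the grid depth.
    """
    layers = tuple(layers)
    if not layers:
        raise ValueError("at least one layer is required")
    total = sum(l.thickness for l in layers)
    if total > grid.depth_extent + 1e-12:
        raise ValueError(
            f"layer stack depth {total:.4f} cm exceeds grid depth {grid.depth_extent:.4f} cm"
        )
    mu = np.zeros(grid.shape)
    dmu = np.zeros(grid.shape)
    phi = np.full(grid.shape, np.nan)

    z = grid.z_centers
    z0 = 0.0
    for layer in layers:
        z1 = z0 + layer.thickness
        rows = (z >= z0) & (z < z1)
        mu[rows, :] = layer.mu_a_mean
        dmu[rows, :] = layer.delta_mu_a
        phi[rows, :] = wrap_orientation(layer.phi)
        z0 = z1
    return TissuePhantom(
        grid=grid,
        mu_a_mean_map=mu,
        delta_mu_a_map=dmu,
        phi_map=phi,
        grueneisen_eta=grueneisen_eta,
        layers=layers,
    )


# Default optical parameters for the tendon presets.  The dichroism ratio
# delta_mu_a / mu_a_bar ~ 0.1 is the measured tendon value; the absolute
# absorption is an assumption (see docs/methods.md): mu_a_bar = 5 /cm places
# the predicted phase-jump depth 1/mu_a_bar = 2 mm inside the 3.2 mm
# imaging depth.
DEFAULT_MU_A_MEAN = 5.0  # 1/cm
DEFAULT_DICHROISM_RATIO = 0.1
DEFAULT_LAYER_THICKNESS = 0.16  # cm, per stacked layer; single uses 2x
DEFAULT_GRID = GridSpec(n_depth=36, n_lateral=32, dz=0.01, dx=0.05)


def tendon_presets(
    name: str,
    *,
    phi1: float = 0.0,
    grid: GridSpec | None = None,
    mu_a_mean: float = DEFAULT_MU_A_MEAN,
    dichroism_ratio: float = DEFAULT_DICHROISM_RATIO,
    layer_thickness: float = DEFAULT_LAYER_THICKNESS,
    water_gap: float = 0.0,
    grueneisen_eta: float = 1.0,
) -> TissuePhantom:
    """Named tendon geometries used in the imaging experiments.

    Presets
    -------
    ``single``
        One homogeneous tendon spanning twice ``layer_thickness`` (default
        3.2 mm, the full imaging depth) at orientation ``phi1``.
    ``stacked_perpendicular``
        Two tendons of ``layer_thickness`` each, bottom one rotated 90 deg.
    ``stacked_30deg``
        Same, bottom one rotated 30 deg.

    ``water_gap`` inserts a non-absorbing gap [cm] between stacked layers.
    """
    if grid is None:
        grid = DEFAULT_GRID
    dmu = dichroism_ratio * mu_a_mean

    def layer(phi, thickness, label):
        return LayerSpec(
            thickness=thickness, mu_a_mean=mu_a_mean, delta_mu_a=dmu, phi=phi, label=label
        )

    if name == "single":
        layers = [layer(phi1, 2.0 * layer_thickness, "tendon")]
    elif name in ("stacked_perpendicular", "stacked_30deg"):
        delta = 90.0 if name == "stacked_perpendicular" else 30.0
        layers = [layer(phi1, layer_thickness, "tendon_top")]
        if water_gap > 0:
            # water: no absorption, no dichroism; phi value irrelevant
            layers.append(
                LayerSpec(
                    thickness=water_gap, mu_a_mean=0.0, delta_mu_a=0.0, phi=0.0, label="gap"
                )
            )
        layers.append(layer(phi1 + delta, layer_thickness, "tendon_bottom"))
    else:
        raise ValueError(f"unknown preset {name!r}; choose one of {PRESET_NAMES}")
    ph = build_layered_phantom(layers, grid, grueneisen_eta=grueneisen_eta)
    # gap pixels are water even though rasterized from an explicit layer
    ph.phi_map[~ph.tissue_mask] = np.nan
    return ph


# ---------------------------------------------------------------------------
# structured-text (YAML) phantom configs; units fixed to cm and degrees
# ---------------------------------------------------------------------------

def phantom_config_to_yaml(layers, grid: GridSpec, grueneisen_eta: float = 1.0) -> str:
    doc = {
        "units": {"length": "cm", "absorption": "1/cm", "angle": "deg"},
        "grid": {
            "n_depth": grid.n_depth,
            "n_lateral": grid.n_lateral,
            "dz": grid.dz,
            "dx": grid.dx,
        },
        "grueneisen_eta": grueneisen_eta,
        "layers": [
            {
                "thickness": l.thickness,
                "mu_a_mean": l.mu_a_mean,
                "delta_mu_a": l.delta_mu_a,
                "phi": l.phi,
                "label": l.label,
            }
            for l in layers
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def phantom_from_yaml(text: str) -> TissuePhantom:
    doc = yaml.safe_load(text)
    g = doc["grid"]
    grid = GridSpec(
        n_depth=int(g["n_depth"]),
        n_lateral=int(g["n_lateral"]),
        dz=float(g["dz"]),
        dx=float(g["dx"]),
    )
    layers = [
        LayerSpec(
            thickness=float(l["thickness"]),
            mu_a_mean=float(l["mu_a_mean"]),
            delta_mu_a=float(l["delta_mu_a"]),
            phi=float(l["phi"]),
            label=str(l.get("label", "")),
        )
        for l in doc["layers"]
    ]
    return build_layered_phantom(layers, grid, grueneisen_eta=float(doc.get("grueneisen_eta", 1.0)))
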