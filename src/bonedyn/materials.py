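"""QCT-style material mapping: attenuation -> ash density -> Young's modulus.

A CT attenuation volume (Hounsfield units) is calibrated against a density
phantom to give the *ash density* rho_ash (g/cm^3), which is converted to an
isotropic Young's modulus per FE node through a double-exponential law

    E = e0 * exp(a * exp(b * rho_ash)),    E >= e_floor,

with a = -5.19 and b = -2.30 cm^3/g. The prefactor e0 is stored in Pa and
defaults to 20 GPa (20000 MPa), giving E(rho_ash = 1 g/cm^3) ~= 11.9 GPa,
consistent with cortical bone; the asymptote for dense bone is e0 itself.
Moduli below the 1 MPa floor (air-like or negative densities) are clamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .mesh import TetMesh

#: Default attenuation-to-density slope: 1 g/cm^3 per 895.93 HU.
DEFAULT_HU_PER_UNIT_DENSITY = 895.93


class CalibrationError(ValueError):
    """Raised for unusable phantom specifications or degenerate regressions."""


@dataclass
class HUVolume:
    """3D scalar attenuation grid (Hounsfield units) on a regular lattice.

    ``values[i, j, k]`` sits at ``origin + spacing * (i, j, k)`` (voxel
    centres); spacing and origin are in millimetres, matching NIfTI headers.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = (
            np.zeros(3) if self.origin is None else np.asarray(self.origin, dtype=float)
        )
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("volume must be 3D with >= 2 voxels per axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite attenuation values")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be 3 positive components (mm)")

    def axes(self):
        """Voxel-centre coordinates (mm) along each axis."""
        return tuple(
            self.origin[d] + self.spacing[d] * np.arange(self.values.shape[d])
            for d in range(3)
        )

    def interpolator(self, fill_value=None):
        return RegularGridInterpolator(
            self.axes(),
            self.values,
            method="linear",
            bounds_error=fill_value is None,
            fill_value=fill_value,
        )


@dataclass
class PhantomSpec:
    """Calibration phantom: inserts of known equivalent density.

    ``inserts`` is a list of ``(density g/cm^3, region)`` where region is
    either a boolean voxel mask or a ``(center_mm, radius_mm)`` sphere.
    """

    inserts: list

    def __post_init__(self):
        if len(self.inserts) < 2:
            raise CalibrationError("phantom needs at least 2 inserts")
        dens = [float(d) for d, _ in self.inserts]
        if len(set(dens)) != len(dens):
            raise CalibrationError("insert densities must be pairwise distinct")

    def region_masks(self, volume: HUVolume):
        ax = volume.axes()
        grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
        masks = []
        for _, region in self.inserts:
            if isinstance(region, np.ndarray) and region.dtype == bool:
                mask = region
            else:
                center, radius = region
                mask = (
                    np.linalg.norm(grid - np.asarray(center, dtype=float), axis=-1)
                    <= radius
                )
            if not mask.any():
                raise CalibrationError("phantom insert region lies outside the volume")
            masks.append(mask)
        return masks


@dataclass
class CalibrationModel:
    """Linear HU -> ash-density map: rho_ash = slope * HU + intercept."""

    slope: float  # g/cm^3 per HU
    intercept: float = 0.0  # g/cm^3
    source: str = "built-in-default"

    def __post_init__(self):
        if self.slope <= 0:
            raise CalibrationError("calibration slope must be positive")

    @classmethod
    def default(cls) -> "CalibrationModel":
        return cls(slope=1.0 / DEFAULT_HU_PER_UNIT_DENSITY, intercept=0.0)


@dataclass
class MaterialLaw:
    """Constants of the density-to-modulus law (see module docstring)."""

    e0: float = 20000e6  # Pa (20000 MPa prefactor)
    a: float = -5.19  # dimensionless
    b_coef: float = -2.30  # cm^3/g
    e_floor: float = 1e6  # Pa
    poisson: float = 0.3
    mass_density: float = 1940.0  # kg/m^3

    def __post_init__(self):
        if self.e_floor <= 0:
            raise ValueError("modulus floor must be positive")
        if not 0 <= self.poisson < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        if self.mass_density <= 0:
            raise ValueError("mass density must be positive")


@dataclass
class MaterialField:
    """Per-node ash density (g/cm^3) and clamped Young's modulus (Pa)."""

    node_ash_density: np.ndarray
    node_modulus: np.ndarray
    law: MaterialLaw = field(default_factory=MaterialLaw)

    def __post_init__(self):
        self.node_ash_density = np.asarray(self.node_ash_density, dtype=float)
        self.node_modulus = np.asarray(self.node_modulus, dtype=float)
        if self.node_ash_density.shape != self.node_modulus.shape:
            raise ValueError("density and modulus arrays must have equal shape")
        if np.any(self.node_modulus < self.law.e_floor * (1 - 1e-12)):
            raise ValueError("modulus below the law's floor")

    @classmethod
    def uniform(cls, n_nodes: int, modulus: float, law: MaterialLaw = None,
                ash_density: float = np.nan) -> "MaterialField":
        law = law or MaterialLaw(e_floor=min(1e6, modulus))
        return cls(
            np.full(n_nodes, ash_density),
            np.full(n_nodes, float(modulus)),
            law,
        )

    def element_modulus(self, mesh: TetMesh) -> np.ndarray:
        """Element modulus = arithmetic mean of its nodes' moduli."""
        return self.node_modulus[mesh.elements].mean(axis=1)


@dataclass
class TissueClassification:
    """Per-element cortical/trabecular label by mean ash density."""

    element_label: np.ndarray  # bool: True = cortical
    threshold_used: float

    @property
    def cortical(self) -> np.ndarray:
        return np.where(self.element_label)[0]

    @property
    def trabecular(self) -> np.ndarray:
        return np.where(~self.element_label)[0]


def calibrate_phantom(volume: HUVolume, phantom: PhantomSpec) -> CalibrationModel:
    """Fit the HU -> density line by ordinary least squares over insert means."""
    masks = phantom.region_masks(volume)
    mean_hu = np.array([volume.values[m].mean() for m in masks])
    dens = np.array([float(d) for d, _ in phantom.inserts])
    if np.ptp(mean_hu) < 1e-12:
        raise CalibrationError("degenerate phantom: all inserts have equal mean HU")
    slope, intercept = np.polyfit(mean_hu, dens, 1)
    return CalibrationModel(slope=float(slope), intercept=float(intercept),
                            source="phantom-regression")


def hu_to_ash_density(hu, cal: CalibrationModel = None):
    """Apply the linear calibration; with the default, rho = HU / 895.93."""
    cal = cal or CalibrationModel.default()
    return cal.slope * np.asarray(hu, dtype=float) + cal.intercept


def ash_density_to_modulus(rho_ash, law: MaterialLaw = None):
    """Double-exponential density-to-modulus law with the 1 MPa floor."""
    law = law or MaterialLaw()
    rho = np.asarray(rho_ash, dtype=float)
    e = law.e0 * np.exp(law.a * np.exp(law.b_coef * rho))
    return np.maximum(e, law.e_floor)


def sample_field_to_nodes(
    volume: HUVolume,
    cal: CalibrationModel,
    law: MaterialLaw,
    mesh: TetMesh,
    out_of_bounds: str = "error",
) -> MaterialField:
    """Trilinearly sample HU at node positions and map to a MaterialField.

    Mesh coordinates are metres; the volume lattice is millimetres.
    ``out_of_bounds`` is ``"error"`` (default) or ``"nearest"`` (clamp node
    positions to the lattice bounding box before sampling).
    """
    cal = cal or CalibrationModel.default()
    law = law or MaterialLaw()
    pts_mm = mesh.nodes * 1e3
    ax = volume.axes()
    lo = np.array([a[0] for a in ax])
    hi = np.array([a[-1] for a in ax])
    outside = np.any((pts_mm < lo) | (pts_mm > hi), axis=1)
    if outside.any():
        if out_of_bounds == "error":
            i = int(np.where(outside)[0][0])
            raise ValueError(
                f"{outside.sum()} mesh node(s) outside the attenuation volume "
                f"(first: node {i} at {mesh.nodes[i]} m); pass "
                "out_of_bounds='nearest' to clamp"
            )
        elif out_of_bounds == "nearest":
            pts_mm = np.clip(pts_mm, lo, hi)
        else:
            raise ValueError("out_of_bounds must be 'error' or 'nearest'")
    hu = volume.interpolator(fill_value=None)(pts_mm)
    rho = hu_to_ash_density(hu, cal)
    return MaterialField(rho, ash_density_to_modulus(rho, law), law)


def classify_tissue(
    field: MaterialField, mesh: TetMesh, threshold: float = 0.6
) -> TissueClassification:
    """Label elements cortical (mean rho_ash >= threshold) or trabecular."""
    if len(field.node_ash_density) != mesh.n_nodes:
        raise ValueError("material field does not match mesh")
    mean_rho = field.node_ash_density[mesh.elements].mean(axis=1)
    return TissueClassification(mean_rho >= threshold, float(threshold))


def node_tissue_labels(mesh: TetMesh, classification: TissueClassification) -> np.ndarray:
    """Per-node label by majority vote of incident elements (tie -> cortical)."""
    cort = np.zeros(mesh.n_nodes)
    total = np.zeros(mesh.n_nodes)
    flat = mesh.elements.ravel()
    np.add.at(total, flat, 1.0)
    np.add.at(cort, flat, np.repeat(classification.element_label.astype(float), 4))
    with np.errstate(invalid="ignore"):
        frac = np.where(total > 0, cort / np.maximum(total, 1), 1.0)
    return frac >= 0.5  # True = cortical; isolated nodes default to cortical


def apply_bmd_loss(
    field: MaterialField,
    mesh: TetMesh,
    classification: TissueClassification,
    cortical_factor: float,
    trabecular_factor: float,
) -> MaterialField:
    """Scale nodal moduli by tissue-class factors (mineral-loss scenarios).

    The osteopenic scenario uses (0.84, 0.67) and the osteoporotic one
    (0.68, 0.34). Returns a new field; the floor is re-applied.
    """
    for f in (cortical_factor, trabecular_factor):
        if not 0 < f <= 1:
            raise ValueError("BMD-loss factors must lie in (0, 1]")
    node_is_cortical = node_tissue_labels(mesh, classification)
    factor = np.where(node_is_cortical, cortical_factor, trabecular_factor)
    e = np.maximum(field.node_modulus * factor, field.law.e_floor)
    return replace(field, node_modulus=e, node_ash_density=field.node_ash_density.copy())


#: Standard mineral-loss ladder: label -> (cortical, trabecular) stiffness factors.
BMD_LOSS_SCENARIOS = {
    "native": (1.0, 1.0),
    "C84T67": (0.84, 0.67),
    "C68T34": (0.68, 0.34),
}
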