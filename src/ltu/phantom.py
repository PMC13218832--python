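"""Voxelized digital-twin phantoms.

A phantom is a regular isotropic voxel grid carrying per-region optical,
thermal, and acoustic tissue properties.  Geometry follows a voxel-center
convention with 0-based indices; the z axis points into the tissue (z index
increases with depth below the illuminated surface).

Three canonical phantom builders are provided: a layered slab, an
absorbing-plane phantom (scattering cover over a strongly absorbing gel
slab, used for depth-attenuation studies), and a spherical-tumor phantom
(absorbing agarose sphere embedded in soft tissue, used for simulated
photothermal therapy).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TissueProperties",
    "VoxelGrid",
    "SamplingPoint",
    "PRESETS",
    "preset",
    "build_layered_phantom",
    "build_tumor_phantom",
    "build_absorber_plane_phantom",
]


@dataclass(frozen=True)
class TissueProperties:
    """Per-region tissue material constants.

    Parameters
    ----------
    mu_a : float
        Optical absorption coefficient (1/m).
    mu_s : float
        Optical scattering coefficient (1/m).
    g : float
        Scattering anisotropy factor, ``0 <= g < 1``.
    rho : float
        Mass density (kg/m^3).
    cp : float
        Specific heat capacity (J/(kg K)).
    kv : float
        Thermal conductivity (W/(m K)).
    vs : float
        Speed of sound (m/s).
    grueneisen_A : float
        Intercept of the linear Grueneisen model ``Gamma = A + B*T``.
    grueneisen_B : float
        Slope of the Grueneisen model (1/K).
    """

    mu_a: float
    mu_s: float
    g: float
    rho: float
    cp: float
    kv: float
    vs: float
    grueneisen_A: float = -0.031
    grueneisen_B: float = 0.004

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not (0.0 <= self.g < 1.0):
            raise ValueError("anisotropy g must satisfy 0 <= g < 1")
        for name in ("rho", "cp", "kv", "vs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def mu_s_reduced(self) -> float:
        """Reduced scattering coefficient mu_s' = (1 - g) * mu_s (1/m)."""
        return (1.0 - self.g) * self.mu_s

    def replace(self, **kwargs) -> "TissueProperties":
        return replace(self, **kwargs)


#: Named property presets.  Optical values are soft-tissue literature scale
#: at 808 nm; thermal values are muscle/water scale.  They are overridable
#: stand-ins, not measured constants.
PRESETS: dict[str, TissueProperties] = {
    # chicken breast at 808 nm: low absorption, strong forward scattering
    "chicken_breast_808": TissueProperties(
        mu_a=10.0, mu_s=6000.0, g=0.9, rho=1050.0, cp=3600.0, kv=0.5,
        vs=1540.0, grueneisen_A=-0.031, grueneisen_B=0.004,
    ),
    # ink-loaded agarose: intercepts essentially all light; water-like gel
    "black_agarose": TissueProperties(
        mu_a=3000.0, mu_s=1000.0, g=0.9, rho=1000.0, cp=4180.0, kv=0.6,
        vs=1500.0, grueneisen_A=-0.031, grueneisen_B=0.004,
    ),
    # moderately absorbing tumor mimic (diluted ink sphere)
    "tumor_mimic": TissueProperties(
        mu_a=300.0, mu_s=2000.0, g=0.9, rho=1000.0, cp=4000.0, kv=0.55,
        vs=1520.0, grueneisen_A=-0.031, grueneisen_B=0.004,
    ),
    "water": TissueProperties(
        mu_a=0.02, mu_s=0.1, g=0.0, rho=1000.0, cp=4180.0, kv=0.6,
        vs=1480.0, grueneisen_A=-0.031, grueneisen_B=0.004,
    ),
}


def preset(name: str, **overrides) -> TissueProperties:
    """Return a named preset, optionally with field overrides."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return base.replace(**overrides) if overrides else base


@dataclass(frozen=True)
class SamplingPoint:
    """Virtual thermocouple at a grid index."""

    position: tuple[int, int, int]
    label: str = "custom"
    sensor_noise_sd: float = 0.0

    _LABELS = frozenset(
        {"tumor_top", "tumor_core", "adjacent_tissue", "lateral_margin", "custom"}
    )

    def __post_init__(self) -> None:
        if self.label not in self._LABELS:
            raise ValueError(f"label must be one of {sorted(self._LABELS)}")


@dataclass
class VoxelGrid:
    """Regular isotropic voxel grid with region-labelled properties.

    ``region_labels[i, j, k]`` is an integer tissue id; ``props[id]`` maps it
    to its :class:`TissueProperties`.  ``origin`` is the physical position of
    the center of voxel (0, 0, 0).  Axis order is (x, y, z) with z = depth.
    """

    shape: tuple[int, int, int]
    dl: float
    region_labels: np.ndarray
    props: dict[int, TissueProperties]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sampling_points: list[SamplingPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dl <= 0:
            raise ValueError("voxel edge length dl must be positive")
        self.region_labels = np.ascontiguousarray(self.region_labels, dtype=np.int32)
        if self.region_labels.shape != tuple(self.shape):
            raise ValueError("region_labels shape does not match grid shape")
        present = set(np.unique(self.region_labels).tolist())
        missing = present - set(self.props)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no TissueProperties")

    # -- derived per-voxel fields --------------------------------------

    def property_map(self, name: str) -> np.ndarray:
        """Per-voxel array of one property (lookup through region labels)."""
        if name == "mu_s_reduced":
            values = {k: p.mu_s_reduced for k, p in self.props.items()}
        else:
            values = {k: getattr(p, name) for k, p in self.props.items()}
        lut = np.zeros(max(values) + 1, dtype=np.float64)
        for k, v in values.items():
            lut[k] = v
        return lut[self.region_labels]

    @property
    def voxel_volume(self) -> float:
        return self.dl**3

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (m) along each axis."""
        return tuple(n * self.dl for n in self.shape)

    def mask(self, label: int) -> np.ndarray:
        return self.region_labels == label

    def voxel_centers_z(self) -> np.ndarray:
        """Depth coordinate (m) of voxel centers along z."""
        return self.origin[2] + (np.arange(self.shape[2]) + 0.5) * self.dl

    def index_of_depth(self, depth: float) -> int:
        """z index whose voxel spans the given physical depth."""
        return int(np.clip(depth / self.dl, 0, self.shape[2] - 1))

    def add_sampling_point(self, point: SamplingPoint) -> None:
        i, j, k = point.position
        nx, ny, nz = self.shape
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            raise ValueError(f"sampling point {point.position} outside grid {self.shape}")
        self.sampling_points.append(point)


def _round_voxels(thickness: float, dl: float) -> int:
    """Nearest-voxel rounding with a 1-voxel floor."""
    return max(1, int(round(thickness / dl)))


def build_layered_phantom(
    layer_thicknesses: list[float],
    layer_props: list[TissueProperties],
    dl: float,
    lateral_extent: tuple[float, float] = (0.02, 0.02),
) -> VoxelGrid:
    """Stack horizontal tissue layers along the depth axis.

    Each physical thickness is rounded to the nearest whole number of voxels
    (minimum one voxel), so the realized depth of layer boundaries is exact
    grid arithmetic.
    """
    if len(layer_thicknesses) != len(layer_props):
        raise ValueError("one TissueProperties required per layer")
    if not layer_thicknesses:
        raise ValueError("at least one layer required")
    for idx, t in enumerate(layer_thicknesses):
        if t <= 0:
            raise ValueError(f"layer {idx} has non-positive thickness {t}")
    nx = _round_voxels(lateral_extent[0], dl)
    ny = _round_voxels(lateral_extent[1], dl)
    n_per_layer = [_round_voxels(t, dl) for t in layer_thicknesses]
    nz = sum(n_per_layer)
    labels = np.empty((nx, ny, nz), dtype=np.int32)
    props: dict[int, TissueProperties] = {}
    z0 = 0
    for lab, (n, p) in enumerate(zip(n_per_layer, layer_props)):
        labels[:, :, z0 : z0 + n] = lab
        props[lab] = p
        z0 += n
    return VoxelGrid(shape=(nx, ny, nz), dl=dl, region_labels=labels, props=props)


def build_tumor_phantom(
    tumor_diameter: float,
    tumor_depth: float,
    background: TissueProperties,
    tumor: TissueProperties,
    dl: float,
    extent: tuple[float, float, float] = (0.024, 0.024, 0.016),
) -> VoxelGrid:
    """Spherical tumor embedded in a homogeneous background slab.

    The sphere is laterally centered; its top is ``tumor_depth`` below the
    illuminated surface, so the center sits at depth
    ``tumor_depth + tumor_diameter / 2``.  A voxel belongs to the tumor when
    its center lies within the sphere radius.
    """
    if tumor_diameter <= 0:
        raise ValueError("tumor diameter must be positive")
    nx, ny, nz = (_round_voxels(e, dl) for e in extent)
    r = tumor_diameter / 2.0
    cx, cy = nx * dl / 2.0, ny * dl / 2.0
    cz = tumor_depth + r
    if tumor_depth < 0 or cz + r > nz * dl or cx - r < 0 or cy - r < 0:
        raise ValueError(
            f"sphere (d={tumor_diameter}, depth={tumor_depth}) clipped by extent {extent}"
        )
    x = (np.arange(nx) + 0.5) * dl
    y = (np.arange(ny) + 0.5) * dl
    z = (np.arange(nz) + 0.5) * dl
    dist2 = (
        (x - cx)[:, None, None] ** 2
        + (y - cy)[None, :, None] ** 2
        + (z - cz)[None, None, :] ** 2
    )
    labels = np.where(dist2 <= r * r, np.int32(1), np.int32(0))
    return VoxelGrid(
        shape=(nx, ny, nz), dl=dl, region_labels=labels,
        props={0: background, 1: tumor},
    )


def build_absorber_plane_phantom(
    cover_depth: float,
    cover: TissueProperties,
    absorber: TissueProperties,
    dl: float,
    lateral_extent: tuple[float, float] = (0.02, 0.02),
    absorber_thickness: float = 0.002,
) -> VoxelGrid:
    """Scattering cover tissue over a strongly absorbing flat slab.

    ``cover_depth`` = 0 places the absorber at the surface and serves as the
    zero-attenuation normalization anchor for depth-attenuation studies.
    """
    if cover_depth < 0:
        raise ValueError("cover_depth must be non-negative")
    nx = _round_voxels(lateral_extent[0], dl)
    ny = _round_voxels(lateral_extent[1], dl)
    n_cover = 0 if cover_depth == 0 else _round_voxels(cover_depth, dl)
    n_abs = _round_voxels(absorber_thickness, dl)
    nz = n_cover + n_abs
    labels = np.empty((nx, ny, nz), dtype=np.int32)
    labels[:, :, :n_cover] = 0
    labels[:, :, n_cover:] = 1
    return VoxelGrid(
        shape=(nx, ny, nz), dl=dl, region_labels=labels,
        props={0: cover, 1: absorber},
    )
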