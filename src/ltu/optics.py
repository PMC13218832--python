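"""Light transport in voxelized tissue.

Two fluence solvers are provided:

* :func:`mc_fluence` — voxel Monte-Carlo photon transport (the reference):
  Henyey–Greenstein scattering, implicit-capture weight deposition, Russian
  roulette, exact voxel-boundary ray tracing, refractive-index-matched
  boundaries.
* :func:`diffusion_fluence` — steady-state diffusion approximation solved by
  a 7-point finite-difference scheme, as a fast alternative.

Both return the fluence Φ(r); :func:`heat_source` converts it to the
photothermal volumetric source S = μa·Φ.  Under matching illumination
conditions (pulsed and continuous beams with identical surface energy
distribution and wavelength) one fluence solution serves both the
photoacoustic excitation and the continuous heating, rescaled by pulse
energy versus continuous power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

from .phantom import VoxelGrid
from .thermal import HeatSourceField

__all__ = [
    "BeamSpec",
    "FluenceField",
    "HeatSourceField",
    "MCResult",
    "DiffusionProblem",
    "mc_fluence",
    "diffusion_fluence",
    "solve_diffusion",
    "heat_source",
    "depth_energy_integral",
]

_ROULETTE_THRESHOLD = 1e-4
_ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class BeamSpec:
    """Laser beam incident normally on the top (z = 0) surface.

    ``diameter`` is interpreted per profile: for ``gaussian`` it is the 1/e²
    intensity diameter by default (``width_convention="fwhm"`` switches to
    full width at half maximum); for ``flattop`` it is the hard edge.
    ``power_or_energy`` is W in continuous mode and J per pulse in pulsed
    mode; the wavelength is carried as metadata only.
    """

    profile: str = "gaussian"
    diameter: float = 3e-3
    wavelength: float = 808e-9
    power_or_energy: float = 1e-3
    mode: str = "pulsed"
    center: tuple[float, float] | None = None
    width_convention: str = "e2"

    def __post_init__(self) -> None:
        if self.profile not in ("gaussian", "flattop"):
            raise ValueError("profile must be 'gaussian' or 'flattop'")
        if self.mode not in ("continuous", "pulsed"):
            raise ValueError("mode must be 'continuous' or 'pulsed'")
        if self.width_convention not in ("e2", "fwhm"):
            raise ValueError("width_convention must be 'e2' or 'fwhm'")
        if self.diameter <= 0:
            raise ValueError("beam diameter must be positive")
        if self.power_or_energy <= 0:
            raise ValueError("beam power/energy must be positive")

    @property
    def gaussian_waist(self) -> float:
        """1/e² intensity radius w0 (m) of the gaussian profile."""
        if self.width_convention == "e2":
            return self.diameter / 2.0
        # FWHM of exp(-2 r^2 / w0^2) is w0 * sqrt(2 ln 2)
        return self.diameter / np.sqrt(2.0 * np.log(2.0))

    def with_output(self, power_or_energy: float, mode: str) -> "BeamSpec":
        """Same spatial beam at a different output level/mode (MIC rescaling)."""
        return BeamSpec(
            profile=self.profile, diameter=self.diameter,
            wavelength=self.wavelength, power_or_energy=power_or_energy,
            mode=mode, center=self.center,
            width_convention=self.width_convention,
        )


@dataclass
class FluenceField:
    """Fluence Φ per voxel: J/m² for a pulsed beam, W/m² for continuous."""

    phi: np.ndarray
    beam: BeamSpec
    n_photons: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phi)) or np.any(self.phi < 0):
            raise ValueError("fluence must be finite and non-negative")


@dataclass
class MCResult:
    """Monte-Carlo transport result with energy bookkeeping."""

    fluence: FluenceField
    absorbed_fraction: float
    escaped_fraction: float
    transmitted_fraction: float
    absorbed_map: np.ndarray  # fraction of input energy absorbed per voxel


@dataclass
class DiffusionProblem:
    """Assembled steady-state diffusion system (diagnostic container)."""

    L: np.ndarray
    D: np.ndarray
    c: float = 2.998e8 / 1.37


# ----------------------------------------------------------------------
# Monte-Carlo kernel
# ----------------------------------------------------------------------

@njit(cache=True)
def _mc_kernel(mu_a, mu_s, g_map, dl, nx, ny, nz,
               profile_flag, radius_param, cx, cy,
               n_photons, seed):  # pragma: no cover - exercised via mc_fluence
    np.random.seed(seed)
    dep = np.zeros((nx, ny, nz))
    escaped = 0.0
    transmitted = 0.0
    lx = nx * dl
    ly = ny * dl
    lz = nz * dl
    eps = dl * 1e-9
    for _ in range(n_photons):
        # launch at the top surface with the beam's radial profile
        u = np.random.random()
        if profile_flag == 0:  # gaussian, radius_param = 1/e^2 waist
            r = radius_param * np.sqrt(-np.log(u) / 2.0)
        else:  # flattop, radius_param = edge radius
            r = radius_param * np.sqrt(u)
        phi_ang = 2.0 * np.pi * np.random.random()
        x = cx + r * np.cos(phi_ang)
        y = cy + r * np.sin(phi_ang)
        z = 0.0
        if x <= 0.0 or x >= lx or y <= 0.0 or y >= ly:
            escaped += 1.0
            continue
        ux, uy, uz = 0.0, 0.0, 1.0
        w = 1.0
        alive = True
        while alive:
            tau = -np.log(np.random.random())
            # consume optical depth tau along the ray, voxel by voxel
            while True:
                ix = int(np.floor(x / dl))
                iy = int(np.floor(y / dl))
                iz = int(np.floor(z / dl))
                if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0:
                    escaped += w
                    alive = False
                    break
                if iz >= nz:
                    transmitted += w
                    alive = False
                    break
                mua = mu_a[ix, iy, iz]
                mus = mu_s[ix, iy, iz]
                mut = mua + mus
                # distance to the nearest voxel face along the direction
                if ux > 0.0:
                    tx = ((ix + 1) * dl - x) / ux
                elif ux < 0.0:
                    tx = (ix * dl - x) / ux
                else:
                    tx = 1e30
                if uy > 0.0:
                    ty = ((iy + 1) * dl - y) / uy
                elif uy < 0.0:
                    ty = (iy * dl - y) / uy
                else:
                    ty = 1e30
                if uz > 0.0:
                    tz = ((iz + 1) * dl - z) / uz
                elif uz < 0.0:
                    tz = (iz * dl - z) / uz
                else:
                    tz = 1e30
                sb = min(tx, ty, tz)
                if sb < 0.0:
                    sb = 0.0
                if mut > 0.0 and mut * sb >= tau:
                    # interaction inside this voxel
                    s = tau / mut
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    dep[ix, iy, iz] += w * mua / mut
                    w *= mus / mut
                    if w < _ROULETTE_THRESHOLD:
                        if np.random.random() < _ROULETTE_SURVIVAL:
                            w /= _ROULETTE_SURVIVAL
                        else:
                            alive = False
                            break
                    # Henyey-Greenstein scatter
                    gg = g_map[ix, iy, iz]
                    if gg == 0.0:
                        cost = 2.0 * np.random.random() - 1.0
                    else:
                        tmp = (1.0 - gg * gg) / (1.0 - gg + 2.0 * gg * np.random.random())
                        cost = (1.0 + gg * gg - tmp * tmp) / (2.0 * gg)
                        if cost > 1.0:
                            cost = 1.0
                        elif cost < -1.0:
                            cost = -1.0
                    sint = np.sqrt(1.0 - cost * cost)
                    psi = 2.0 * np.pi * np.random.random()
                    cosp = np.cos(psi)
                    sinp = np.sin(psi)
                    if abs(uz) > 0.99999:
                        nux = sint * cosp
                        nuy = sint * sinp
                        nuz = cost * (1.0 if uz >= 0.0 else -1.0)
                    else:
                        den = np.sqrt(1.0 - uz * uz)
                        nux = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                        nuy = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                        nuz = -sint * cosp * den + uz * cost
                    norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                    ux, uy, uz = nux / norm, nuy / norm, nuz / norm
                    break  # new tau
                else:
                    # traverse to the next voxel
                    x += ux * (sb + eps)
                    y += uy * (sb + eps)
                    z += uz * (sb + eps)
                    if mut > 0.0:
                        tau -= mut * sb
    return dep, escaped, transmitted


def mc_fluence(grid: VoxelGrid, beam: BeamSpec, n_photons: int = 1_000_000,
               seed: int = 0) -> MCResult:
    """Monte-Carlo fluence of a beam incident on the top surface.

    The per-voxel fluence is normalized so that the absorbed power/energy
    ``μa·Φ·dl³`` summed over voxels equals ``absorbed_fraction`` times the
    beam output.  Deterministic for a given seed.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    nx, ny, nz = grid.shape
    mu_a = np.ascontiguousarray(grid.property_map("mu_a"))
    mu_s = np.ascontiguousarray(grid.property_map("mu_s"))
    g_map = np.ascontiguousarray(grid.property_map("g"))
    cx, cy = beam.center if beam.center is not None else (
        nx * grid.dl / 2.0, ny * grid.dl / 2.0)
    if beam.profile == "gaussian":
        profile_flag, radius_param = 0, beam.gaussian_waist
    else:
        profile_flag, radius_param = 1, beam.diameter / 2.0
    dep, escaped, transmitted = _mc_kernel(
        mu_a, mu_s, g_map, grid.dl, nx, ny, nz,
        profile_flag, radius_param, cx, cy, int(n_photons),
        int(seed) & 0x7FFFFFFF,
    )
    dep /= n_photons
    escaped /= n_photons
    transmitted /= n_photons
    absorbed = float(dep.sum())
    # Φ = absorbed energy density / μa where μa > 0
    phi = np.zeros_like(dep)
    pos = mu_a > 0
    phi[pos] = dep[pos] * beam.power_or_energy / (mu_a[pos] * grid.voxel_volume)
    fluence = FluenceField(phi=phi, beam=beam, n_photons=n_photons, seed=seed)
    return MCResult(
        fluence=fluence,
        absorbed_fraction=absorbed,
        escaped_fraction=float(escaped),
        transmitted_fraction=float(transmitted),
        absorbed_map=dep,
    )


# ----------------------------------------------------------------------
# Diffusion approximation
# ----------------------------------------------------------------------

def _assemble_diffusion(grid: VoxelGrid) -> tuple[sp.csr_matrix, np.ndarray]:
    """7-point FD system for -div(D grad Φ) + μa Φ = q, Dirichlet Φ=0 outside."""
    nx, ny, nz = grid.shape
    dl = grid.dl
    mu_a = grid.property_map("mu_a").ravel()
    mu_t = (grid.property_map("mu_a") + grid.property_map("mu_s_reduced")).ravel()
    if np.any(mu_t <= 0):
        raise ValueError("diffusion coefficient undefined where mu_a + mu_s' = 0")
    D = 1.0 / (3.0 * mu_t)
    n = nx * ny * nz
    idx = np.arange(n).reshape(nx, ny, nz)
    diag = mu_a.copy()
    rows, cols, vals = [], [], []
    Dv = D.reshape(nx, ny, nz)
    for axis in range(3):
        for side in (-1, 1):
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if side == 1:
                src[axis] = slice(0, grid.shape[axis] - 1)
                dst[axis] = slice(1, grid.shape[axis])
            else:
                src[axis] = slice(1, grid.shape[axis])
                dst[axis] = slice(0, grid.shape[axis] - 1)
            Dface = 2.0 * Dv[tuple(src)] * Dv[tuple(dst)] / (
                Dv[tuple(src)] + Dv[tuple(dst)])
            coeff = Dface / dl**2
            rows.append(idx[tuple(src)].ravel())
            cols.append(idx[tuple(dst)].ravel())
            vals.append(-coeff.ravel())
            np.add.at(diag, idx[tuple(src)].ravel(), coeff.ravel())
    # Dirichlet Φ=0 ghost at the outer faces (extrapolated-boundary closure)
    for axis in range(3):
        for face in (0, grid.shape[axis] - 1):
            sl = [slice(None)] * 3
            sl[axis] = face
            face_idx = idx[tuple(sl)].ravel()
            np.add.at(diag, face_idx, 2.0 * D[face_idx] / dl**2)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return A, D


def solve_diffusion(grid: VoxelGrid, source: np.ndarray) -> FluenceField:
    """Solve the steady-state diffusion system for an arbitrary source (W/m³)."""
    A, _ = _assemble_diffusion(grid)
    q = np.asarray(source, dtype=np.float64).ravel()
    if q.size != A.shape[0]:
        raise ValueError("source shape does not match grid")
    n = A.shape[0]
    if n <= 150_000:
        phi = spla.spsolve(A.tocsc(), q)
    else:
        ml = spla.spilu(A.tocsc(), drop_tol=1e-5, fill_factor=10)
        M = spla.LinearOperator(A.shape, ml.solve)
        phi, info = spla.cg(A, q, rtol=1e-8, maxiter=5000, M=M)
        if info != 0:
            raise RuntimeError(f"diffusion solve did not converge (info={info})")
    phi = np.clip(phi, 0.0, None).reshape(grid.shape)
    beam = BeamSpec(power_or_energy=max(float(q.sum()) * grid.voxel_volume, 1e-300),
                    mode="continuous")
    return FluenceField(phi=phi, beam=beam)


def diffusion_fluence(grid: VoxelGrid, beam: BeamSpec) -> FluenceField:
    """Fluence by the steady-state diffusion approximation.

    The beam is mapped to an equivalent isotropic source sheet one transport
    mean free path below the surface, carrying the beam's lateral profile.
    Validity requires a scattering-dominated medium (μs' ≫ μa); a warning is
    emitted otherwise.
    """
    mu_a = grid.property_map("mu_a")
    mu_sp = grid.property_map("mu_s_reduced")
    if np.median(mu_sp[mu_a > 0]) < 5 * np.median(mu_a[mu_a > 0]):
        warnings.warn("diffusion approximation of questionable validity: "
                      "mu_s' is not much larger than mu_a", stacklevel=2)
    nx, ny, nz = grid.shape
    dl = grid.dl
    # depth of the equivalent source: one transport mean free path
    mu_t_surface = float(mu_a[nx // 2, ny // 2, 0] + mu_sp[nx // 2, ny // 2, 0])
    z_src = min(int((1.0 / mu_t_surface) / dl), nz - 1)
    cx, cy = beam.center if beam.center is not None else (nx * dl / 2, ny * dl / 2)
    x = (np.arange(nx) + 0.5) * dl - cx
    y = (np.arange(ny) + 0.5) * dl - cy
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    if beam.profile == "gaussian":
        w0 = beam.gaussian_waist
        lateral = np.exp(-2.0 * r2 / w0**2)
    else:
        lateral = (r2 <= (beam.diameter / 2.0) ** 2).astype(float)
    lateral_sum = lateral.sum()
    if lateral_sum == 0:
        raise ValueError("beam footprint does not overlap the grid surface")
    q = np.zeros(grid.shape)
    q[:, :, z_src] = (beam.power_or_energy / (lateral_sum * grid.voxel_volume)) * lateral
    out = solve_diffusion(grid, q)
    out.beam = beam
    return out


# ----------------------------------------------------------------------
# Derived quantities
# ----------------------------------------------------------------------

def heat_source(grid: VoxelGrid, fluence: FluenceField) -> HeatSourceField:
    """Photothermal source S = μa·Φ per voxel."""
    if fluence.phi.shape != tuple(grid.shape):
        raise ValueError("fluence grid does not match phantom grid")
    return HeatSourceField(S=grid.property_map("mu_a") * fluence.phi)


def depth_energy_integral(result: MCResult, grid: VoxelGrid,
                          absorber_label: int = 1,
                          reference: float | None = None) -> float:
    """Absorbed energy integrated over the absorber region.

    If ``reference`` is given (the same integral from a zero-cover-depth
    run), the relative energy is returned; otherwise the absolute absorbed
    fraction over the absorber region.
    """
    mask = grid.mask(absorber_label)
    if not mask.any():
        raise ValueError(f"grid has no region with label {absorber_label}")
    total = float(result.absorbed_map[mask].sum())
    if reference is None:
        return total
    if reference <= 0:
        raise ValueError("reference integral must be positive")
    return total / reference
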