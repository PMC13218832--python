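"""Bioheat conduction and its state-space form.

The temperature field obeys the conduction-only bioheat balance
``ρcp ∂T/∂t = ∇·(kv ∇T) + S`` (perfusion and metabolic terms dropped for
ex vivo tissue), discretized by an explicit Euler step with a 7-point
Laplacian.  Heterogeneous conductivity uses harmonic-mean kv across voxel
faces so interface fluxes are continuous.  The explicit scheme is stable
only under the CFL bound ``Δt ≤ Δl²ρcp / (6 kv)``.

For data fusion the same discretization is re-expressed as a linear state
transition over the stacked state ``x = [ΔT at ROI points; S at heat-source
points]`` with block matrix ``F = [[FT, FST], [0, I]]``: FT is the
conduction stencil, every nonzero of FST equals ``Δt/(ρcp)`` of the
receiving voxel, and the identity block encodes a constant-power source.
Temperatures inside the state space are increments ΔT relative to the
initial/bath temperature; absolute temperatures appear only at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .phantom import VoxelGrid

__all__ = [
    "TemperatureField",
    "HeatSourceField",
    "SimClock",
    "PointSets",
    "StateSpaceModel",
    "cfl_max_dt",
    "step_heat",
    "build_state_space",
]


@dataclass
class TemperatureField:
    """Absolute temperature per voxel (°C) at a simulation time (s)."""

    T: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=np.float64)
        if not np.all(np.isfinite(self.T)):
            raise ValueError("temperature field must be finite")


@dataclass
class HeatSourceField:
    """Volumetric heat source per voxel (W/m³ in continuous mode)."""

    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=np.float64)
        if np.any(self.S < 0):
            raise ValueError("heat source must be non-negative")


@dataclass
class SimClock:
    """Simulation step size and step counter."""

    dt: float
    n: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def cfl_max_dt(grid: VoxelGrid) -> float:
    """Largest stable explicit time step: min over voxels of Δl²ρcp/(6kv)."""
    rho_cp = grid.property_map("rho") * grid.property_map("cp")
    kv = grid.property_map("kv")
    return float(np.min(grid.dl**2 * rho_cp / (6.0 * kv)))


def _face_conductivities(kv: np.ndarray, axis: int) -> np.ndarray:
    """Harmonic-mean conductivity on interior faces along one axis."""
    lo = np.swapaxes(kv, 0, axis)[:-1]
    hi = np.swapaxes(kv, 0, axis)[1:]
    face = 2.0 * lo * hi / (lo + hi)
    return np.swapaxes(face, 0, axis)


def step_heat(T: TemperatureField, S: HeatSourceField, grid: VoxelGrid,
              clock: SimClock, bc: str = "dirichlet",
              T_boundary: float = 0.0) -> TemperatureField:
    """One explicit Euler conduction step.

    ``bc`` is ``"dirichlet"`` (outer faces clamped to ``T_boundary``, the
    water-bath/ambient temperature) or ``"adiabatic"`` (no flux).  Rejects
    time steps above the CFL bound.
    """
    if bc not in ("dirichlet", "adiabatic"):
        raise ValueError("bc must be 'dirichlet' or 'adiabatic'")
    bound = cfl_max_dt(grid)
    if clock.dt > bound * (1 + 1e-12):
        raise ValueError(
            f"dt={clock.dt:g}s exceeds the CFL stability bound {bound:g}s")
    if T.T.shape != tuple(grid.shape):
        raise ValueError("temperature shape does not match grid")
    if S.S.shape != tuple(grid.shape):
        raise ValueError("heat source shape does not match grid")
    kv = grid.property_map("kv")
    rho_cp = grid.property_map("rho") * grid.property_map("cp")
    dl2 = grid.dl**2
    Tn = T.T
    flux = np.zeros_like(Tn)
    for axis in range(3):
        kf = _face_conductivities(kv, axis)
        dT = np.diff(Tn, axis=axis)
        f = kf * dT / dl2  # flux into the lower-index voxel, per face
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        flux[tuple(lo)] += f
        flux[tuple(hi)] -= f
        if bc == "dirichlet":
            first = [slice(None)] * 3
            last = [slice(None)] * 3
            first[axis] = 0
            last[axis] = -1
            # ghost cell at T_boundary, same material as the face voxel
            flux[tuple(first)] += kv[tuple(first)] * (T_boundary - Tn[tuple(first)]) / dl2
            flux[tuple(last)] += kv[tuple(last)] * (T_boundary - Tn[tuple(last)]) / dl2
    T_next = Tn + clock.dt * (flux + S.S) / rho_cp
    return TemperatureField(T=T_next, time=T.time + clock.dt)


@dataclass
class PointSets:
    """Ordered point sets for state estimation.

    * ``roips`` — region-of-interest points, the full state lattice (N).
    * ``tops`` — heat-source points with a significant photoacoustic
      response (W), a subset of the ROI.
    * ``aops`` — actually observable points within the aperture's view (M),
      a subset of the TOPs.

    Points live on a regular sub-lattice of the simulation grid: voxel
    indices ``start + stride * lattice_index``.  ``roips`` are ordered in C
    order of the lattice; ``tops``/``aops`` orderings are fixed by their
    index arrays into ``roips``/``tops``.
    """

    roips: np.ndarray            # (N, 3) voxel indices
    top_in_roi: np.ndarray       # (W,) indices into roips
    aop_in_top: np.ndarray       # (M,) indices into top_in_roi
    lattice_shape: tuple[int, int, int]
    stride: int = 1
    start: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        self.roips = np.asarray(self.roips, dtype=np.int64)
        self.top_in_roi = np.asarray(self.top_in_roi, dtype=np.int64)
        self.aop_in_top = np.asarray(self.aop_in_top, dtype=np.int64)
        if self.roips.shape != (int(np.prod(self.lattice_shape)), 3):
            raise ValueError("roips must enumerate the full lattice")
        if self.top_in_roi.size and (
            self.top_in_roi.min() < 0 or self.top_in_roi.max() >= self.N
        ):
            raise ValueError("top_in_roi out of range")
        if self.aop_in_top.size and (
            self.aop_in_top.min() < 0 or self.aop_in_top.max() >= self.W
        ):
            raise ValueError("aop_in_top out of range")

    @property
    def N(self) -> int:
        return self.roips.shape[0]

    @property
    def W(self) -> int:
        return self.top_in_roi.shape[0]

    @property
    def M(self) -> int:
        return self.aop_in_top.shape[0]

    @property
    def tops(self) -> np.ndarray:
        return self.roips[self.top_in_roi]

    @property
    def aops(self) -> np.ndarray:
        return self.tops[self.aop_in_top]

    @property
    def aop_in_roi(self) -> np.ndarray:
        return self.top_in_roi[self.aop_in_top]

    @classmethod
    def regular(cls, grid: VoxelGrid, start: tuple[int, int, int],
                stop: tuple[int, int, int], stride: int = 1,
                top_mask: np.ndarray | None = None,
                aop_mask: np.ndarray | None = None) -> "PointSets":
        """ROI as a regular sub-lattice of the grid over ``[start, stop)``.

        ``top_mask``/``aop_mask`` are boolean per-voxel masks on the full
        grid; lattice points falling on True voxels become TOPs/AOPs.
        ``aop_mask`` is applied on top of ``top_mask`` (AOPs ⊆ TOPs).
        """
        axes = []
        for a in range(3):
            if not (0 <= start[a] < stop[a] <= grid.shape[a]):
                raise ValueError("ROI box outside grid")
            axes.append(np.arange(start[a], stop[a], stride))
        lattice_shape = tuple(len(ax) for ax in axes)
        ii, jj, kk = np.meshgrid(*axes, indexing="ij")
        roips = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        if top_mask is not None:
            on = top_mask[roips[:, 0], roips[:, 1], roips[:, 2]]
            top_in_roi = np.flatnonzero(on)
        else:
            top_in_roi = np.arange(roips.shape[0])
        if aop_mask is not None:
            tops = roips[top_in_roi]
            on = aop_mask[tops[:, 0], tops[:, 1], tops[:, 2]]
            aop_in_top = np.flatnonzero(on)
        else:
            aop_in_top = np.arange(top_in_roi.shape[0])
        return cls(roips=roips, top_in_roi=top_in_roi, aop_in_top=aop_in_top,
                   lattice_shape=lattice_shape, stride=stride,
                   start=tuple(start))


@dataclass
class StateSpaceModel:
    """Linear transition ``x(n+1) = F x(n)`` over ``[ΔT_ROI; S_TOP]``."""

    F: sp.csr_matrix
    point_sets: PointSets
    dt: float
    dl_eff: float
    bc: str = "dirichlet"
    rho_cp: np.ndarray = field(default=None)  # per ROI point

    @property
    def FT(self) -> sp.csr_matrix:
        n = self.point_sets.N
        return self.F[:n, :n]

    @property
    def FST(self) -> sp.csr_matrix:
        n = self.point_sets.N
        return self.F[:n, n:]

    @property
    def FS(self) -> sp.csr_matrix:
        n = self.point_sets.N
        return self.F[n:, n:]

    def propagate(self, x: np.ndarray) -> np.ndarray:
        return self.F @ x


def build_state_space(grid: VoxelGrid, point_sets: PointSets,
                      clock: SimClock, bc: str = "dirichlet") -> StateSpaceModel:
    """Assemble the sparse transition matrix F for the stacked state.

    FT follows the explicit conduction stencil on the ROI lattice (spacing
    ``stride × Δl``) with harmonic-mean face conductivity; lattice
    neighbours outside the ROI are treated per ``bc``: Dirichlet folds the
    bath (ΔT = 0) closure into the row, adiabatic closes the face.  FST
    routes each source point's ``S·Δt/(ρcp)`` into its own ROI row; FS is
    the identity (constant-power source).
    """
    if bc not in ("dirichlet", "adiabatic"):
        raise ValueError("bc must be 'dirichlet' or 'adiabatic'")
    ps = point_sets
    N, W = ps.N, ps.W
    dl_eff = grid.dl * ps.stride
    kv_full = grid.property_map("kv")
    rho_cp_full = grid.property_map("rho") * grid.property_map("cp")
    coords = ps.roips
    kv = kv_full[coords[:, 0], coords[:, 1], coords[:, 2]]
    rho_cp = rho_cp_full[coords[:, 0], coords[:, 1], coords[:, 2]]
    bound = float(np.min(dl_eff**2 * rho_cp / (6.0 * kv)))
    if clock.dt > bound * (1 + 1e-12):
        raise ValueError(
            f"dt={clock.dt:g}s exceeds the ROI-lattice CFL bound {bound:g}s")
    shape = ps.lattice_shape
    lat = np.arange(N).reshape(shape)
    kv_lat = kv.reshape(shape)
    lam = clock.dt / (rho_cp * dl_eff**2)  # per receiving point
    lam_lat = lam.reshape(shape)
    rows, cols, vals = [], [], []
    diag = np.ones(N)
    for axis in range(3):
        kf = _face_conductivities(kv_lat, axis)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        i_lo = lat[tuple(lo)].ravel()
        i_hi = lat[tuple(hi)].ravel()
        kfr = kf.ravel()
        # receiving at lo from hi and vice versa
        rows.append(i_lo); cols.append(i_hi); vals.append(lam[i_lo] * kfr)
        rows.append(i_hi); cols.append(i_lo); vals.append(lam[i_hi] * kfr)
        np.subtract.at(diag, i_lo, lam[i_lo] * kfr)
        np.subtract.at(diag, i_hi, lam[i_hi] * kfr)
        if bc == "dirichlet":
            for face in (0, -1):
                sl = [slice(None)] * 3
                sl[axis] = face
                fi = lat[tuple(sl)].ravel()
                # ghost at ΔT = 0, own conductivity
                diag[fi] -= lam_lat[tuple(sl)].ravel() * kv_lat[tuple(sl)].ravel()
    rows.append(np.arange(N)); cols.append(np.arange(N)); vals.append(diag)
    FT = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    )
    # FST: value Δt/(ρcp) of the receiving voxel, one nonzero per TOP column
    top_rows = ps.top_in_roi
    FST = sp.csr_matrix(
        (clock.dt / rho_cp[top_rows], (top_rows, np.arange(W))), shape=(N, W))
    F = sp.bmat(
        [[FT, FST], [None, sp.identity(W, format="csr")]], format="csr")
    return StateSpaceModel(F=F, point_sets=ps, dt=clock.dt, dl_eff=dl_eff,
                           bc=bc, rho_cp=rho_cp)
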