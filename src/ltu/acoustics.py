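"""Photoacoustic forward model and universal back-projection.

The forward model is the analytic point-detector solution of the PA wave
equation for a homogeneous sound speed: each detector trace is the time
derivative of the spherical-mean (isochronous-shell) projection of the
initial pressure, which reproduces the characteristic N-shaped bipolar
pulse of compact sources.  Reconstruction is universal back-projection:
the filtered term ``b(d,t) = p' - t ∂p'/∂t`` is evaluated at the
time-of-flight ``t = |r-d|/vs`` for every element and summed with
solid-angle weights ``dΩ``, normalized by the total angle ``Ω0`` seen from
each voxel.  With a limited-view linear aperture the reconstruction
concentrates on interfaces facing the probe (the upper surface of a
sphere), as expected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .phantom import VoxelGrid
from .thermal import HeatSourceField, TemperatureField
from .optics import FluenceField

__all__ = [
    "GrueneisenModel",
    "PressureField",
    "TransducerArray",
    "RFData",
    "NoiseSpec",
    "initial_pressure",
    "forward_project",
    "ubp_reconstruct",
    "estimate_deconvolution",
]


@dataclass(frozen=True)
class GrueneisenModel:
    """Linear temperature dependence of the Grüneisen parameter, Γ = A + B·T.

    T is in °C, so A is the extrapolated intercept at 0 °C and may be
    negative for soft tissue; what matters physically is Γ > 0 over the
    operating range.  The defaults give a relative amplitude slope
    B/Γ(36 °C) ≈ 3.5 %/K, the soft-tissue scale.  A single (A, B) pair
    applies to the whole field: the Grüneisen coefficient of one tissue
    type is taken as spatially uniform.  A per-region block hook exists in
    the observation-matrix builder for heterogeneous maps, but per-region
    calibration is out of scope.
    """

    A: float = -0.031
    B: float = 0.004
    valid_range: tuple[float, float] = (30.0, 45.0)

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if self.gamma(lo) <= 0 or self.gamma(hi) <= 0:
            raise ValueError(
                f"Gamma = A + B*T must stay positive over {self.valid_range}")

    def gamma(self, T) -> np.ndarray | float:
        return self.A + self.B * np.asarray(T, dtype=float)


@dataclass
class PressureField:
    """Initial pressure p0 per voxel (relative units)."""

    p0: np.ndarray
    grid: VoxelGrid | None = None

    def __post_init__(self) -> None:
        self.p0 = np.asarray(self.p0, dtype=np.float64)
        if not np.all(np.isfinite(self.p0)):
            raise ValueError("initial pressure must be finite")


@dataclass
class TransducerArray:
    """Ultrasound detector array of point-like elements.

    Default geometry is the system probe: a 128-element, 5.5 MHz linear
    array in the x–z imaging plane at the tissue surface (z = 0), elements
    spread along x.  ``element_positions`` is an (n, 3) array of physical
    coordinates; elements must be coplanar and must not sit below the
    tissue surface.
    """

    n_elements: int = 128
    pitch: float = 0.3e-3
    center_frequency: float = 5.5e6
    sampling_rate: float = 40e6
    element_positions: np.ndarray | None = None
    bandwidth: float = 0.8

    def __post_init__(self) -> None:
        if self.element_positions is None:
            x = (np.arange(self.n_elements) - (self.n_elements - 1) / 2) * self.pitch
            self.element_positions = np.stack(
                [x, np.zeros_like(x), np.zeros_like(x)], axis=1)
        self.element_positions = np.asarray(self.element_positions, dtype=np.float64)
        if self.element_positions.shape != (self.n_elements, 3):
            raise ValueError("element_positions must be (n_elements, 3)")
        if self.sampling_rate <= 2 * self.center_frequency * (1 + self.bandwidth / 2):
            raise ValueError("sampling_rate below twice the upper band edge")

    @classmethod
    def linear(cls, n_elements: int = 128, pitch: float = 0.3e-3,
               center: tuple[float, float, float] = (0.0, 0.0, 0.0),
               **kwargs) -> "TransducerArray":
        """Linear array along x centered at ``center``."""
        x = (np.arange(n_elements) - (n_elements - 1) / 2) * pitch
        pos = np.stack([x + center[0],
                        np.full(n_elements, center[1]),
                        np.full(n_elements, center[2])], axis=1)
        return cls(n_elements=n_elements, pitch=pitch,
                   element_positions=pos, **kwargs)

    @classmethod
    def planar(cls, nx: int, ny: int, pitch: float,
               center: tuple[float, float, float] = (0.0, 0.0, 0.0),
               **kwargs) -> "TransducerArray":
        """Dense planar (synthetic full-view) aperture at z = center[2]."""
        x = (np.arange(nx) - (nx - 1) / 2) * pitch + center[0]
        y = (np.arange(ny) - (ny - 1) / 2) * pitch + center[1]
        X, Y = np.meshgrid(x, y, indexing="ij")
        pos = np.stack([X.ravel(), Y.ravel(),
                        np.full(nx * ny, center[2])], axis=1)
        return cls(n_elements=nx * ny, pitch=pitch,
                   element_positions=pos, **kwargs)

    def shifted(self, offset: tuple[float, float, float]) -> "TransducerArray":
        """Same array translated by a physical offset (scan step)."""
        return TransducerArray(
            n_elements=self.n_elements, pitch=self.pitch,
            center_frequency=self.center_frequency,
            sampling_rate=self.sampling_rate,
            element_positions=self.element_positions + np.asarray(offset),
            bandwidth=self.bandwidth)


@dataclass
class RFData:
    """Per-element time series on a common time base."""

    samples: np.ndarray  # (n_elements, n_samples)
    dt_sample: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.shape[1]) * self.dt_sample


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for simulated acquisitions.

    ``channel_snr_db`` sets additive white Gaussian noise per RF channel
    relative to the signal RMS; ``pulse_jitter_frac`` is the fractional
    standard deviation of per-frame pulse energy (a multiplicative factor
    common to all channels of one frame, the dominant error source of PA
    thermometry).
    """

    channel_snr_db: float = np.inf
    pulse_jitter_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pulse_jitter_frac < 0:
            raise ValueError("pulse_jitter_frac must be >= 0")


def initial_pressure(heat_or_fluence, grid: VoxelGrid,
                     T: TemperatureField | float,
                     gm: GrueneisenModel) -> PressureField:
    """Initial pressure p0 = Γ(T)·Φ·μa = Γ(T)·S (relative units).

    Accepts either a :class:`FluenceField` (multiplied by μa) or a
    :class:`HeatSourceField` (already μa·Φ).  ``T`` may be a uniform
    temperature or a co-registered field.
    """
    if isinstance(heat_or_fluence, FluenceField):
        if heat_or_fluence.phi.shape != tuple(grid.shape):
            raise ValueError("fluence grid does not match phantom grid")
        dep = grid.property_map("mu_a") * heat_or_fluence.phi
    elif isinstance(heat_or_fluence, HeatSourceField):
        if heat_or_fluence.S.shape != tuple(grid.shape):
            raise ValueError("heat source grid does not match phantom grid")
        dep = heat_or_fluence.S
    else:
        raise TypeError("expected FluenceField or HeatSourceField")
    temps = T.T if isinstance(T, TemperatureField) else np.asarray(T, dtype=float)
    gamma = gm.gamma(temps)
    if np.any(np.asarray(gamma) <= 0):
        raise ValueError("Grueneisen parameter non-positive at some voxels")
    return PressureField(p0=gamma * dep, grid=grid)


def _slab_mask(grid: VoxelGrid, slab: tuple[float, float] | None) -> np.ndarray:
    if slab is None:
        return np.ones(grid.shape, dtype=bool)
    y0, half = slab
    y = grid.origin[1] + (np.arange(grid.shape[1]) + 0.5) * grid.dl
    mask = np.zeros(grid.shape, dtype=bool)
    mask[:, np.abs(y - y0) <= half, :] = True
    return mask


def forward_project(p0: PressureField, array: TransducerArray, vs: float,
                    noise: NoiseSpec | None = None,
                    slab: tuple[float, float] | None = None,
                    pad_time: float = 2e-6,
                    voxel_bandlimit: float = 1.0) -> RFData:
    """Simulate channel data from an initial pressure distribution.

    Each element trace is ``∂/∂t`` of the isochronous-shell projection of
    p0 with far-field 1/r weighting (the exact point-detector solution up
    to a constant).  ``slab`` restricts sources to an imaging slab
    ``(y_center, half_thickness)`` for 2-D mode.  Additive channel noise
    and one multiplicative pulse-energy factor are applied if ``noise`` is
    given.
    """
    grid = p0.grid
    if grid is None:
        raise ValueError("PressureField carries no grid reference")
    if np.any(array.element_positions[:, 2] > grid.origin[2] + 1e-12):
        raise ValueError("grid extends behind the array plane")
    mask = _slab_mask(grid, slab) & (p0.p0 != 0)
    src = p0.p0[mask]
    idx = np.argwhere(mask)
    pos = grid.origin + (idx + 0.5) * grid.dl
    dt_s = 1.0 / array.sampling_rate
    if src.size == 0:
        n_t = int(round(pad_time / dt_s))
        return RFData(samples=np.zeros((array.n_elements, n_t)), dt_sample=dt_s)
    # common time base covering delays to every corner of the grid, so a
    # later reconstruction of any voxel stays inside the trace
    corners = np.array(grid.origin) + np.array(
        [[i, j, k] for i in (0, grid.shape[0]) for j in (0, grid.shape[1])
         for k in (0, grid.shape[2])]) * grid.dl
    d_corner = np.linalg.norm(
        corners[None, :, :] - array.element_positions[:, None, :], axis=2)
    t_max = d_corner.max() / vs + pad_time
    n_t = int(np.ceil(t_max / dt_s)) + 2
    shell = np.zeros((array.n_elements, n_t))
    for e in range(array.n_elements):
        d = np.linalg.norm(pos - array.element_positions[e], axis=1)
        w = src * grid.voxel_volume / (4.0 * np.pi * d)
        tf = d / vs / dt_s
        i0 = np.floor(tf).astype(np.int64)
        frac = tf - i0
        np.add.at(shell[e], i0, w * (1 - frac))
        np.add.at(shell[e], i0 + 1, w * frac)
    # band-limit the shell projection at the voxel scale before the time
    # derivative: a voxel is a finite volume, not a point, and the raw
    # histogram carries voxelization noise finer than the grid resolution
    sigma_bins = voxel_bandlimit * grid.dl / vs / dt_s
    shell = gaussian_filter1d(shell, sigma_bins, axis=1, mode="constant")
    # s(t) = (1/vs) d/dt [shell / (vs * dt)] up to constant scaling
    samples = np.gradient(shell, dt_s, axis=1) / (vs * dt_s)
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        if noise.pulse_jitter_frac > 0:
            samples = samples * (1.0 + noise.pulse_jitter_frac * rng.standard_normal())
        if np.isfinite(noise.channel_snr_db):
            rms = np.sqrt(np.mean(samples**2))
            sd = rms * 10 ** (-noise.channel_snr_db / 20.0)
            samples = samples + sd * rng.standard_normal(samples.shape)
    return RFData(samples=samples, dt_sample=dt_s)


def ubp_reconstruct(rf: RFData, array: TransducerArray, vs: float,
                    recon_grid: VoxelGrid,
                    slab: tuple[float, float] | None = None) -> PressureField:
    """Universal back-projection of channel data onto a voxel grid.

    For each voxel the filtered term ``b = p' - t ∂p'/∂t`` is linearly
    interpolated at the element's time of flight and summed with
    solid-angle weights ``dΩ = cosθ / r²``, normalized by ``Ω0 = Σ dΩ``.
    Elements whose time of flight exceeds the trace are dropped with a
    warning.  ``slab`` restricts the output to an imaging slab.
    """
    t = rf.times
    p = rf.samples
    dpdt = np.gradient(p, rf.dt_sample, axis=1)
    b = p - t[None, :] * dpdt
    mask = _slab_mask(recon_grid, slab)
    idx = np.argwhere(mask)
    pos = recon_grid.origin + (idx + 0.5) * recon_grid.dl
    acc = np.zeros(idx.shape[0])
    omega = np.zeros(idx.shape[0])
    n_t = p.shape[1]
    dropped = 0
    for e in range(array.n_elements):
        d = pos - array.element_positions[e]
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, recon_grid.dl * 0.5)
        cos_theta = np.abs(d[:, 2]) / r
        tf = (r / vs - rf.t0) / rf.dt_sample
        inside = (tf >= 0) & (tf <= n_t - 2)
        if not inside.all():
            dropped += 1
        i0 = np.clip(np.floor(tf).astype(np.int64), 0, n_t - 2)
        frac = np.clip(tf - i0, 0.0, 1.0)
        bval = b[e, i0] * (1 - frac) + b[e, i0 + 1] * frac
        dw = cos_theta / r**2
        acc[inside] += (bval * dw)[inside]
        omega[inside] += dw[inside]
    if dropped:
        warnings.warn(
            f"{dropped} element(s) had voxels outside the RF time coverage; "
            "their contributions were dropped", stacklevel=2)
    out = np.zeros(idx.shape[0])
    ok = omega > 0
    out[ok] = 2.0 * acc[ok] / omega[ok]
    field = np.zeros(recon_grid.shape)
    field[mask] = out
    return PressureField(p0=field, grid=recon_grid)


def estimate_deconvolution(rf: RFData, array: TransducerArray,
                           mode: str = "identity",
                           reg: float = 0.05) -> RFData:
    """Approximate p' from band-limited channel data.

    ``mode="identity"`` passes the data through unchanged (the default: the
    forward model here is broadband).  ``mode="equalize"`` divides each
    trace's spectrum by a Gaussian band model around the array's center
    frequency with Tikhonov regularization, flattening the in-band
    response.  Equalization is not idempotent; applying it twice
    over-whitens the data.
    """
    if mode == "identity":
        return RFData(samples=rf.samples.copy(), dt_sample=rf.dt_sample, t0=rf.t0)
    if mode != "equalize":
        raise ValueError("mode must be 'identity' or 'equalize'")
    warnings.warn("spectral equalization is not idempotent; apply once",
                  stacklevel=2)
    n = rf.samples.shape[1]
    freqs = np.fft.rfftfreq(n, rf.dt_sample)
    fc = array.center_frequency
    sigma = array.bandwidth * fc / 2.355  # fractional bandwidth as FWHM
    response = np.exp(-0.5 * ((freqs - fc) / sigma) ** 2)
    spec = np.fft.rfft(rf.samples, axis=1)
    eq = response / (response**2 + reg**2)
    out = np.fft.irfft(spec * eq[None, :], n=n, axis=1)
    return RFData(samples=out, dt_sample=rf.dt_sample, t0=rf.t0)
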