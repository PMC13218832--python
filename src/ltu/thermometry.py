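"""Photoacoustic thermometry.

Within the biologically viable temperature range the Grüneisen parameter —
and with it the photoacoustic amplitude at fixed optical deposition — is
linear in temperature: Γ = A + B·T.  The relative amplitude increment

    α = (p0(T) − p0(T0)) / p0(T0) = B·ΔT / (A + B·T0)

is therefore an affine thermometer with observation gain
``B/(A + B·T0)`` per kelvin.  Only this composite gain enters the
pipeline; it is calibrated from a water-bath temperature sweep, never
decomposed into A and B.

The module also selects the observable point sets: TOPs (voxels with a
significant photoacoustic response, thresholded at a fraction of the
reconstruction maximum) and AOPs (TOPs inside the aperture's view), and
assembles the Kalman observation matrix H = [gain·I | 0 | 0] over the
stacked state [ΔT_ROI; S_TOP].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .acoustics import PressureField
from .thermal import PointSets

__all__ = [
    "CalibrationModel",
    "ObservationMatrix",
    "AlphaSeries",
    "alpha",
    "delta_T",
    "calibrate",
    "select_tops",
    "build_H",
]


@dataclass
class CalibrationModel:
    """Observation gain of the photoacoustic thermometer.

    ``slope_coeff`` is B/(A + B·T0) in 1/K: the slope of α against the
    temperature increment above the reference ``T0``.  ``fit_r`` is the
    Pearson correlation of the calibration fit (reported whenever the model
    was fitted rather than configured).
    """

    slope_coeff: float
    T0: float
    fit_r: float | None = None
    source: str = "configured"

    def __post_init__(self) -> None:
        if self.slope_coeff <= 0:
            raise ValueError("slope_coeff must be positive")
        if self.source not in ("fit", "configured"):
            raise ValueError("source must be 'fit' or 'configured'")
        if self.source == "fit" and self.fit_r is None:
            raise ValueError("fitted calibration must report fit_r")


@dataclass
class AlphaSeries:
    """α values per actually-observable point over acquisition frames."""

    alpha: np.ndarray        # (n_frames, M)
    p0_ref: np.ndarray       # (M,) reference amplitudes at T0

    def __post_init__(self) -> None:
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=np.float64))
        self.p0_ref = np.asarray(self.p0_ref, dtype=np.float64)
        if self.alpha.shape[1] != self.p0_ref.shape[0]:
            raise ValueError("alpha frames and p0_ref lengths disagree")

    @classmethod
    def from_frames(cls, frames: np.ndarray, p0_ref: np.ndarray,
                    noise_floor: float = 0.0) -> "AlphaSeries":
        """Build α from raw amplitude frames against a reference frame.

        Points whose reference amplitude is at or below ``noise_floor``
        cannot form a meaningful ratio; they are excluded with a warning
        (callers should drop them from the AOP set).
        """
        frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
        p0_ref = np.asarray(p0_ref, dtype=np.float64)
        bad = p0_ref <= noise_floor
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} point(s) at/below the noise floor excluded "
                "from the observable set", stacklevel=2)
        keep = ~bad
        a = (frames[:, keep] - p0_ref[keep]) / p0_ref[keep]
        return cls(alpha=a, p0_ref=p0_ref[keep])


def alpha(p0_T, p0_T0):
    """Relative photoacoustic increment α = (p0(T) − p0(T0)) / p0(T0)."""
    p0_T = np.asarray(p0_T, dtype=np.float64)
    p0_T0 = np.asarray(p0_T0, dtype=np.float64)
    if np.any(p0_T0 <= 0):
        raise ValueError("reference amplitude must be positive (above noise)")
    return (p0_T - p0_T0) / p0_T0


def delta_T(alpha_vec, cal: CalibrationModel):
    """Temperature increment ΔT = α / slope_coeff (K), elementwise.

    Valid only within the linear (biologically viable) range of the
    Grüneisen model; a warning is issued when the implied temperatures
    leave roughly 30–45 °C.
    """
    a = alpha_vec.alpha if isinstance(alpha_vec, AlphaSeries) else np.asarray(alpha_vec)
    dT = a / cal.slope_coeff
    if np.any(cal.T0 + dT > 50.0) or np.any(cal.T0 + dT < 20.0):
        warnings.warn("implied temperatures leave the calibrated linear range",
                      stacklevel=2)
    return dT


def calibrate(temps, pa_amplitudes, T0: float) -> CalibrationModel:
    """Fit the observation gain from a water-bath temperature sweep.

    ``pa_amplitudes`` is (n_temps,) or (n_temps, M): mean photoacoustic
    amplitude per observable point at each bath temperature.  α is formed
    against the amplitude at the temperature closest to ``T0`` and fitted
    against (T − T0) by least squares; the slope is the gain, and the
    Pearson correlation of the fit is reported.
    """
    temps = np.asarray(temps, dtype=np.float64)
    amps = np.atleast_2d(np.asarray(pa_amplitudes, dtype=np.float64).T).T
    if temps.size < 3 or np.unique(temps).size < 3:
        raise ValueError("calibration needs at least 3 distinct temperatures")
    if temps.size != amps.shape[0]:
        raise ValueError("one amplitude row per temperature required")
    if np.any(amps <= 0):
        raise ValueError("amplitudes must be positive")
    i_ref = int(np.argmin(np.abs(temps - T0)))
    ref = amps[i_ref]
    a = (amps - ref) / ref
    x = np.repeat(temps - T0, amps.shape[1])
    y = a.ravel()
    fit = stats.linregress(x, y)
    if not np.isfinite(fit.slope) or fit.slope <= 0:
        raise ValueError("degenerate calibration fit (non-positive slope)")
    return CalibrationModel(slope_coeff=float(fit.slope), T0=float(T0),
                            fit_r=float(fit.rvalue), source="fit")


def select_tops(p0_recon: PressureField, threshold_frac: float = 0.05,
                aperture_slab: tuple[float, float] | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Select observable voxels from a reconstructed pressure field.

    TOPs are voxels whose |p0′| reaches ``threshold_frac`` of the field
    maximum (the same fraction used to delimit the beam spot); AOPs are
    TOPs restricted to the aperture's view, here an imaging slab
    ``(y_center, half_thickness)``.  Returns boolean per-voxel masks
    ``(top_mask, aop_mask)`` to feed :meth:`PointSets.regular`.
    """
    mag = np.abs(p0_recon.p0)
    peak = mag.max()
    if peak <= 0:
        raise ValueError("reconstruction is identically zero; no TOPs")
    top_mask = mag > 0 if threshold_frac == 0 else mag >= threshold_frac * peak
    if not top_mask.any():
        raise ValueError(
            f"threshold {threshold_frac} selected no voxels "
            f"(max |p0'| = {peak:g})")
    if aperture_slab is None:
        aop_mask = top_mask.copy()
    else:
        grid = p0_recon.grid
        y0, half = aperture_slab
        y = grid.origin[1] + (np.arange(grid.shape[1]) + 0.5) * grid.dl
        slab = np.zeros(grid.shape, dtype=bool)
        slab[:, np.abs(y - y0) <= half, :] = True
        aop_mask = top_mask & slab
    return top_mask, aop_mask


@dataclass
class ObservationMatrix:
    """Sparse H mapping the stacked state to α measurements.

    In the uniform-Γ case H carries exactly M nonzeros, all equal to the
    calibration gain, on the AOP columns of the ΔT block; all S columns are
    zero (the heat source is never directly observed).  ``gains`` supports
    the per-region block structure for heterogeneous Γ maps (one gain per
    AOP); per-region calibration itself is not provided.
    """

    H: sp.csr_matrix
    M: int
    N: int
    W: int
    gain: float | np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.H @ x


def build_H(points: PointSets, cal: CalibrationModel,
            gains: np.ndarray | None = None) -> ObservationMatrix:
    """Assemble H = [gain·I over AOP columns | 0 | 0] for the stacked state."""
    M, N, W = points.M, points.N, points.W
    cols = points.aop_in_roi
    if np.unique(cols).size != M:
        raise ValueError("AOP ordering maps to duplicate ROI points")
    if gains is None:
        data = np.full(M, cal.slope_coeff)
        gain = cal.slope_coeff
    else:
        gains = np.asarray(gains, dtype=np.float64)
        if gains.shape != (M,):
            raise ValueError("gains must have one entry per AOP")
        data = gains.copy()
        gain = gains
    H = sp.csr_matrix((data, (np.arange(M), cols)), shape=(M, N + W))
    return ObservationMatrix(H=H, M=M, N=N, W=W, gain=gain)
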