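"""Kalman-filter fusion of the conduction model with PA thermometry.

The stacked state ``x = [ΔT over ROI points; S over heat-source points]``
evolves through the sparse transition F built by :mod:`ltu.thermal`; the
measurement is the α vector itself (H carries the calibration gain, so the
calibration is applied exactly once).  The recursion is the standard
predict/update pair

    P  = F P̂ Fᵀ + Q
    K  = P Hᵀ (H P Hᵀ + R)⁻¹
    x̂  = x + K (α − H x)
    P̂  = (I − K H) P

with diagonal Q and R.  Because the heat source block propagates through
an identity (constant-power source) but carries a large initial
covariance, the filter gradually converges the heat-source estimate from
the temperature observations — which is what corrects the temperature at
points the aperture never sees.

The covariance is dense, so the fusion ROI is meant to be a reduced
lattice (a decimated sub-box of the simulation grid); sizes up to
N + W ≈ 2·10⁴ are practical on a desktop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .thermal import StateSpaceModel
from .thermometry import AlphaSeries, ObservationMatrix

__all__ = [
    "StateVector",
    "KalmanConfig",
    "KalmanState",
    "predict",
    "update",
    "estimate_R",
    "run_fusion",
    "FusionResult",
]

_R_FLOOR = 1e-12


@dataclass
class StateVector:
    """Stacked state [ΔT_ROI (K); S_TOP (W/m³)]."""

    x: np.ndarray
    N: int
    W: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.shape != (self.N + self.W,):
            raise ValueError("state length must be N + W")

    @property
    def delta_T(self) -> np.ndarray:
        return self.x[: self.N]

    @property
    def S(self) -> np.ndarray:
        return self.x[self.N :]


@dataclass
class KalmanConfig:
    """Noise and initialization settings.

    ``q_T`` and ``q_S`` are per-step process-noise variances for the ΔT
    block (K²) and the S block ((W/m³)²); ``r`` the measurement-noise
    variance of α (dimensionless²: scalar, per-AOP diagonal, or a full
    M×M covariance for correlated noise).  The transient /
    steady-state pair for q_T follows the operating guidance of roughly
    1e-3–1e-2 during active heating and 1e-5–1e-4 once quasi-static; the
    scheduler in :func:`run_fusion` switches on commanded laser power.
    ``p0_T`` and ``p0_S`` scale the initial covariance: small on ΔT (the
    run starts equilibrated at the bath temperature), large on S (the heat
    source is the quantity the filter must converge).
    """

    q_T: float = 1e-3
    q_T_steady: float = 1e-4
    q_S: float = 0.0
    r: float | np.ndarray = 1e-4
    p0_T: float = 1e-4
    p0_S: float = 0.0

    def __post_init__(self) -> None:
        if self.q_T < 0 or self.q_T_steady < 0 or self.q_S < 0:
            raise ValueError("process-noise variances must be >= 0")
        r = np.asarray(self.r)
        r_check = np.diag(r) if r.ndim == 2 else r
        if np.any(r_check <= 0):
            raise ValueError("measurement-noise variance must be > 0")
        if self.p0_T < 0 or self.p0_S < 0:
            raise ValueError("initial covariance scales must be >= 0")

    def q_diag(self, N: int, W: int, heating: bool = True) -> np.ndarray:
        qT = self.q_T if heating else self.q_T_steady
        return np.concatenate([np.full(N, qT), np.full(W, self.q_S)])

    def r_matrix(self, M: int) -> np.ndarray:
        """Measurement-noise covariance: scalar / per-AOP diagonal / full.

        A full (M×M) matrix supports correlated noise, in particular the
        common-mode component of pulse-energy jitter, which hits every
        channel of a frame coherently and must not be counted as M
        independent measurements.
        """
        r = np.asarray(self.r, dtype=np.float64)
        if r.ndim == 2:
            if r.shape != (M, M):
                raise ValueError("full R must be (M, M)")
            out = r.copy()
            out[np.diag_indices(M)] = np.maximum(np.diag(out), _R_FLOOR)
            return out
        return np.diag(np.maximum(np.broadcast_to(r, (M,)), _R_FLOOR))


@dataclass
class KalmanState:
    """Covariance state of the filter (dense)."""

    P: np.ndarray
    K: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("P must be square")

    @classmethod
    def initial(cls, cfg: KalmanConfig, N: int, W: int) -> "KalmanState":
        d = np.concatenate([np.full(N, cfg.p0_T), np.full(W, cfg.p0_S)])
        return cls(P=np.diag(d))


def predict(x: StateVector, model: StateSpaceModel, ks: KalmanState,
            cfg: KalmanConfig, heating: bool = True
            ) -> tuple[StateVector, KalmanState]:
    """Time update: x ← F x,  P ← F P̂ Fᵀ + Q."""
    n = x.x.shape[0]
    if model.F.shape != (n, n) or ks.P.shape != (n, n):
        raise ValueError("state/model/covariance dimensions disagree")
    x_new = StateVector(x=model.F @ x.x, N=x.N, W=x.W)
    # F P Fᵀ = F (F P)ᵀ for symmetric P: two sparse-dense products
    FP = np.asarray(model.F @ ks.P)
    P = np.asarray(model.F @ FP.T)
    P[np.diag_indices_from(P)] += cfg.q_diag(x.N, x.W, heating)
    P = 0.5 * (P + P.T)
    return x_new, KalmanState(P=P, K=ks.K)


def update(x: StateVector, ks: KalmanState, alpha_obs: np.ndarray,
           H: ObservationMatrix, cfg: KalmanConfig
           ) -> tuple[StateVector, KalmanState]:
    """Measurement update with the α vector as the measurement."""
    alpha_obs = np.asarray(alpha_obs, dtype=np.float64).ravel()
    if alpha_obs.shape[0] != H.M:
        raise ValueError(f"expected {H.M} measurements, got {alpha_obs.shape[0]}")
    Hm = H.H
    PHt = ks.P @ Hm.T.toarray().astype(np.float64) if sp.issparse(Hm) else ks.P @ Hm.T
    S_inn = np.asarray(Hm @ PHt) + cfg.r_matrix(H.M)
    try:
        cho = scipy.linalg.cho_factor(S_inn)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(S_inn)
        raise np.linalg.LinAlgError(
            f"innovation covariance not positive definite (cond={cond:.3e}); "
            "increase R or reduce P_init") from exc
    K = scipy.linalg.cho_solve(cho, PHt.T).T
    innovation = alpha_obs - Hm @ x.x
    x_new = StateVector(x=x.x + K @ innovation, N=x.N, W=x.W)
    P_hat = ks.P - K @ (Hm @ ks.P)
    P_hat = 0.5 * (P_hat + P_hat.T)
    return x_new, KalmanState(P=P_hat, K=K)


def estimate_R(static_alpha: AlphaSeries | np.ndarray,
               structure: str = "diagonal") -> np.ndarray:
    """Measurement-noise model from a static (non-heating) acquisition.

    ``structure="diagonal"`` (default) returns the per-AOP sample variance
    of α across repeated frames.  ``structure="common_mode"`` returns the
    full covariance of a two-component model fitted to the same frames —
    a rank-one common-mode term (the variance of the per-frame mean, the
    signature of pulse-energy jitter shared by every channel) plus the
    per-AOP residual variance on the diagonal.  Identically-zero
    fluctuation is degenerate; a small floor keeps the update well posed.
    """
    a = static_alpha.alpha if isinstance(static_alpha, AlphaSeries) else np.atleast_2d(static_alpha)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 static frames to estimate R")
    if structure == "diagonal":
        return np.maximum(a.var(axis=0, ddof=1), _R_FLOOR)
    if structure != "common_mode":
        raise ValueError("structure must be 'diagonal' or 'common_mode'")
    common = a.mean(axis=1)
    var_c = common.var(ddof=1)
    resid = a - common[:, None]
    var_r = np.maximum(resid.var(axis=0, ddof=1), _R_FLOOR)
    M = a.shape[1]
    return var_c * np.ones((M, M)) + np.diag(var_r)


@dataclass
class FusionResult:
    """Trajectories and diagnostics of a fusion run."""

    times: np.ndarray                 # (n_steps,)
    delta_T: np.ndarray               # (n_steps, N) fused ΔT over ROI
    S_est: np.ndarray                 # (n_steps, W) heat-source estimates
    innovations: np.ndarray           # (n_steps, M)
    P_trace: np.ndarray               # (n_steps,)
    model_only_delta_T: np.ndarray    # (n_steps, N) open-loop model
    config: KalmanConfig = field(repr=False, default=None)


def run_fusion(model: StateSpaceModel, H: ObservationMatrix,
               alpha_frames: np.ndarray, cfg: KalmanConfig,
               x0: StateVector | None = None,
               heating_schedule: np.ndarray | None = None,
               obs_times: np.ndarray | None = None) -> FusionResult:
    """Predict/update loop over a sequence of α observation frames.

    ``alpha_frames`` is (n_steps, M), one frame per model step (NaN rows
    mean no observation at that step: predict only).  If ``obs_times`` is
    given it is checked against the model clock; frames are associated to
    the nearest model step with a warning when misaligned.
    ``heating_schedule`` is a boolean per-step flag (commanded laser on):
    it selects the transient vs steady-state process noise, and while the
    laser is off the heat-source block injects no heat (its magnitude is
    retained in the state for a later re-switch-on).
    """
    import warnings as _w

    ps = model.point_sets
    N, W, M = ps.N, ps.W, ps.M
    alpha_frames = np.atleast_2d(np.asarray(alpha_frames, dtype=np.float64))
    n_steps = alpha_frames.shape[0]
    if alpha_frames.shape[1] != M:
        raise ValueError("alpha frames do not match the AOP count")
    if obs_times is not None:
        model_times = (np.arange(n_steps) + 1) * model.dt
        if np.max(np.abs(obs_times - model_times)) > model.dt / 2:
            _w.warn("observation timestamps not aligned to model steps; "
                    "frames associated to the nearest step", stacklevel=2)
    if heating_schedule is None:
        heating_schedule = np.ones(n_steps, dtype=bool)
    x = x0 if x0 is not None else StateVector(x=np.zeros(N + W), N=N, W=W)
    xm = StateVector(x=x.x.copy(), N=N, W=W)
    ks = KalmanState.initial(cfg, N, W)
    out = FusionResult(
        times=(np.arange(n_steps) + 1) * model.dt,
        delta_T=np.empty((n_steps, N)),
        S_est=np.empty((n_steps, W)),
        innovations=np.full((n_steps, M), np.nan),
        P_trace=np.empty(n_steps),
        model_only_delta_T=np.empty((n_steps, N)),
        config=cfg,
    )
    for n in range(n_steps):
        on = bool(heating_schedule[n])
        s_prev = x.x[N:].copy()
        sm_prev = xm.x[N:].copy()
        x, ks = predict(x, model, ks, cfg, heating=on)
        xm = StateVector(x=model.F @ xm.x, N=N, W=W)
        if not on and W:
            # commanded source off: remove the source injection of this step
            x.x[:N] -= model.FST @ s_prev
            xm.x[:N] -= model.FST @ sm_prev
        frame = alpha_frames[n]
        if not np.any(np.isnan(frame)):
            pre = x.x.copy()
            x, ks = update(x, ks, frame, H, cfg)
            out.innovations[n] = frame - H.H @ pre
        out.delta_T[n] = x.delta_T
        out.S_est[n] = x.S
        out.P_trace[n] = np.trace(ks.P)
        out.model_only_delta_T[n] = xm.delta_T
    return out
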