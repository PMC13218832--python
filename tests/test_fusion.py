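"""Kalman fusion: closed forms, limits, covariance health, twin behavior."""

import numpy as np
import pytest
import scipy.sparse as sp

from ltu.phantom import TissueProperties, VoxelGrid
from ltu.thermal import PointSets, SimClock, StateSpaceModel, build_state_space
from ltu.thermometry import CalibrationModel, AlphaSeries, build_H
from ltu.fusion import (StateVector, KalmanConfig, KalmanState, predict,
                        update, estimate_R, run_fusion)

GAIN = 0.0354


def scalar_model(f=0.9):
    class PS:
        N, W, M = 1, 0, 1
        aop_in_roi = np.array([0])
    m = StateSpaceModel(F=sp.csr_matrix(np.array([[f]])), point_sets=PS(),
                        dt=1.0, dl_eff=1.0)
    return m, PS()


def rod_twin(n=16, source_at=3, bias=0.0):
    """Small conduction rod with one heat source and one observed point."""
    shape = (n, 3, 3)
    tp = TissueProperties(mu_a=10, mu_s=100, g=0.5, rho=1000, cp=4000,
                          kv=0.5, vs=1500)
    grid = VoxelGrid(shape=shape, dl=0.5e-3,
                     region_labels=np.zeros(shape, dtype=np.int32),
                     props={0: tp})
    top = np.zeros(shape, bool)
    top[source_at, 1, 1] = True
    aop = top.copy()
    ps = PointSets.regular(grid, (0, 0, 0), shape, 1, top_mask=top,
                           aop_mask=aop)
    model = build_state_space(grid, ps, SimClock(dt=0.3), bc="dirichlet")
    cal = CalibrationModel(slope_coeff=GAIN, T0=36.0)
    H = build_H(ps, cal)
    S_true = 5e7  # drives a few-kelvin rise at the source voxel
    x_true = np.concatenate([np.zeros(ps.N), [S_true]])
    return grid, ps, model, H, x_true, S_true, bias


class TestScalarClosedForm:
    def test_predict_update_match_hand_formulas(self):
        model, ps = scalar_model()
        cfg = KalmanConfig(q_T=0.01, r=1e-4, p0_T=1.0)
        cal = CalibrationModel(slope_coeff=GAIN, T0=36.0)
        H = build_H(ps, cal)
        x = StateVector(x=np.array([1.0]), N=1, W=0)
        ks = KalmanState(P=np.array([[1.0]]))
        x, ks = predict(x, model, ks, cfg)
        assert x.x[0] == pytest.approx(0.9)
        assert ks.P[0, 0] == pytest.approx(0.9**2 + 0.01)
        z = 0.05
        P = ks.P[0, 0]
        S = GAIN**2 * P + 1e-4
        K = P * GAIN / S
        x_hand = x.x[0] + K * (z - GAIN * x.x[0])
        P_hand = (1 - K * GAIN) * P
        x, ks = update(x, ks, np.array([z]), H, cfg)
        assert x.x[0] == pytest.approx(x_hand, abs=1e-12)
        assert ks.P[0, 0] == pytest.approx(P_hand, abs=1e-12)

    def test_large_r_trusts_model(self):
        model, ps = scalar_model()
        cal = CalibrationModel(slope_coeff=GAIN, T0=36.0)
        H = build_H(ps, cal)
        cfg = KalmanConfig(q_T=0.01, r=1e12, p0_T=1.0)
        x = StateVector(x=np.array([2.0]), N=1, W=0)
        ks = KalmanState(P=np.array([[1.0]]))
        x2, _ = update(x, ks, np.array([10.0]), H, cfg)
        assert x2.x[0] == pytest.approx(2.0, abs=1e-9)

    def test_small_r_trusts_measurement(self):
        model, ps = scalar_model()
        cal = CalibrationModel(slope_coeff=GAIN, T0=36.0)
        H = build_H(ps, cal)
        cfg = KalmanConfig(q_T=0.01, r=1e-12, p0_T=1.0)
        x = StateVector(x=np.array([2.0]), N=1, W=0)
        ks = KalmanState(P=np.array([[1.0]]))
        z = 0.1
        x2, _ = update(x, ks, np.array([z]), H, cfg)
        assert x2.x[0] == pytest.approx(z / GAIN, rel=1e-6)


class TestPredict:
    def test_zero_state_zero_source_stays_zero(self):
        grid, ps, model, H, x_true, S_true, _ = rod_twin()
        x = StateVector(x=np.zeros(ps.N + ps.W), N=ps.N, W=ps.W)
        ks = KalmanState.initial(KalmanConfig(), ps.N, ps.W)
        x2, _ = predict(x, model, ks, KalmanConfig())
        assert np.all(x2.x == 0)

    def test_zero_q_zero_cov_stays_zero(self):
        grid, ps, model, H, *_ = rod_twin()
        cfg = KalmanConfig(q_T=0.0, q_T_steady=0.0, q_S=0.0, p0_T=0.0,
                           p0_S=0.0)
        x = StateVector(x=np.zeros(ps.N + ps.W), N=ps.N, W=ps.W)
        ks = KalmanState.initial(cfg, ps.N, ps.W)
        _, ks2 = predict(x, model, ks, cfg)
        assert np.all(ks2.P == 0)

    def test_trace_growth_bounded_by_process_noise(self):
        """Contractive conduction: trace(FPFᵀ) ≤ trace(P), growth ≤ tr(Q)."""
        grid, ps, model, H, *_ = rod_twin()
        cfg = KalmanConfig(q_T=1e-3, q_S=0.0, p0_T=1e-2, p0_S=0.0)
        x = StateVector(x=np.zeros(ps.N + ps.W), N=ps.N, W=ps.W)
        ks = KalmanState.initial(cfg, ps.N, ps.W)
        tr0 = np.trace(ks.P)
        _, ks2 = predict(x, model, ks, cfg)
        assert np.trace(ks2.P) <= tr0 + ps.N * 1e-3 + 1e-12

    def test_dimension_mismatch_rejected(self):
        grid, ps, model, *_ = rod_twin()
        x = StateVector(x=np.zeros(3), N=3, W=0)
        ks = KalmanState(P=np.eye(3))
        with pytest.raises(ValueError):
            predict(x, model, ks, KalmanConfig())


class TestEstimateR:
    def test_recovers_known_variance(self):
        rng = np.random.default_rng(3)
        a = 0.01 * rng.standard_normal((100, 4))
        R = estimate_R(a)
        np.testing.assert_allclose(R, 1e-4, rtol=0.5)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            estimate_R(np.zeros((1, 4)))

    def test_identical_frames_floored(self):
        R = estimate_R(np.ones((10, 3)))
        assert np.all(R == 1e-12)

    def test_independent_of_mean_level(self):
        rng = np.random.default_rng(4)
        noise = 0.01 * rng.standard_normal((200, 2))
        R0 = estimate_R(noise)
        R1 = estimate_R(noise + 5.0)
        np.testing.assert_allclose(R0, R1)


class TestCovarianceHealth:
    def test_psd_over_thousand_steps(self):
        """P stays symmetric PSD through a long predict/update run."""
        grid, ps, model, H, x_true, S_true, _ = rod_twin(n=8)
        cfg = KalmanConfig(q_T=1e-3, q_S=1e4, r=1e-4, p0_T=1e-2,
                           p0_S=(0.3 * S_true) ** 2)
        rng = np.random.default_rng(0)
        x = StateVector(x=np.concatenate([np.zeros(ps.N), [0.8 * S_true]]),
                        N=ps.N, W=ps.W)
        xt = x_true.copy()
        ks = KalmanState.initial(cfg, ps.N, ps.W)
        for n in range(1000):
            xt = model.F @ xt
            x, ks = predict(x, model, ks, cfg)
            z = GAIN * xt[ps.aop_in_roi] + 0.005 * rng.standard_normal(ps.M)
            x, ks = update(x, ks, z, H, cfg)
            if n % 100 == 0:
                assert np.allclose(ks.P, ks.P.T)
                w = np.linalg.eigvalsh(ks.P)
                assert w.min() > -1e-8 * np.trace(ks.P)


class TestRunFusion:
    def test_exact_model_noise_free_observations_track_truth(self):
        grid, ps, model, H, x_true, S_true, _ = rod_twin()
        n_steps = 80
        xt = x_true.copy()
        alphas = np.empty((n_steps, ps.M))
        truth = np.empty((n_steps, ps.N))
        for n in range(n_steps):
            xt = model.F @ xt
            truth[n] = xt[:ps.N]
            alphas[n] = GAIN * xt[ps.aop_in_roi]
        cfg = KalmanConfig(q_T=1e-4, q_S=0.0, r=1e-10, p0_T=0.0, p0_S=0.0)
        res = run_fusion(model, H, alphas, cfg,
                         x0=StateVector(x=x_true.copy(), N=ps.N, W=ps.W))
        np.testing.assert_allclose(res.delta_T, truth, atol=1e-9)

    def test_fusion_beats_biased_model(self):
        """10% heat-source bias: fused error at the AOP below model-only."""
        grid, ps, model, H, x_true, S_true, _ = rod_twin()
        n_steps = 120
        rng = np.random.default_rng(7)
        xt = x_true.copy()
        alphas = np.empty((n_steps, ps.M))
        truth = np.empty((n_steps, ps.N))
        for n in range(n_steps):
            xt = model.F @ xt
            truth[n] = xt[:ps.N]
            alphas[n] = GAIN * xt[ps.aop_in_roi] \
                + 0.003 * rng.standard_normal(ps.M)
        cfg = KalmanConfig(q_T=1e-4, q_S=0.0, r=9e-6, p0_T=1e-4,
                           p0_S=(0.3 * S_true) ** 2)
        x0 = StateVector(x=np.concatenate([np.zeros(ps.N), [1.1 * S_true]]),
                         N=ps.N, W=ps.W)
        res = run_fusion(model, H, alphas, cfg, x0=x0)
        aop = ps.aop_in_roi[0]
        fused_err = np.abs(res.delta_T[:, aop] - truth[:, aop]).max()
        model_err = np.abs(res.model_only_delta_T[:, aop]
                           - truth[:, aop]).max()
        assert fused_err < model_err

    def test_unobserved_point_correction(self):
        """Model bias is corrected even where no observation exists."""
        grid, ps, model, H, x_true, S_true, _ = rod_twin()
        n_steps = 150
        rng = np.random.default_rng(11)
        xt = x_true.copy()
        alphas = np.empty((n_steps, ps.M))
        truth = np.empty((n_steps, ps.N))
        for n in range(n_steps):
            xt = model.F @ xt
            truth[n] = xt[:ps.N]
            alphas[n] = GAIN * xt[ps.aop_in_roi] \
                + 0.002 * rng.standard_normal(ps.M)
        cfg = KalmanConfig(q_T=1e-5, q_S=0.0, r=4e-6, p0_T=1e-4,
                           p0_S=(0.3 * S_true) ** 2)
        x0 = StateVector(x=np.concatenate([np.zeros(ps.N), [1.15 * S_true]]),
                         N=ps.N, W=ps.W)
        res = run_fusion(model, H, alphas, cfg, x0=x0)
        # probe a conduction-coupled neighbour two voxels from the source
        probe = int(np.ravel_multi_index((5, 1, 1), ps.lattice_shape))
        fused_err = np.abs(res.delta_T[-50:, probe] - truth[-50:, probe]).max()
        model_err = np.abs(res.model_only_delta_T[-50:, probe]
                           - truth[-50:, probe]).max()
        assert fused_err <= model_err

    def test_innovation_whiteness_on_well_specified_twin(self):
        grid, ps, model, H, x_true, S_true, _ = rod_twin()
        n_steps = 200
        rng = np.random.default_rng(13)
        xt = x_true.copy()
        alphas = np.empty((n_steps, ps.M))
        for n in range(n_steps):
            xt = model.F @ xt
            alphas[n] = GAIN * xt[ps.aop_in_roi] \
                + 0.003 * rng.standard_normal(ps.M)
        cfg = KalmanConfig(q_T=1e-6, q_S=0.0, r=9e-6, p0_T=1e-6,
                           p0_S=(0.2 * S_true) ** 2)
        res = run_fusion(model, H, alphas, cfg,
                         x0=StateVector(x=x_true * 0.9, N=ps.N, W=ps.W))
        inn = res.innovations[50:, 0]  # after transient
        rho = np.corrcoef(inn[:-1], inn[1:])[0, 1]
        assert abs(rho) < 0.2

    def test_low_pass_property(self):
        """Fused non-AOP trajectory is smoother than raw PA thermometry."""
        grid, ps, model, H, x_true, S_true, _ = rod_twin()
        n_steps = 150
        rng = np.random.default_rng(17)
        xt = x_true.copy()
        alphas = np.empty((n_steps, ps.M))
        truth = np.empty((n_steps, ps.N))
        for n in range(n_steps):
            xt = model.F @ xt
            truth[n] = xt[:ps.N]
            alphas[n] = GAIN * xt[ps.aop_in_roi] \
                + 0.005 * rng.standard_normal(ps.M)
        cfg = KalmanConfig(q_T=1e-5, q_S=0.0, r=2.5e-5, p0_T=1e-4, p0_S=0.0)
        res = run_fusion(model, H, alphas, cfg,
                         x0=StateVector(x=x_true.copy(), N=ps.N, W=ps.W))
        probe = int(np.ravel_multi_index((4, 1, 1), ps.lattice_shape))
        pa_resid = alphas[:, 0] / GAIN - truth[:, ps.aop_in_roi[0]]
        fused_resid = res.delta_T[:, probe] - truth[:, probe]
        assert np.var(np.diff(fused_resid)) < np.var(np.diff(pa_resid))

    def test_misaligned_timestamps_warn(self):
        grid, ps, model, H, x_true, *_ = rod_twin(n=6)
        alphas = np.zeros((5, ps.M))
        with pytest.warns(UserWarning, match="nearest"):
            run_fusion(model, H, alphas, KalmanConfig(),
                       obs_times=np.arange(5) * 0.4)

    def test_singular_innovation_rejected_with_diagnostic(self):
        model, ps = scalar_model()
        cal = CalibrationModel(slope_coeff=GAIN, T0=36.0)
        H = build_H(ps, cal)

        class BadCfg(KalmanConfig):
            def r_matrix(self, M):
                return np.diag(np.full(M, -1.0))  # force an indefinite system

        cfg = BadCfg(q_T=0.0, r=1.0, p0_T=0.0)
        x = StateVector(x=np.array([0.0]), N=1, W=0)
        ks = KalmanState(P=np.array([[0.0]]))
        with pytest.raises(np.linalg.LinAlgError, match="cond"):
            update(x, ks, np.array([0.0]), H, cfg)
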