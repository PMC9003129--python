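"""Kalman filter family: exactness, limits, and Monte Carlo convergence."""

import numpy as np
import pytest

from fekf.filters import (
    Ensemble,
    KalmanBelief,
    ekf_step,
    enkf_step,
    kf_predict,
    kf_update,
    run_filter,
)
from fekf.model import LinearModel, StateSpaceModel


def scalar_model(F=1.0, H=1.0, qu=0.01, qw=0.1):
    return LinearModel(F=[[F]], H=[[H]], Qu=[[qu]], Qw=[[qw]])


def textbook_kf(ys, F, H, qu, qw, x0, P0):
    """Independent scalar Kalman recursion, written from the textbook
    equations with plain floats."""
    x, P = x0, P0
    out = [x]
    for y in ys[1:]:
        x_pred = F * x
        P_pred = F * P * F + qu
        S = H * P_pred * H + qw
        K = P_pred * H / S
        x = x_pred + K * (y - H * x_pred)
        P = (1 - K * H) * P_pred
        out.append(x)
    return np.array(out)


class TestKF:
    def test_identity_dynamics_leave_belief_unchanged(self):
        m = LinearModel(F=np.eye(2), H=np.eye(2), Qu=np.zeros((2, 2)), Qw=np.eye(2))
        b = KalmanBelief(x_hat=[1.0, -2.0], P=np.diag([0.3, 0.4]))
        out = kf_predict(b, m)
        np.testing.assert_array_equal(out.x_pred, b.x_hat)
        np.testing.assert_array_equal(out.P_pred, b.P)

    def test_scalar_prediction_arithmetic(self):
        m = scalar_model(F=2.0, qu=0.5)
        out = kf_predict(KalmanBelief(x_hat=[1.0], P=[[1.0]]), m)
        assert out.P_pred[0, 0] == pytest.approx(4.5)

    def test_random_3x3_against_matrix_oracle(self, rng):
        F = rng.standard_normal((3, 3))
        H = rng.standard_normal((2, 3))
        A = rng.standard_normal((3, 3))
        Qu = A @ A.T
        B = rng.standard_normal((2, 2))
        Qw = B @ B.T + np.eye(2)
        m = LinearModel(F=F, H=H, Qu=Qu, Qw=Qw)
        P = np.eye(3) * 0.5
        x = rng.standard_normal(3)
        y = rng.standard_normal(2)
        b = kf_update(kf_predict(KalmanBelief(x_hat=x, P=P), m), m, y)
        # dense-matrix oracle, spelled out
        x_pred = F @ x
        P_pred = F @ P @ F.T + Qu
        K = P_pred @ H.T @ np.linalg.inv(H @ P_pred @ H.T + Qw)
        np.testing.assert_allclose(b.x_hat, x_pred + K @ (y - H @ x_pred), atol=1e-10)
        np.testing.assert_allclose(b.P, (np.eye(3) - K @ H) @ P_pred, atol=1e-10)

    def test_huge_measurement_noise_ignores_observation(self):
        m = scalar_model(qw=1e12)
        b = kf_update(kf_predict(KalmanBelief(x_hat=[2.0], P=[[1.0]]), m), m, [100.0])
        assert b.x_hat[0] == pytest.approx(2.0, abs=1e-6)

    def test_perfect_measurement_snaps_to_observation(self):
        m = scalar_model(qw=0.0)
        b = kf_update(kf_predict(KalmanBelief(x_hat=[2.0], P=[[1.0]]), m), m, [7.0])
        assert b.x_hat[0] == pytest.approx(7.0)

    def test_sequence_matches_textbook_recursion(self, rng):
        ys = rng.standard_normal(50)
        m = scalar_model()
        est = run_filter(ys, m, method="kf")
        oracle = textbook_kf(ys, 1.0, 1.0, 0.01, 0.1, ys[0], 0.1 + 1e-12)
        np.testing.assert_allclose(est[:, 0], oracle, atol=1e-12)

    def test_update_requires_prediction(self):
        m = scalar_model()
        with pytest.raises(ValueError):
            kf_update(KalmanBelief(x_hat=[0.0], P=[[1.0]]), m, [1.0])

    def test_covariance_stays_symmetric_psd(self, rng):
        m = LinearModel(
            F=[[0.9, 0.1], [0.0, 0.95]],
            H=[[1.0, 0.0]],
            Qu=np.diag([0.01, 0.02]),
            Qw=[[0.1]],
        )
        b = KalmanBelief(x_hat=[0.0, 0.0], P=np.eye(2))
        for _ in range(1000):
            b = kf_update(kf_predict(b, m), m, rng.standard_normal(1))
            assert np.allclose(b.P, b.P.T)
            assert np.min(np.linalg.eigvalsh(b.P)) > -1e-12


class TestEKF:
    def test_reduces_to_kf_on_linear_model(self, rng):
        m = scalar_model()
        ys = rng.standard_normal(30)
        kf = run_filter(ys, m, method="kf")
        ekf = run_filter(ys, m.to_state_space(), method="ekf")
        np.testing.assert_allclose(kf, ekf, atol=1e-12)

    def test_requires_jacobians(self):
        ss = StateSpaceModel(
            f=lambda x, n: x, h=lambda x, n: x, Qu=[[0.1]], Qw=[[0.1]], Dx=1, Dy=1
        )
        with pytest.raises(ValueError):
            ekf_step(KalmanBelief(x_hat=[0.0], P=[[1.0]]), ss, [1.0])


class TestEnKF:
    def test_uninformative_observation_leaves_ensemble_unchanged(self, rng):
        ss = StateSpaceModel(
            f=lambda x, n: x,
            h=lambda x, n: np.ones(x.shape[:-1] + (1,)),  # constant observation
            Qu=np.zeros((2, 2)),
            Qw=[[0.0]],
            Dx=2,
            Dy=1,
        )
        members = rng.standard_normal((20, 2))
        out = enkf_step(Ensemble(members=members.copy()), ss, [1.0], rng)
        np.testing.assert_allclose(out.K_hat, 0.0)
        np.testing.assert_allclose(out.members, members)

    def test_perfect_measurement_collapses_members_to_observation(self, rng):
        ss = StateSpaceModel(
            f=lambda x, n: x,
            h=lambda x, n: x,
            Qu=np.zeros((2, 2)),
            Qw=np.zeros((2, 2)),
            Dx=2,
            Dy=2,
        )
        members = rng.standard_normal((30, 2))
        out = enkf_step(Ensemble(members=members), ss, [3.0, -1.0], rng, reg_scale=0.0)
        np.testing.assert_allclose(out.members, np.tile([3.0, -1.0], (30, 1)), atol=1e-8)

    def test_mean_equals_member_average(self, rng):
        ss = scalar_model().to_state_space()
        out = enkf_step(Ensemble(members=rng.standard_normal((50, 1))), ss, [0.5], rng)
        np.testing.assert_allclose(out.mean_x, out.members.mean(axis=0), atol=1e-14)

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            Ensemble(members=np.zeros((1, 2)))

    def test_converges_to_exact_kf(self, rng):
        """Monte Carlo check: scalar linear-Gaussian model, the EnKF
        posterior mean tracks the exact KF within 3 sigma / sqrt(N)."""
        x = 0.0
        ys = []
        for _ in range(100):
            x += rng.normal(0, 0.1)
            ys.append(x + rng.normal(0, np.sqrt(0.1)))
        ys = np.array(ys)
        m = scalar_model()
        kf = run_filter(ys, m, method="kf")
        N = 10_000
        enkf = run_filter(ys, m.to_state_space(), method="enkf", n_ensemble=N, seed=3)
        # steady-state posterior sd of this model is ~0.164
        tol = 3 * 0.165 / np.sqrt(N)
        assert np.mean(np.abs(kf - enkf)) < tol

    def test_gain_from_exact_covariances_matches_kf_gain(self):
        """On a linear model the covariance-form gain built from exact
        (population) covariances equals the innovation-form KF gain."""
        m = LinearModel(
            F=[[0.8, 0.2], [0.0, 0.9]],
            H=[[1.0, 0.5]],
            Qu=np.diag([0.05, 0.02]),
            Qw=[[0.3]],
        )
        P_pred = np.array([[0.4, 0.1], [0.1, 0.6]])
        Pxy = P_pred @ m.H.T
        Pyy = m.H @ P_pred @ m.H.T + m.Qw
        K_cov = Pxy @ np.linalg.inv(Pyy)
        K_kf = P_pred @ m.H.T @ np.linalg.inv(m.H @ P_pred @ m.H.T + m.Qw)
        np.testing.assert_allclose(K_cov, K_kf, atol=1e-14)


class TestRunFilter:
    def test_variance_decreases_on_constant_state(self, rng):
        m = scalar_model(qu=0.0, qw=1.0)
        ys = 1.0 + rng.standard_normal(200)
        _, belief = run_filter(ys, m, method="kf", return_belief=True)
        # accumulate information: posterior variance must shrink well below
        # the single-observation variance
        assert belief.P[0, 0] < 0.02

    def test_seed_reproducibility_is_bitwise(self, rng):
        ys = rng.standard_normal(50)
        ss = scalar_model().to_state_space()
        a = run_filter(ys, ss, method="enkf", n_ensemble=25, seed=11)
        b = run_filter(ys, ss, method="enkf", n_ensemble=25, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            run_filter(np.array([]), scalar_model(), method="kf")

    def test_enkf_beats_ekf_on_strongly_nonlinear_observation(self):
        """Quadratic observation map: over 50 replicates the sampled
        covariance of the EnKF handles the nonlinearity at least as well as
        the EKF's linearization (mean state RMSE)."""
        qu, qw = 0.05, 0.05
        rmse_enkf, rmse_ekf = [], []
        for rep in range(50):
            r = np.random.default_rng(1000 + rep)
            x = 1.0
            xs, ys = [], []
            for _ in range(60):
                x = 0.95 * x + r.normal(0, np.sqrt(qu))
                xs.append(x)
                ys.append(x**2 + r.normal(0, np.sqrt(qw)))
            xs, ys = np.array(xs), np.array(ys)
            ss = StateSpaceModel(
                f=lambda x, n: 0.95 * x,
                h=lambda x, n: x**2,
                Qu=[[qu]],
                Qw=[[qw]],
                Dx=1,
                Dy=1,
                jac_f=lambda x, n: [[0.95]],
                jac_h=lambda x, n: [[2 * float(np.atleast_1d(x)[0])]],
            )
            x0, P0 = [1.0], [[0.1]]
            ekf = run_filter(ys, ss, method="ekf", x0=x0, P0=P0)
            enkf = run_filter(ys, ss, method="enkf", n_ensemble=100, seed=rep, x0=x0, P0=P0)
            rmse_ekf.append(np.sqrt(np.mean((ekf[:, 0] - xs) ** 2)))
            rmse_enkf.append(np.sqrt(np.mean((enkf[:, 0] - xs) ** 2)))
        assert np.mean(rmse_enkf) <= np.mean(rmse_ekf)
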