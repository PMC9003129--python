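"""Kalman filtering: exact KF, extended KF, and the ensemble KF.

The ensemble Kalman filter (EnKF) is a sequential Monte Carlo approximation
of the Kalman update: an ensemble of N state draws is propagated through the
(possibly nonlinear) dynamics, the Kalman gain is approximated from the
ensemble's sample cross- and observation-covariances (1/N normalization),
and each member is nudged toward a stochastically perturbed copy of the
observation.  The state estimate is the ensemble mean.

The extended Kalman filter (EKF) instead linearizes the dynamics and
observation maps with their Jacobians; it serves as the comparison baseline
throughout the package.

Angular state components (the cardiac phase) are handled through the model's
``residual`` hooks so that differences across the 0/2*pi wrap never corrupt
the sample covariances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LinearModel, StateSpaceModel

__all__ = [
    "KalmanBelief",
    "Ensemble",
    "kf_predict",
    "kf_update",
    "ekf_step",
    "enkf_step",
    "init_ensemble",
    "run_filter",
]


@dataclass
class KalmanBelief:
    """Posterior (and, after a predict step, prior) belief of a Kalman-type
    filter: mean, covariance, predicted mean/covariance and last gain."""

    x_hat: np.ndarray
    P: np.ndarray
    x_pred: np.ndarray | None = None
    P_pred: np.ndarray | None = None
    K: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_hat = np.atleast_1d(np.asarray(self.x_hat, dtype=float))
        self.P = np.atleast_2d(np.asarray(self.P, dtype=float))
        if not np.allclose(self.P, self.P.T, atol=1e-8):
            raise ValueError("P must be symmetric")


@dataclass
class Ensemble:
    """State of the ensemble Kalman filter after one analysis step.

    ``members`` are the N analysis (updated) state vectors; ``pred_obs`` the
    predicted observations of the forecast ensemble; ``perturbations`` the
    observation-noise draws used in the stochastic update; ``mean_x`` the
    post-update ensemble mean (the state estimate); the remaining fields are
    the forecast sample statistics that built the approximate gain.
    """

    members: np.ndarray
    pred_obs: np.ndarray | None = None
    perturbations: np.ndarray | None = None
    mean_x: np.ndarray | None = None
    mean_y: np.ndarray | None = None
    Pxy_hat: np.ndarray | None = None
    Pyy_hat: np.ndarray | None = None
    K_hat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.members = np.atleast_2d(np.asarray(self.members, dtype=float))
        if self.members.shape[0] < 2:
            raise ValueError("ensemble needs at least 2 members")
        if self.mean_x is None:
            self.mean_x = self.members.mean(axis=0)

    @property
    def n_members(self) -> int:
        return self.members.shape[0]


# ---------------------------------------------------------------------------
# exact Kalman filter (linear-Gaussian models)
# ---------------------------------------------------------------------------


def kf_predict(belief: KalmanBelief, model: LinearModel) -> KalmanBelief:
    """Time update: propagate mean and covariance through the linear
    dynamics."""
    F = model.F
    if F.shape[1] != belief.x_hat.size:
        raise ValueError("state dimension mismatch between belief and model")
    x_pred = F @ belief.x_hat
    P_pred = F @ belief.P @ F.T + model.Qu
    return KalmanBelief(
        x_hat=belief.x_hat, P=belief.P, x_pred=x_pred, P_pred=P_pred, K=belief.K
    )


def kf_update(belief: KalmanBelief, model: LinearModel, y: np.ndarray) -> KalmanBelief:
    """Measurement update: correct the prediction with the observation.

    The gain is computed both in the innovation form
    ``K = P_pred H' (H P_pred H' + Qw)^-1`` and in the covariance form
    ``K = Pxy Pyy^-1``; the two are asserted equal.
    """
    if belief.x_pred is None or belief.P_pred is None:
        raise ValueError("kf_update requires a prediction (call kf_predict first)")
    H = model.H
    y = np.atleast_1d(np.asarray(y, dtype=float))
    Pxy = belief.P_pred @ H.T
    Pyy = H @ belief.P_pred @ H.T + model.Qw
    cond = np.linalg.cond(Pyy)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"innovation covariance singular (condition number {cond:.3g})"
        )
    K = np.linalg.solve(Pyy.T, Pxy.T).T
    K_cov_form = Pxy @ np.linalg.inv(Pyy)
    assert np.allclose(K, K_cov_form, atol=1e-8 * max(1.0, np.abs(K).max())), (
        "gain identity K = Pxy Pyy^-1 violated"
    )
    x_hat = belief.x_pred + K @ (y - H @ belief.x_pred)
    P = (np.eye(model.Dx) - K @ H) @ belief.P_pred
    P = (P + P.T) / 2  # enforce symmetry against round-off
    return KalmanBelief(
        x_hat=x_hat, P=P, x_pred=belief.x_pred, P_pred=belief.P_pred, K=K
    )


# ---------------------------------------------------------------------------
# extended Kalman filter
# ---------------------------------------------------------------------------


def ekf_step(
    belief: KalmanBelief,
    model: StateSpaceModel,
    y: np.ndarray,
    n: int = 0,
    jacobians: tuple | None = None,
) -> KalmanBelief:
    """One EKF predict+update cycle.

    The nonlinear maps ``f``/``h`` propagate the means; the Jacobians
    (``jacobians`` or the model's ``jac_f``/``jac_h``) propagate the
    covariances.  On a linear model this reduces exactly to
    ``kf_update(kf_predict(...))``.
    """
    jac_f = jacobians[0] if jacobians else model.jac_f
    jac_h = jacobians[1] if jacobians else model.jac_h
    if jac_f is None or jac_h is None:
        raise ValueError("EKF requires Jacobian callables")
    y = np.atleast_1d(np.asarray(y, dtype=float))

    F = np.atleast_2d(np.asarray(jac_f(belief.x_hat, n), dtype=float))
    x_pred = np.atleast_1d(model.f(belief.x_hat, n))
    P_pred = F @ belief.P @ F.T + model.Qu

    H = np.atleast_2d(np.asarray(jac_h(x_pred, n), dtype=float))
    Pyy = H @ P_pred @ H.T + model.Qw
    cond = np.linalg.cond(Pyy)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"innovation covariance singular (condition number {cond:.3g})"
        )
    K = np.linalg.solve(Pyy.T, (P_pred @ H.T).T).T
    innov = model.innovation(y, np.atleast_1d(model.h(x_pred, n)))
    x_hat = x_pred + K @ innov
    P = (np.eye(model.Dx) - K @ H) @ P_pred
    P = (P + P.T) / 2
    return KalmanBelief(x_hat=x_hat, P=P, x_pred=x_pred, P_pred=P_pred, K=K)


# ---------------------------------------------------------------------------
# ensemble Kalman filter
# ---------------------------------------------------------------------------


def _draw_noise(
    rng: np.random.Generator, Q: np.ndarray, size: int, center: bool = False
) -> np.ndarray:
    """Zero-mean Gaussian draws with covariance Q (fast diagonal path).

    With ``center=True`` the draws are recentred to an exactly zero sample
    mean — a standard ensemble-filter variance-reduction device that removes
    the O(1/sqrt(N)) sampling error a nonzero noise mean would inject into
    the ensemble-mean state estimate.
    """
    d = Q.shape[0]
    if np.allclose(Q, np.diag(np.diag(Q))):
        z = rng.standard_normal((size, d))
        if center:
            z -= z.mean(axis=0)
            sd = z.std(axis=0)
            z /= np.where(sd > 0, sd, 1.0)  # exact unit sample variance
        return z * np.sqrt(np.diag(Q))
    L = np.linalg.cholesky(Q + 1e-15 * np.trace(Q) * np.eye(d))
    z = rng.standard_normal((size, d))
    if center:
        z -= z.mean(axis=0)
        sd = z.std(axis=0)
        z /= np.where(sd > 0, sd, 1.0)
    return z @ L.T


def _circular_mean_dev(arr: np.ndarray, residual) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble mean and member deviations, honouring a wrapping residual.

    With ``residual=None`` this is the plain arithmetic mean and deviations.
    Otherwise the mean is computed relative to the first member so that a
    tight ensemble straddling an angular wrap is centred correctly.
    """
    if residual is None:
        mean = arr.mean(axis=0)
        return mean, arr - mean
    ref = arr[0]
    d = residual(arr, ref[None, :])
    d_mean = d.mean(axis=0)
    return ref + d_mean, d - d_mean


def enkf_step(
    ensemble: Ensemble,
    model: StateSpaceModel,
    y: np.ndarray,
    rng: np.random.Generator,
    n: int = 0,
    perturbation_mean: str = "zero",
    reg_scale: float = 1e-8,
) -> Ensemble:
    """One EnKF forecast+analysis cycle.

    (i) each member is propagated through ``f`` with an independent
    state-noise draw; (ii) the forecast sample statistics — means, the
    state-observation cross-covariance and the observation covariance, both
    with 1/N normalization — are formed from predicted observations
    ``h(x_i)``; (iii) the gain is ``Pxy (Pyy + eps I)^-1`` with a tiny
    trace-scaled ridge ``eps`` guarding against near-singular small-ensemble
    covariances; (iv) each member is updated toward the observation plus an
    independent zero-mean Gaussian perturbation with covariance ``Qw``
    (``perturbation_mean="ensemble_obs_mean"`` recentres the perturbations on
    the predicted-observation mean instead); (v) the state estimate is the
    ensemble mean.
    """
    if perturbation_mean not in ("zero", "ensemble_obs_mean"):
        raise ValueError("perturbation_mean must be 'zero' or 'ensemble_obs_mean'")
    members = ensemble.members
    N = members.shape[0]

    # (i) forecast: propagate + state noise
    forecast = np.atleast_2d(model.f(members, n))
    if np.any(np.diag(model.Qu) > 0):
        forecast = forecast + _draw_noise(rng, model.Qu, N, center=True)

    # (ii) predicted observations and 1/N sample covariances
    pred_obs = np.atleast_2d(model.h(forecast, n))
    mean_x, dev_x = _circular_mean_dev(forecast, model.residual if model.Dx == model.Dy else None)
    mean_y, dev_y = _circular_mean_dev(pred_obs, model.residual)
    Pxy = dev_x.T @ dev_y / N
    Pyy = dev_y.T @ dev_y / N

    # (iii) regularized gain.  The observation-error covariance is that of
    # the *noisy* measurement, so Qw is added to the sample covariance of
    # the noise-free predicted observations (the perturbed-observation
    # update below supplies the matching stochastic term).
    S = Pyy + model.Qw
    tr = np.trace(S)
    if tr <= 0 or np.allclose(Pxy, 0):
        K = np.zeros((model.Dx, model.Dy))
    else:
        eps = reg_scale * tr / model.Dy
        K = np.linalg.solve((S + eps * np.eye(model.Dy)).T, Pxy.T).T

    # (iv) stochastic update with perturbed observations
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if np.any(np.diag(model.Qw) > 0):
        v = _draw_noise(rng, model.Qw, N, center=True)
    else:
        v = np.zeros((N, model.Dy))
    if perturbation_mean == "ensemble_obs_mean":
        v = v + mean_y
    innov = model.innovation(y[None, :] + v, pred_obs)
    updated = forecast + innov @ K.T

    bad = ~np.all(np.isfinite(updated), axis=1)
    if np.any(bad):
        raise FloatingPointError(
            f"non-finite ensemble member(s) after update: {np.flatnonzero(bad).tolist()}"
        )

    # (v) state estimate = ensemble mean (circular-aware in the state space
    # when the model wraps its residuals)
    mean_upd, _ = _circular_mean_dev(
        updated, model.residual if model.Dx == model.Dy else None
    )
    return Ensemble(
        members=updated,
        pred_obs=pred_obs,
        perturbations=v,
        mean_x=mean_upd,
        mean_y=mean_y,
        Pxy_hat=Pxy,
        Pyy_hat=Pyy,
        K_hat=K,
    )


def init_ensemble(
    y0: np.ndarray, model: StateSpaceModel, n_ensemble: int, rng: np.random.Generator
) -> Ensemble:
    """Initial ensemble: members drawn Gaussian around the first observation
    with covariance ``Qw`` (requires an observation space that doubles as a
    state initializer, i.e. Dx == Dy)."""
    if n_ensemble < 2:
        raise ValueError("n_ensemble must be >= 2")
    if model.Dx != model.Dy:
        raise ValueError("default initialization requires Dx == Dy; pass x0")
    y0 = np.atleast_1d(np.asarray(y0, dtype=float))
    members = y0[None, :] + _draw_noise(
        rng, model.Qw + 1e-12 * np.eye(model.Dy), n_ensemble
    )
    return Ensemble(members=members)


def run_filter(
    signal: np.ndarray,
    model: StateSpaceModel | LinearModel,
    method: str = "enkf",
    n_ensemble: int = 70,
    seed: int | None = None,
    x0: np.ndarray | None = None,
    P0: np.ndarray | None = None,
    perturbation_mean: str = "zero",
    return_belief: bool = False,
):
    """Filter an observation sequence and return the state-estimate trace.

    Parameters
    ----------
    signal : ndarray, shape (n, Dy) or (n,)
        Observation sequence.
    model : StateSpaceModel or LinearModel
        ``method="kf"`` requires a LinearModel; the nonlinear methods accept
        either (a LinearModel is converted).
    method : {"kf", "ekf", "enkf"}
    n_ensemble : int
        Ensemble size for the EnKF (ignored otherwise).
    seed : int, optional
        Root seed; all per-step noise streams derive from it, so runs are
        replayable.
    x0, P0 : optional initial mean / covariance.  By default the filter is
        initialized at the first observation with covariance ``Qw``.

    Returns
    -------
    ndarray, shape (n, Dx) — per-sample state estimates; the estimate at
    sample 0 is the initialization.
    """
    obs = np.asarray(signal, dtype=float)
    if obs.size == 0:
        raise ValueError("empty observation sequence")
    if obs.ndim == 1:
        obs = obs[:, None]
    n_steps = obs.shape[0]

    linear = model if isinstance(model, LinearModel) else None
    ss = model.to_state_space() if isinstance(model, LinearModel) else model
    if obs.shape[1] != ss.Dy:
        raise ValueError("observation dimension mismatch")

    if x0 is None:
        if ss.Dx != ss.Dy:
            raise ValueError("x0 required when Dx != Dy")
        x0 = obs[0]
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if P0 is None:
        P0 = ss.Qw if ss.Dx == ss.Dy else np.eye(ss.Dx)
    P0 = np.atleast_2d(np.asarray(P0, dtype=float)) + 1e-12 * np.eye(ss.Dx)

    estimates = np.empty((n_steps, ss.Dx))
    estimates[0] = x0
    rng = np.random.default_rng(seed)

    if method == "kf":
        if linear is None:
            raise ValueError("method='kf' requires a LinearModel")
        belief = KalmanBelief(x_hat=x0, P=P0)
        for k in range(1, n_steps):
            belief = kf_update(kf_predict(belief, linear), linear, obs[k])
            estimates[k] = belief.x_hat
        return (estimates, belief) if return_belief else estimates

    if method == "ekf":
        belief = KalmanBelief(x_hat=x0, P=P0)
        for k in range(1, n_steps):
            belief = ekf_step(belief, ss, obs[k], n=k)
            estimates[k] = belief.x_hat
        return (estimates, belief) if return_belief else estimates

    if method == "enkf":
        ens = Ensemble(members=x0[None, :] + _draw_noise(rng, P0, n_ensemble))
        estimates[0] = ens.mean_x
        for k in range(1, n_steps):
            ens = enkf_step(
                ens, ss, obs[k], rng, n=k, perturbation_mean=perturbation_mean
            )
            estimates[k] = ens.mean_x
        return (estimates, ens) if return_belief else estimates

    raise ValueError(f"unknown method {method!r}")
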