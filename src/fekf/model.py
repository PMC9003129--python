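"""Dynamic state-space model of the ECG in polar coordinates.

The heart's electrical cycle is represented as motion around a unit-phase
limit cycle: the state is ``x_k = [theta_k, z_k]`` where ``theta`` is the
cardiac phase in [0, 2*pi) and ``z`` the ECG amplitude.  Each of the five
characteristic waves (P, Q, R, S, T) contributes a Gaussian bump in phase, so
the noise-free waveform is a Gaussian sum

    G(theta) = sum_i alpha_i * exp(-(theta - theta_i)^2 / (2 b_i^2))

and the discrete-time dynamics move ``z`` along the derivative of that sum:

    theta_k = (theta_{k-1} + omega * delta) mod 2*pi
    z_k     = z_{k-1} - sum_i (alpha_i * omega * delta / b_i^2)
                        * dtheta_i * exp(-dtheta_i^2 / (2 b_i^2)) + eta_k

with ``dtheta_i = wrap(theta_k - theta_i)`` into [-pi, pi) so every wave acts
locally around its own centre.  The observation is the phase (derived from
R-peak times by linear time-wrapping of each R-R interval onto [0, 2*pi)) and
the measured amplitude, each with additive noise.

This module also provides the generic nonlinear state-space container used by
the filters, synthetic beat-train generation, and Gaussian-sum parameter
fitting from a phase-averaged beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.optimize import least_squares

from .signals import AnnotatedSignal

__all__ = [
    "WAVE_ORDER",
    "WaveParams",
    "ObservationNoise",
    "ECGModelParams",
    "ECGState",
    "ECGObservation",
    "StateSpaceModel",
    "LinearModel",
    "FitError",
    "mcsharry_params",
    "wrap_phase",
    "wrap_diff",
    "gaussian_sum",
    "ecg_transition",
    "ecg_observe",
    "ecg_jacobian_f",
    "generate_beat_train",
    "phase_average",
    "fit_beat_params",
    "make_ecg_model",
]

WAVE_ORDER = ("P", "Q", "R", "S", "T")

#: Canonical Gaussian wave parameters of the synthetic ECG model
#: (amplitude in signal units, width in rad, centre in rad).
_MCSHARRY_ALPHA = {"P": 1.2, "Q": -5.0, "R": 30.0, "S": -7.5, "T": 0.75}
_MCSHARRY_B = {"P": 0.25, "Q": 0.1, "R": 0.1, "S": 0.1, "T": 0.4}
_MCSHARRY_THETA = {
    "P": -np.pi / 3,
    "Q": -np.pi / 12,
    "R": 0.0,
    "S": np.pi / 12,
    "T": np.pi / 2,
}


def wrap_phase(theta):
    """Wrap angles into [0, 2*pi)."""
    return np.mod(theta, 2 * np.pi)


def wrap_diff(dtheta):
    """Wrap angle differences into [-pi, pi)."""
    return np.mod(np.asarray(dtheta) + np.pi, 2 * np.pi) - np.pi


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian wave: amplitude ``alpha``, width ``b`` (rad), centre
    ``theta`` (rad, stored in [0, 2*pi))."""

    alpha: float
    b: float
    theta: float

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("wave width b must be positive")
        object.__setattr__(self, "theta", float(wrap_phase(self.theta)))


@dataclass(frozen=True)
class ObservationNoise:
    """Measurement-noise variances: phase noise (rad^2) and amplitude noise
    (signal-units^2)."""

    phase_var: float = 0.0
    amplitude_var: float = 0.0

    def __post_init__(self) -> None:
        if self.phase_var < 0 or self.amplitude_var < 0:
            raise ValueError("observation-noise variances must be >= 0")


@dataclass(frozen=True)
class ECGModelParams:
    """Full parameter set of the dynamic ECG model.

    Parameters
    ----------
    waves : mapping {P,Q,R,S,T} -> WaveParams
    omega : float
        Angular velocity of the limit-cycle trajectory (rad/s); one cardiac
        cycle lasts ``2*pi/omega`` seconds.
    delta : float
        Sampling period (s).
    eta_var : float
        Variance of the additive state noise on ``z`` (signal-units^2).  The
        phase equation is noise-free.
    obs_noise : ObservationNoise
    """

    waves: Mapping[str, WaveParams]
    omega: float
    delta: float
    eta_var: float = 0.0
    obs_noise: ObservationNoise = field(default_factory=ObservationNoise)

    def __post_init__(self) -> None:
        if set(self.waves) != set(WAVE_ORDER):
            raise ValueError(f"waves must be keyed exactly {WAVE_ORDER}")
        if not self.omega > 0:
            raise ValueError("omega must be positive")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.eta_var < 0:
            raise ValueError("eta_var must be >= 0")
        object.__setattr__(self, "waves", dict(self.waves))

    # convenience arrays in canonical P,Q,R,S,T order
    @property
    def alphas(self) -> np.ndarray:
        return np.array([self.waves[w].alpha for w in WAVE_ORDER])

    @property
    def bs(self) -> np.ndarray:
        return np.array([self.waves[w].b for w in WAVE_ORDER])

    @property
    def thetas(self) -> np.ndarray:
        return np.array([self.waves[w].theta for w in WAVE_ORDER])

    @property
    def fs(self) -> float:
        return 1.0 / self.delta

    def with_waves(self, alphas, bs, thetas) -> "ECGModelParams":
        waves = {
            w: WaveParams(float(a), float(b), float(t))
            for w, a, b, t in zip(WAVE_ORDER, alphas, bs, thetas)
        }
        return replace(self, waves=waves)


@dataclass(frozen=True)
class ECGState:
    """State vector [theta, z]: cardiac phase and ECG amplitude."""

    theta: float
    z: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.theta) and np.isfinite(self.z)):
            raise ValueError("non-finite state")
        object.__setattr__(self, "theta", float(wrap_phase(self.theta)))


@dataclass(frozen=True)
class ECGObservation:
    """Observation vector [phi, s]: observed phase and observed amplitude."""

    phi: float
    s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", float(wrap_phase(self.phi)))


def mcsharry_params(
    fs: float = 250.0,
    heart_rate: float = 60.0,
    amplitude_scale: float = 1.0,
    width_scale: float = 1.0,
    eta_var: float = 0.0,
    phase_var: float = 0.0,
    amplitude_var: float = 0.0,
) -> ECGModelParams:
    """Canonical wave-parameter defaults, optionally rescaled.

    ``amplitude_scale`` multiplies every alpha (use e.g. ``1/30`` for a unit
    R amplitude, or a negative value for reversed polarity); ``width_scale``
    multiplies every width (fetal beats are narrower than maternal ones).
    """
    waves = {
        w: WaveParams(
            _MCSHARRY_ALPHA[w] * amplitude_scale,
            _MCSHARRY_B[w] * width_scale,
            _MCSHARRY_THETA[w],
        )
        for w in WAVE_ORDER
    }
    return ECGModelParams(
        waves=waves,
        omega=2 * np.pi * heart_rate / 60.0,
        delta=1.0 / fs,
        eta_var=eta_var,
        obs_noise=ObservationNoise(phase_var, amplitude_var),
    )


def gaussian_sum(theta, alphas, bs, thetas) -> np.ndarray:
    """Closed-form Gaussian-sum waveform G(theta); the noise-free limit of
    the discrete dynamics as the sampling period goes to zero."""
    theta = np.asarray(theta, dtype=float)
    d = wrap_diff(theta[..., None] - np.asarray(thetas))
    return np.sum(np.asarray(alphas) * np.exp(-(d**2) / (2 * np.asarray(bs) ** 2)), axis=-1)


def _z_increment(theta_new, params: ECGModelParams, omega=None) -> np.ndarray:
    """Sum of the five Gaussian derivative terms at phase ``theta_new``."""
    om = params.omega if omega is None else np.asarray(omega, dtype=float)
    d = wrap_diff(np.asarray(theta_new, dtype=float)[..., None] - params.thetas)
    b2 = params.bs**2
    terms = params.alphas * d * np.exp(-(d**2) / (2 * b2)) / b2
    return -om * params.delta * np.sum(terms, axis=-1)


def ecg_transition(state: ECGState, params: ECGModelParams, eta: float = 0.0) -> ECGState:
    """One step of the discrete ECG dynamics.

    The phase advances by ``omega * delta`` (noise-free) and wraps; the
    amplitude follows the Gaussian-sum derivative evaluated at the new phase,
    plus the state-noise draw ``eta``.
    """
    if not np.isfinite(eta):
        raise ValueError("eta must be finite")
    theta_new = wrap_phase(state.theta + params.omega * params.delta)
    z_new = state.z + float(_z_increment(theta_new, params)) + eta
    return ECGState(theta=float(theta_new), z=float(z_new))


def ecg_observe(state: ECGState, u: float = 0.0, v: float = 0.0) -> ECGObservation:
    """Observe the state: phase plus noise ``u`` (wrapped), amplitude plus
    noise ``v``."""
    return ECGObservation(phi=wrap_phase(state.theta + u), s=state.z + v)


def ecg_jacobian_f(theta_prev, params: ECGModelParams, omega=None) -> np.ndarray:
    """Jacobian of the transition map w.r.t. [theta, z] at the given previous
    phase; shape (..., 2, 2)."""
    om = params.omega if omega is None else np.asarray(omega, dtype=float)
    theta_new = np.asarray(theta_prev, dtype=float) + om * params.delta
    d = wrap_diff(theta_new[..., None] - params.thetas)
    b2 = params.bs**2
    # d(z_k)/d(theta_{k-1}): derivative of each Gaussian term via the chain
    # rule (d(dtheta)/d(theta_{k-1}) = 1)
    factor = np.asarray(om * params.delta, dtype=float)
    dz_dtheta = -np.sum(
        factor[..., None] * params.alphas / b2 * (1 - d**2 / b2)
        * np.exp(-(d**2) / (2 * b2)),
        axis=-1,
    )
    out = np.zeros(np.shape(dz_dtheta) + (2, 2))
    out[..., 0, 0] = 1.0
    out[..., 1, 0] = dz_dtheta
    out[..., 1, 1] = 1.0
    return out


# ---------------------------------------------------------------------------
# generic state-space containers
# ---------------------------------------------------------------------------


def _check_cov(name: str, Q: np.ndarray, dim: int) -> np.ndarray:
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    if Q.shape != (dim, dim):
        raise ValueError(f"{name} must be {dim}x{dim}, got {Q.shape}")
    if not np.allclose(Q, Q.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.min(np.linalg.eigvalsh(Q)) < -1e-10 * max(1.0, np.trace(Q)):
        raise ValueError(f"{name} must be positive semi-definite")
    return Q


@dataclass
class StateSpaceModel:
    """Generic (possibly nonlinear, possibly time-varying) state-space model.

    ``f(x, n)`` and ``h(x, n)`` must be vectorized over leading axes of ``x``
    (shape ``(..., Dx)``); ``n`` is the time index.  ``jac_f``/``jac_h``
    return Jacobians at a working point and are required only by the EKF.
    ``residual(y, y_pred)`` computes the innovation; the default is plain
    subtraction, the ECG model overrides it to wrap the phase component.
    """

    f: Callable[[np.ndarray, int], np.ndarray]
    h: Callable[[np.ndarray, int], np.ndarray]
    Qu: np.ndarray
    Qw: np.ndarray
    Dx: int
    Dy: int
    jac_f: Callable[[np.ndarray, int], np.ndarray] | None = None
    jac_h: Callable[[np.ndarray, int], np.ndarray] | None = None
    residual: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.Qu = _check_cov("Qu", self.Qu, self.Dx)
        self.Qw = _check_cov("Qw", self.Qw, self.Dy)

    def innovation(self, y: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
        if self.residual is None:
            return y - y_pred
        return self.residual(y, y_pred)


@dataclass
class LinearModel:
    """Linear-Gaussian special case with transition matrix F and observation
    matrix H."""

    F: np.ndarray
    H: np.ndarray
    Qu: np.ndarray
    Qw: np.ndarray

    def __post_init__(self) -> None:
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float))
        if self.F.shape[0] != self.F.shape[1]:
            raise ValueError("F must be square")
        if self.H.shape[1] != self.F.shape[0]:
            raise ValueError("H column count must equal state dimension")
        self.Qu = _check_cov("Qu", self.Qu, self.Dx)
        self.Qw = _check_cov("Qw", self.Qw, self.Dy)

    @property
    def Dx(self) -> int:
        return self.F.shape[0]

    @property
    def Dy(self) -> int:
        return self.H.shape[0]

    def to_state_space(self) -> StateSpaceModel:
        F, H = self.F, self.H
        return StateSpaceModel(
            f=lambda x, n: x @ F.T,
            h=lambda x, n: x @ H.T,
            Qu=self.Qu,
            Qw=self.Qw,
            Dx=self.Dx,
            Dy=self.Dy,
            jac_f=lambda x, n: F,
            jac_h=lambda x, n: H,
        )


def make_ecg_model(
    params: ECGModelParams,
    omega_series: np.ndarray | None = None,
    theta_jitter: float = 1e-6,
) -> StateSpaceModel:
    """Build the filtering state-space model for the dynamic ECG.

    ``omega_series`` gives a per-sample angular velocity (rad/s), e.g.
    ``2*pi / RR`` from the detected beat-to-beat intervals, so the limit
    cycle tracks the record's heart-rate variability; when omitted the
    constant ``params.omega`` is used.  The process-noise covariance is
    ``diag(theta_jitter, eta_var)`` — the tiny phase jitter exists purely for
    covariance conditioning, since the model's phase equation is noise-free.
    """
    om_series = None if omega_series is None else np.asarray(omega_series, dtype=float)

    def omega_at(n: int):
        if om_series is None:
            return params.omega
        return om_series[min(n, om_series.size - 1)]

    def f(x, n):
        x = np.asarray(x, dtype=float)
        om = omega_at(n)
        theta_new = wrap_phase(x[..., 0] + om * params.delta)
        z_new = x[..., 1] + _z_increment(theta_new, params, omega=om)
        return np.stack([theta_new, z_new], axis=-1)

    def h(x, n):
        return np.asarray(x, dtype=float)

    def jac_f(x, n):
        return ecg_jacobian_f(np.asarray(x)[..., 0], params, omega=omega_at(n))

    def jac_h(x, n):
        return np.eye(2)

    def residual(y, y_pred):
        r = np.asarray(y) - np.asarray(y_pred)
        r = np.array(r, dtype=float, copy=True)
        r[..., 0] = wrap_diff(r[..., 0])
        return r

    Qw = np.diag([params.obs_noise.phase_var, params.obs_noise.amplitude_var])
    # keep Qw invertible even in noise-free configurations
    Qw = Qw + 1e-12 * np.eye(2)
    return StateSpaceModel(
        f=f,
        h=h,
        Qu=np.diag([theta_jitter, params.eta_var]),
        Qw=Qw,
        Dx=2,
        Dy=2,
        jac_f=jac_f,
        jac_h=jac_h,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# synthetic beat-train generation
# ---------------------------------------------------------------------------


def generate_beat_train(
    params: ECGModelParams,
    duration: float,
    seed: int | None = None,
    rr_series: np.ndarray | None = None,
    phase0: float = 0.0,
) -> AnnotatedSignal:
    """Generate a synthetic beat train by integrating the discrete dynamics.

    When ``rr_series`` (per-beat R-R intervals in seconds) is given, the
    angular velocity is set to ``2*pi/RR`` for each beat so the train carries
    the prescribed heart-rate variability; the series is cycled if the
    requested duration outruns it.  Ground-truth R-peak indices are the
    samples where the unwrapped phase crosses multiples of ``2*pi`` (the R
    wave is centred at phase zero in the canonical parameterization).

    State noise (variance ``eta_var``) and observation noise are drawn from
    a generator seeded with ``seed``; the output is reproducible for a fixed
    seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / params.delta))
    if n < 1:
        raise ValueError("duration shorter than one sample")
    rng = np.random.default_rng(seed)

    if rr_series is None:
        omega = np.full(n, params.omega)
    else:
        rr = np.asarray(rr_series, dtype=float)
        if rr.size == 0 or np.any(rr <= 0):
            raise ValueError("rr_series entries must be positive")
        # per-sample omega: walk beats until the record is covered
        omega = np.empty(n)
        k = 0
        beat = 0
        phase_in_beat = wrap_phase(phase0)
        while k < n:
            rr_b = rr[beat % rr.size]
            om_b = 2 * np.pi / rr_b
            # samples remaining in this beat given current phase
            steps = int(np.ceil((2 * np.pi - phase_in_beat) / (om_b * params.delta)))
            steps = max(steps, 1)
            stop = min(k + steps, n)
            omega[k:stop] = om_b
            k = stop
            beat += 1
            phase_in_beat = 0.0

    # unwrapped phase: Theta_0 = phase0, Theta_k = phase0 + sum omega*delta
    increments = omega * params.delta
    theta_unwrapped = wrap_phase(phase0) + np.concatenate(
        [[0.0], np.cumsum(increments[:-1])]
    )
    theta = wrap_phase(theta_unwrapped)

    # z trace: cumulative sum of the Gaussian-derivative increments evaluated
    # at each (new) phase, starting on the closed-form waveform
    incr = _z_increment(theta, params, omega=omega)
    incr[0] = 0.0
    eta = (
        rng.normal(0.0, np.sqrt(params.eta_var), size=n)
        if params.eta_var > 0
        else np.zeros(n)
    )
    eta[0] = 0.0
    z0 = float(gaussian_sum(theta[0], params.alphas, params.bs, params.thetas))
    z = z0 + np.cumsum(incr + eta)

    u_var = params.obs_noise.phase_var
    v_var = params.obs_noise.amplitude_var
    s = z + (rng.normal(0.0, np.sqrt(v_var), size=n) if v_var > 0 else 0.0)
    del u_var  # phase observations are produced by the QRS/phase stage

    # R peaks: first sample at or past each multiple of 2*pi (a hair of
    # tolerance absorbs cumsum round-off at exact crossings)
    j_max = int(np.floor((theta_unwrapped[-1] + 1e-6) / (2 * np.pi)))
    targets = 2 * np.pi * np.arange(0, j_max + 1) - 1e-6
    peaks = np.searchsorted(theta_unwrapped, targets, side="left")
    peaks = peaks[peaks < n]
    # drop a sample-0 "peak" unless the train really starts on an R crest
    if wrap_phase(phase0) > 1e-12 and peaks.size and peaks[0] == 0:
        peaks = peaks[1:]
    return AnnotatedSignal(samples=s, fs=params.fs, peaks=peaks.astype(int))


# ---------------------------------------------------------------------------
# Gaussian-sum parameter fitting
# ---------------------------------------------------------------------------


class FitError(RuntimeError):
    """Gaussian-sum fit failed; carries the final residual if available."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


def phase_average(
    samples: np.ndarray, phase: np.ndarray, n_bins: int = 250
) -> tuple[np.ndarray, np.ndarray]:
    """Median waveform as a function of phase.

    Bins the per-sample phases into ``n_bins`` uniform bins over [0, 2*pi)
    and takes the median amplitude in each — the median makes the average
    beat robust to another heart's beats contaminating individual cycles.
    Empty bins are filled by periodic linear interpolation.

    Returns (bin-centre grid, mean beat).
    """
    samples = np.asarray(samples, dtype=float)
    phase = wrap_phase(np.asarray(phase, dtype=float))
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    beat = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = samples[idx == b]
        if sel.size:
            beat[b] = np.median(sel)
    grid = (edges[:-1] + edges[1:]) / 2
    if np.isnan(beat).all():
        raise ValueError("no samples to phase-average")
    if np.isnan(beat).any():
        good = ~np.isnan(beat)
        beat = np.interp(grid, grid[good], beat[good], period=2 * np.pi)
    return grid, beat


def fit_beat_params(
    mean_beat: np.ndarray,
    init: ECGModelParams,
    phase_grid: np.ndarray | None = None,
    max_rel_residual: float = 0.5,
) -> ECGModelParams:
    """Nonlinear least-squares fit of the 15 Gaussian parameters to a
    phase-averaged beat.

    The beat must cover [0, 2*pi) on a uniform phase grid (bin centres by
    default).  The fit is initialized at ``init`` and the recovered wave
    centres must preserve the physiological P<Q<R<S<T ordering in the
    R-centred frame (up to rotation of the circle).

    Raises
    ------
    FitError
        If the optimizer fails, the relative RMS residual exceeds
        ``max_rel_residual``, the beat is degenerate (flat), or the wave
        ordering is violated.
    """
    beat = np.asarray(mean_beat, dtype=float)
    if phase_grid is None:
        m = beat.size
        edges = np.linspace(0, 2 * np.pi, m + 1)
        phase_grid = (edges[:-1] + edges[1:]) / 2
    scale = np.ptp(beat)
    if not np.isfinite(scale) or scale < 1e-12:
        raise FitError("degenerate flat beat: nothing to fit")

    # wave centres are parameterized as offsets from the initialization and
    # confined to windows short of the neighbouring waves: the least-squares
    # landscape is otherwise label-degenerate (two waves can trade places
    # while fitting the waveform equally well)
    th0 = init.thetas
    gaps = np.mod(np.diff(np.concatenate([th0, th0[:1] + 2 * np.pi])), 2 * np.pi)
    prev_gaps = np.roll(gaps, 1)
    windows = 0.45 * np.minimum(gaps, prev_gaps)

    x0 = np.concatenate([init.alphas, init.bs, np.zeros(5)])
    lo = np.concatenate([np.full(5, -np.inf), np.full(5, 1e-3), -windows])
    hi = np.concatenate([np.full(5, np.inf), np.full(5, np.pi), windows])

    def resid(x):
        return gaussian_sum(phase_grid, x[:5], x[5:10], th0 + x[10:15]) - beat

    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
    sol.x[10:15] = th0 + sol.x[10:15]
    rel = float(np.sqrt(np.mean(sol.fun**2)) / scale)
    if not sol.success:
        raise FitError(f"Gaussian-sum fit did not converge: {sol.message}", residual=rel)
    if rel > max_rel_residual:
        raise FitError(
            f"Gaussian-sum fit residual too large (relative RMS {rel:.3f})",
            residual=rel,
        )
    alphas, bs, thetas = sol.x[:5], sol.x[5:10], wrap_phase(sol.x[10:15])
    # centres must keep the P,Q,R,S,T cyclic order (any rotation of the
    # circle is fine): forward gaps around the cycle must close in one turn
    gaps = np.mod(np.diff(np.concatenate([thetas, thetas[:1]])), 2 * np.pi)
    if not np.isclose(gaps.sum(), 2 * np.pi) or np.any(gaps <= 0):
        raise FitError("fitted wave centres violate P<Q<R<S<T ordering", residual=rel)
    return init.with_waves(alphas, bs, thetas)
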