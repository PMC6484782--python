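"""Model predictive control of inducible gene expression.

The controller follows the standard offset-free construction used for
feedback control of gene expression in microfluidics: a 2-state linear
prediction model augmented with a constant disturbance state ``x3``
(``x3(k+1) = x3(k)``) that enters the output, a Kalman filter estimating
the full 3-state vector from the measured fluorescence, and a
receding-horizon optimization of the galactose pulse duration
``d = u * T`` (``u`` in [0, 1]) minimizing the sum of squared predicted
tracking errors over the prediction horizon.

The state equations are::

    x1(k+1) = a11 x1(k) + a12 x2(k) + b1 u(k)
    x2(k+1) = a21 x1(k) + a22 x2(k) + b2 u(k)
    x3(k+1) = x3(k)
    y(k)    = c1 x1(k) + c2 x2(k) + x3(k)

with the input held constant over each sampling period T (zero-order
hold).  Because the decision variable is a single bounded scalar, the
optimizer is a bounded Brent search rather than an SQP solver; an optional
mode optimizes the full input sequence instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["LTIModel", "KalmanState", "ControllerConfig", "IdentificationResult",
           "predict_outputs", "kalman_step", "mpc_step", "identify_model"]

log = logging.getLogger(__name__)


@dataclass
class LTIModel:
    """3-state linear prediction model (2 dynamic states + constant offset)."""

    a11: float
    a12: float
    a21: float
    a22: float
    b1: float
    b2: float
    c1: float
    c2: float
    T: float = 5.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("sampling period T must be > 0")

    @property
    def A(self) -> np.ndarray:
        return np.array([[self.a11, self.a12, 0.0],
                         [self.a21, self.a22, 0.0],
                         [0.0, 0.0, 1.0]])

    @property
    def B(self) -> np.ndarray:
        return np.array([self.b1, self.b2, 0.0])

    @property
    def C(self) -> np.ndarray:
        return np.array([self.c1, self.c2, 1.0])


@dataclass
class KalmanState:
    """Running state estimate and covariance of the Kalman filter."""

    x: np.ndarray = field(default_factory=lambda: np.zeros(3))
    P: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).reshape(3)
        self.P = np.asarray(self.P, dtype=float).reshape(3, 3)
        if not np.allclose(self.P, self.P.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


@dataclass
class ControllerConfig:
    prediction_horizon: float = 120.0  # min (TP); 24 steps at T = 5 min
    T: float = 5.0                     # sampling / pulse period, min
    u_bounds: tuple[float, float] = (0.0, 1.0)
    q: float = 1e-3                    # process-noise scale (incl. x3)
    r: float = 1e-1                    # measurement-noise variance
    optimize_sequence: bool = False    # optimize full input sequence vs one scalar

    def __post_init__(self) -> None:
        steps = self.prediction_horizon / self.T
        if abs(steps - round(steps)) > 1e-9 or steps < 1:
            raise ValueError("prediction_horizon must be a positive multiple of T")

    @property
    def horizon_steps(self) -> int:
        return int(round(self.prediction_horizon / self.T))


def predict_outputs(model: LTIModel, x0, u_seq) -> np.ndarray:
    """Outputs y(k) along the horizon, starting from the state x0.

    Returns one output per horizon step: y(0) is evaluated at ``x0`` and
    the state then advances with each input, i.e. for inputs
    ``[u0, ..., u_{N-1}]`` the result is ``[y(0), ..., y(N-1)]``.
    """
    u_seq = np.asarray(u_seq, dtype=float)
    if np.any((u_seq < 0.0) | (u_seq > 1.0)):
        raise ValueError("inputs must lie in [0, 1]")
    x1, x2, x3 = (float(v) for v in np.asarray(x0, dtype=float).reshape(3))
    m = model
    out = np.empty(len(u_seq))
    for k, u in enumerate(u_seq):
        out[k] = m.c1 * x1 + m.c2 * x2 + x3
        x1, x2 = (m.a11 * x1 + m.a12 * x2 + m.b1 * u,
                  m.a21 * x1 + m.a22 * x2 + m.b2 * u)
    return out


def kalman_step(model: LTIModel, ks: KalmanState, u_prev: float, y_meas: float,
                config: ControllerConfig) -> KalmanState:
    """One predict-then-correct update from the latest fluorescence sample.

    Process noise is ``q * I`` — the disturbance state x3 receives nonzero
    process noise so the filter can move it, which is what removes the
    steady-state tracking error.  The Joseph-form covariance update keeps
    P symmetric positive semidefinite.
    """
    if not math.isfinite(y_meas):
        raise ValueError("measurement must be finite")
    A, B, C = model.A, model.B, model.C
    Q = config.q * np.eye(3)
    x_pred = A @ ks.x + B * u_prev
    P_pred = A @ ks.P @ A.T + Q
    innov = y_meas - float(C @ x_pred)
    S = float(C @ P_pred @ C) + config.r
    K = (P_pred @ C) / S
    x_new = x_pred + K * innov
    IKC = np.eye(3) - np.outer(K, C)
    P_new = IKC @ P_pred @ IKC.T + config.r * np.outer(K, K)
    P_new = 0.5 * (P_new + P_new.T)
    return KalmanState(x=x_new, P=P_new)


def _sse(model: LTIModel, x0, u_seq, yref) -> float:
    err = np.asarray(yref, dtype=float) - predict_outputs(model, x0, u_seq)
    return float(err @ err)


def mpc_step(model: LTIModel, ks: KalmanState, config: ControllerConfig,
             yref_horizon, u_prev: float = 0.0) -> float:
    """Optimal galactose fraction u* in [0, 1] for the next period.

    Minimizes the sum of squared predicted control errors over the
    prediction horizon, holding u constant across it (receding horizon:
    only the first period's input is applied).  The pulse duration is
    ``d = u* * T``.  On optimizer failure, falls back to the previous
    input and logs a warning.
    """
    yref = np.asarray(yref_horizon, dtype=float)
    n = config.horizon_steps
    if len(yref) != n:
        raise ValueError(f"yref horizon must have {n} entries, got {len(yref)}")
    lo, hi = config.u_bounds
    try:
        if config.optimize_sequence:
            res = optimize.minimize(
                lambda us: _sse(model, ks.x, np.clip(us, lo, hi), yref),
                x0=np.full(n, u_prev), method="L-BFGS-B", bounds=[(lo, hi)] * n)
            if not res.success:
                raise RuntimeError(res.message)
            u = float(np.clip(res.x[0], lo, hi))
        else:
            res = optimize.minimize_scalar(
                lambda u: _sse(model, ks.x, np.full(n, u), yref),
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-4})
            u = float(np.clip(res.x, lo, hi))
            # the cost is quadratic in u, but guard the bounds explicitly
            if _sse(model, ks.x, np.full(n, lo), yref) < res.fun:
                u = lo
            if _sse(model, ks.x, np.full(n, hi), yref) < min(
                    res.fun, _sse(model, ks.x, np.full(n, lo), yref)):
                u = hi
    except Exception as exc:  # noqa: BLE001 - contract: fall back, warn
        log.warning("MPC optimization failed (%s); keeping previous input", exc)
        return float(np.clip(u_prev, lo, hi))
    return u


@dataclass
class IdentificationResult:
    model: LTIModel
    rmse: float            # free-run simulation RMSE against the data
    offset: float          # steady output offset (initial estimate for x3)
    low_quality: bool


def identify_model(u, y, T: float = 5.0) -> IdentificationResult:
    """Fit the 2-state + offset model to an input/output step response.

    Least-squares ARX(2) regression of ``y(k+1)`` on ``[y(k), y(k-1),
    u(k), u(k-1), 1]``, mapped to observable canonical form (c = [1, 0]).
    The reported RMSE is from a free-run simulation of the fitted model
    over the same inputs, so it reflects how well the simulated step
    response matches the data (for pure-noise output it approaches the
    output SD and the fit is flagged low quality).
    """
    u = np.asarray(u, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(u) != len(y):
        raise ValueError("u and y must have equal length")
    if len(y) < 8:
        raise ValueError("need at least 8 samples to identify the model")
    if np.ptp(u) == 0:
        raise ValueError("not identifiable: input has no step change")
    X = np.column_stack([y[1:-1], y[:-2], u[1:-1], u[:-2], np.ones(len(y) - 2)])
    coef, *_ = np.linalg.lstsq(X, y[2:], rcond=None)
    a1, a2, b1, b2, gamma = (float(v) for v in coef)
    denom = 1.0 - a1 - a2
    offset = gamma / denom if abs(denom) > 1e-9 else 0.0
    model = LTIModel(a11=a1, a12=1.0, a21=a2, a22=0.0, b1=b1, b2=b2,
                     c1=1.0, c2=0.0, T=T)
    # free-run simulation: y_hat obeys the fitted recursion seeded with data
    y_hat = np.empty_like(y)
    y_hat[0], y_hat[1] = y[0], y[1]
    for k in range(2, len(y)):
        y_hat[k] = (a1 * y_hat[k - 1] + a2 * y_hat[k - 2]
                    + b1 * u[k - 1] + b2 * u[k - 2] + gamma)
        if not math.isfinite(y_hat[k]) or abs(y_hat[k]) > 1e9:
            y_hat[k:] = y_hat[k - 1]  # unstable fit: freeze, will be flagged
            break
    rmse = float(np.sqrt(np.mean((y - y_hat) ** 2)))
    sd = float(np.std(y))
    return IdentificationResult(model=model, rmse=rmse, offset=offset,
                                low_quality=bool(rmse > 0.5 * sd) if sd > 0 else False)
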