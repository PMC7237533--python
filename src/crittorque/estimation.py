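"""Measurement model, forward sensitivities, and weighted least squares.

Torque measurements during a contraction are modeled as

    eta_j = u_rel(t_j) * h_MVIC(t_j) + eps_j,     eps_j ~ N(0, sigma_j^2)

with the discretized standard deviation

    sigma_j = sigma_2s * (2 - u_rel(t_j)) * sqrt(2 / dt_j),

where ``sigma_2s = 0.0378`` is the standard deviation of a 2 s maximal
measurement on the normalized torque scale (the empirical coefficient of
variation of unfatigued elbow-flexor MVIC torque, applied as an absolute
standard deviation), the factor ``(2 - u_rel)`` inflates submaximal
measurements (estimating a submaximal relative load is harder), and the
``sqrt(2/dt)`` factor weights a measurement by its duration relative to the
2 s reference, so that doubling the duration carries the information of two
reference measurements.

Parameters are estimated by maximum likelihood, i.e. weighted nonlinear
least squares over the ODE-constrained measurement responses, with the
Jacobian supplied by forward sensitivity (variational) equations integrated
alongside the states.  The variance-covariance approximation is
``C = (J^T J)^{-1}`` with rows ``J_j = (1/sigma_j) dh/dp (t_j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .model import (
    ATOL,
    RTOL,
    IntegrationError,
    LoadingScheme,
    ModelParameters,
    _pow_base,
)

__all__ = [
    "SIGMA_2S",
    "MeasurementPlan",
    "MeasurementSet",
    "EstimationResult",
    "measurement_sigma",
    "plan_measurements",
    "simulate_measurements",
    "sensitivities",
    "measurement_response",
    "assemble_jacobian",
    "covariance",
    "fit_parameters",
]

#: standard deviation of a 2 s maximal-effort torque measurement
#: (fraction of baseline MVIC torque)
SIGMA_2S = 0.0378


def measurement_sigma(u_rel: float, dt: float, sigma_2s: float = SIGMA_2S) -> float:
    """Discretized standard deviation of a torque measurement.

    ``u_rel`` is the relative load in (0, 1]; ``dt`` the measurement
    duration in seconds.  A 2 s maximal measurement has sigma = sigma_2s
    exactly.
    """
    if dt <= 0:
        raise ValueError(f"measurement duration must be > 0, got {dt}")
    if not 0.0 < u_rel <= 1.0:
        raise ValueError(f"u_rel must be in (0, 1], got {u_rel}")
    return sigma_2s * (2.0 - u_rel) * np.sqrt(2.0 / dt)


@dataclass(frozen=True)
class MeasurementPlan:
    """Where and how torque is measured within a loading scheme.

    Measurements exist only on contraction stages (torque at rest is zero
    and carries no information).  ``durations`` are the per-measurement
    durations dt_j that enter the error model.
    """

    times: np.ndarray
    durations: np.ndarray
    u_rel: np.ndarray
    sigma_2s: float = SIGMA_2S

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.durations, dtype=float)
        u = np.asarray(self.u_rel, dtype=float)
        if not (t.shape == d.shape == u.shape):
            raise ValueError("times, durations and u_rel must have equal length")
        if np.any(d <= 0):
            raise ValueError("measurement durations must be positive")
        if np.any((u <= 0) | (u > 1)):
            raise ValueError("measurements require u_rel in (0, 1]")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "durations", d)
        object.__setattr__(self, "u_rel", u)

    @property
    def sigmas(self) -> np.ndarray:
        return self.sigma_2s * (2.0 - self.u_rel) * np.sqrt(2.0 / self.durations)

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MeasurementSet:
    """Observed torques (fractions of baseline) with their uncertainties."""

    times: np.ndarray
    torques: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.torques, dtype=float)
        s = np.asarray(self.sigmas, dtype=float)
        if not (t.shape == y.shape == s.shape):
            raise ValueError("times, torques and sigmas must have equal length")
        if np.any(s < 0):
            raise ValueError("sigmas must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "torques", y)
        object.__setattr__(self, "sigmas", s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "torque_fraction": self.torques,
             "sigma": self.sigmas}
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MeasurementSet":
        return cls(frame["time_s"].to_numpy(), frame["torque_fraction"].to_numpy(),
                   frame["sigma"].to_numpy())


@dataclass
class EstimationResult:
    """Fitted parameters with their covariance approximation."""

    p_hat: ModelParameters
    covariance: np.ndarray
    sigma_p: np.ndarray
    objective: float
    condition: float
    n_iterations: int = 0
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "p_hat": list(self.p_hat.as_array()),
            "sigma_p": list(self.sigma_p),
            "covariance": [list(row) for row in self.covariance],
            "objective": self.objective,
            "condition": self.condition,
            "converged": self.converged,
        }


def plan_measurements(scheme: LoadingScheme, n_per_stage: int = 100,
                      sigma_2s: float = SIGMA_2S) -> MeasurementPlan:
    """Uniform midpoint measurement grid on every contraction stage.

    Each contraction stage of duration T contributes ``n_per_stage``
    measurements at midpoints of equal subintervals, each of duration
    ``T / n_per_stage``, approximating a continuous force-transducer record.
    """
    times, durations, u_rel = [], [], []
    t0 = 0.0
    for stage in scheme.stages:
        if not stage.is_rest:
            if stage.mode != "relative":
                raise ValueError("measurement planning requires relative-mode "
                                 "contraction stages")
            dt = stage.duration / n_per_stage
            mids = t0 + (np.arange(n_per_stage) + 0.5) * dt
            times.append(mids)
            durations.append(np.full(n_per_stage, dt))
            u_rel.append(np.full(n_per_stage, stage.level))
        t0 += stage.duration
    if not times:
        raise ValueError("scheme has no contraction stages to measure")
    return MeasurementPlan(np.concatenate(times), np.concatenate(durations),
                           np.concatenate(u_rel), sigma_2s=sigma_2s)


# ---------------------------------------------------------------------------
# sensitivity (variational) equations
#
# y = (x_slow, x_fast, s11..s15, s21..s25): 2 states + the 2x5 sensitivity
# matrix flattened row-major.  ds/dt = (df/dx) s + df/dp, s(0) = 0.


def _jacobians(xs, xf, p: ModelParameters, u_rel, absolute_u):
    """df/dx (2x2) and df/dp (2x5) at one point, with the relative-load
    substitution differentiated through when ``absolute_u`` is None."""
    if absolute_u is None:
        u = u_rel * xs * xf
        du_dxs = u_rel * xf
        du_dxf = u_rel * xs
    else:
        u = absolute_u
        du_dxs = 0.0
        du_dxf = 0.0
    a = 1.0 - u
    A = _pow_base(a, p.p4)
    # d/du (1-u)^p4 needs a^(p4-1); at a = 0 the limit is 0 for p4 > 1,
    # 1 for p4 = 1 and divergent below — clamp the base away from zero
    if p.p4 == 0.0:
        dA_du = 0.0
    elif p.p4 == 1.0:
        dA_du = -1.0
    else:
        dA_du = -p.p4 * _pow_base(max(a, 1e-12), p.p4 - 1.0)
    df2_du = p.p3 * dA_du * (1.0 - xf) - p.p5
    jx = np.array(
        [
            [-p.p1 - p.p2 * du_dxs, -p.p2 * du_dxf],
            [df2_du * du_dxs, -p.p3 * A + df2_du * du_dxf],
        ]
    )
    if a > 0.0:
        dA_dp4 = A * np.log(a)
    else:
        dA_dp4 = 0.0
    jp = np.array(
        [
            [1.0 - xs, -u, 0.0, 0.0, 0.0],
            [0.0, 0.0, A * (1.0 - xf), p.p3 * dA_dp4 * (1.0 - xf), -u],
        ]
    )
    return jx, jp


def _rhs_aug(y, p: ModelParameters, u_rel, absolute_u):
    xs, xf = y[0], y[1]
    if absolute_u is None:
        u = u_rel * xs * xf
    else:
        u = absolute_u
    A = _pow_base(1.0 - u, p.p4)
    f = np.array([p.p1 * (1.0 - xs) - p.p2 * u,
                  p.p3 * A * (1.0 - xf) - p.p5 * u])
    jx, jp = _jacobians(xs, xf, p, u_rel, absolute_u)
    s = y[2:].reshape(2, 5)
    ds = jx @ s + jp
    return np.concatenate([f, ds.ravel()])


def sensitivities(params: ModelParameters, scheme: LoadingScheme,
                  times: np.ndarray, *, rtol: float = RTOL,
                  atol: float = ATOL):
    """States and state sensitivities dx/dp at the requested times.

    Integrates the variational ODE stage by stage with continuity of both
    states and sensitivities across boundaries; ``times`` must be sorted and
    lie within the scheme.  Returns ``(x, s)`` with shapes (n, 2) and
    (n, 2, 5).
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("measurement times must be sorted")
    total = scheme.total_duration
    if times.size and (times[0] < -1e-9 or times[-1] > total + 1e-9):
        raise ValueError("measurement times outside the scheme")
    y = np.concatenate([[scheme.x0.x_slow, scheme.x0.x_fast], np.zeros(10)])
    out_x = np.empty((len(times), 2))
    out_s = np.empty((len(times), 2, 5))
    t0 = 0.0
    k = 0
    for i, stage in enumerate(scheme.stages):
        t1 = t0 + stage.duration
        # times inside this stage (boundary points belong to the earlier stage)
        sel = []
        while k + len(sel) < len(times) and times[k + len(sel)] <= t1 + 1e-9:
            sel.append(times[k + len(sel)] - t0)
        if stage.mode == "relative":
            u_rel, absolute_u = stage.level, None
        else:
            u_rel, absolute_u = None, stage.level
        t_eval = np.clip(np.asarray(sel), 0.0, stage.duration) if sel else None
        sol = solve_ivp(
            lambda t, yy: _rhs_aug(yy, params, u_rel, absolute_u),
            (0.0, stage.duration),
            y,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            t_eval=None,
            dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(i, sol.message)
        if sel:
            vals = sol.sol(t_eval)
            for j in range(len(sel)):
                out_x[k + j] = vals[:2, j]
                out_s[k + j] = vals[2:, j].reshape(2, 5)
            k += len(sel)
        y = sol.y[:, -1].copy()
        t0 = t1
    if k != len(times):
        raise ValueError("some measurement times fell outside the scheme")
    return out_x, out_s


def measurement_response(params: ModelParameters, scheme: LoadingScheme,
                         plan: MeasurementPlan, *, with_jacobian: bool = False,
                         rtol: float = RTOL, atol: float = ATOL):
    """Model torque h = u_rel * h_MVIC at the plan times, optionally with
    the unweighted Jacobian dh/dp (n x 5)."""
    x, s = sensitivities(params, scheme, plan.times, rtol=rtol, atol=atol)
    h = plan.u_rel * x[:, 0] * x[:, 1]
    if not with_jacobian:
        return h
    # dh/dp = u_rel (x_fast dxs/dp + x_slow dxf/dp)
    dh = plan.u_rel[:, None] * (
        x[:, 1, None] * s[:, 0, :] + x[:, 0, None] * s[:, 1, :]
    )
    return h, dh


def simulate_measurements(params: ModelParameters, scheme: LoadingScheme,
                          plan: MeasurementPlan, seed=None,
                          rng: np.random.Generator | None = None) -> MeasurementSet:
    """Draw a synthetic noisy measurement set from the error model.

    Reproducible for a fixed seed; with ``sigma_2s = 0`` in the plan the
    sigma would be zero, which the error model forbids — pass noiseless
    comparisons through :func:`measurement_response` instead.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    h = measurement_response(params, scheme, plan)
    sig = plan.sigmas
    eta = h + rng.normal(0.0, 1.0, size=len(plan)) * sig
    return MeasurementSet(plan.times.copy(), eta, sig)


def assemble_jacobian(params: ModelParameters, scheme: LoadingScheme,
                      plan: MeasurementPlan, *, rtol: float = RTOL,
                      atol: float = ATOL) -> np.ndarray:
    """Weighted Jacobian with rows (1/sigma_j) dh/dp(t_j)."""
    _, dh = measurement_response(params, scheme, plan, with_jacobian=True,
                                 rtol=rtol, atol=atol)
    sig = plan.sigmas
    if np.any(sig == 0):
        raise ValueError("plan contains zero-sigma measurements")
    return dh / sig[:, None]


def covariance(J: np.ndarray):
    """Variance-covariance approximation C = (J^T J)^{-1} and the implied
    per-parameter standard deviations.

    Columns are equilibrated by their norms before inversion (parameters
    span several orders of magnitude, so the raw Gram matrix is artificially
    ill conditioned); the result is the exact inverse, just computed
    stably.
    """
    J = np.asarray(J, dtype=float)
    norms = np.linalg.norm(J, axis=0)
    if np.any(norms == 0):
        dead = [i for i, v in enumerate(norms) if v == 0]
        raise np.linalg.LinAlgError(
            f"J^T J is rank deficient: zero sensitivity for parameter "
            f"index(es) {dead}"
        )
    Jn = J / norms[None, :]
    gram = Jn.T @ Jn
    cond = float(np.linalg.cond(gram))
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"J^T J is numerically rank deficient (equilibrated condition "
            f"number {cond:.3g})"
        )
    Cn = np.linalg.inv(gram)
    C = Cn / np.outer(norms, norms)
    C = 0.5 * (C + C.T)
    return C, np.sqrt(np.diag(C))


def fit_parameters(data: MeasurementSet, scheme: LoadingScheme,
                   plan: MeasurementPlan, p_init: ModelParameters,
                   bounds=None, *, rtol: float = RTOL, atol: float = ATOL,
                   gtol: float = 1e-8, xtol: float = 1e-10,
                   ftol: float = 1e-10, max_nfev: int = 300) -> EstimationResult:
    """Maximum-likelihood fit: minimize 1/2 sum ((h(t_j) - eta_j)/sigma_j)^2
    subject to the model dynamics and p >= 0.

    Trust-region-reflective least squares with the analytic sensitivity
    Jacobian; nonnegativity is enforced through solver bounds, never by
    clipping.  The covariance is evaluated at the optimum via Eq. C =
    (J^T J)^{-1}.
    """
    if len(data.times) != len(plan):
        raise ValueError("data and plan lengths differ")
    if not np.allclose(data.times, plan.times):
        raise ValueError("data times do not match the plan")
    sig = plan.sigmas
    if np.any(sig == 0):
        raise ValueError("plan contains zero-sigma measurements")
    lower = np.zeros(5)
    upper = np.full(5, np.inf)
    if bounds is not None:
        lower = np.maximum(lower, np.asarray(bounds[0], dtype=float))
        upper = np.asarray(bounds[1], dtype=float)

    def residuals(pvec):
        p = ModelParameters.from_array(pvec)
        h = measurement_response(p, scheme, plan, rtol=rtol, atol=atol)
        return (h - data.torques) / sig

    def jac(pvec):
        p = ModelParameters.from_array(pvec)
        _, dh = measurement_response(p, scheme, plan, with_jacobian=True,
                                     rtol=rtol, atol=atol)
        return dh / sig[:, None]

    # characteristic parameter scales keep the trust region well conditioned
    # (rates ~1e-3 next to an O(1) exponent)
    x_scale = np.maximum(np.abs(p_init.as_array()), 1e-4)
    res = least_squares(
        residuals,
        p_init.as_array(),
        jac=jac,
        bounds=(lower, upper),
        method="trf",
        x_scale=x_scale,
        gtol=gtol,
        xtol=xtol,
        ftol=ftol,
        max_nfev=max_nfev,
    )
    if res.status <= 0:
        raise RuntimeError(f"parameter fit did not converge: {res.message}")
    p_hat = ModelParameters.from_array(res.x)
    J = jac(res.x)
    C, sigma_p = covariance(J)
    norms = np.linalg.norm(J, axis=0)
    Jn = J / norms[None, :]
    return EstimationResult(
        p_hat=p_hat,
        covariance=C,
        sigma_p=sigma_p,
        objective=float(res.cost),
        condition=float(np.linalg.cond(Jn.T @ Jn)),
        n_iterations=int(res.nfev),
        converged=bool(res.success),
    )
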