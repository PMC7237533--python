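"""Steady-state analysis: the highest sustainable torque output.

Critical torque (CT) is the largest load ``u`` (fraction of baseline MVIC
torque) for which the fatigue dynamics admit a feasible steady state, i.e.
MVIC torque capacity no longer changes over a contraction-rest cycle and
still covers the demanded load.  For a duty cycle ``d = t_c / (t_c + t_r)``
the cycle-averaged steady-state conditions are

    0 = d * (p1 (1 - x_slow) - p2 u) + (1 - d) * p1 (1 - x_slow)
    0 = d * (p3 (1 - u)^p4 (1 - x_fast) - p5 u) + (1 - d) * p3 (1 - x_fast)

which reduce to the sustained-contraction conditions at d = 1.  CT is then
the solution of

    max u   s.t.  steady state holds,  u <= x_slow x_fast,  all in [0, 1].

Two solvers are provided: a 1-D bisection on the closed-form steady states
(fast, used as the default and as an independent oracle) and a multistart
SLSQP solve of the 3-variable nonlinear program over (u, x_slow, x_fast).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model import ModelParameters, _pow_base

__all__ = [
    "CTSolution",
    "DutyCycleCurve",
    "steady_state_states",
    "steady_state_residual",
    "solve_ct",
    "solve_ct_bisection",
    "solve_ct_nlp_multistart",
    "duty_cycle_sweep",
]

logger = logging.getLogger(__name__)

_FEAS_TOL = 1e-9


@dataclass(frozen=True)
class CTSolution:
    """Critical torque and the accompanying steady state for one duty cycle."""

    u_star: float
    x_slow_star: float
    x_fast_star: float
    duty: float
    method: str
    constraint_active: bool

    @property
    def percent_of_baseline(self) -> float:
        return 100.0 * self.u_star


@dataclass(frozen=True)
class DutyCycleCurve:
    """CT as a function of the duty cycle t_c / (t_c + t_r)."""

    duty: np.ndarray
    ct: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"duty": self.duty, "ct_fraction": self.ct})


def duty_from_times(t_c: float, t_r: float) -> float:
    if t_c < 0 or t_r < 0 or t_c + t_r <= 0:
        raise ValueError("contraction and rest durations must be nonnegative "
                         "with a positive cycle length")
    return t_c / (t_c + t_r)


def steady_state_states(u: float, params: ModelParameters, duty: float):
    """Closed-form steady states implied by load ``u`` at the given duty.

    x_slow = 1 - duty p2 u / p1
    x_fast = 1 - duty p5 u / (p3 (duty (1-u)^p4 + 1 - duty))

    These solve the weighted steady-state conditions exactly (each is linear
    in its state).  Raises for vanishing recovery rates with u > 0, where no
    steady state exists.
    """
    p = params
    if u == 0.0:
        return 1.0, 1.0
    if p.p1 == 0.0 or p.p3 == 0.0:
        raise ZeroDivisionError(
            "steady state undefined: recovery rate p1 or p3 is zero with u > 0"
        )
    x_slow = 1.0 - duty * p.p2 * u / p.p1
    k_fast = p.p3 * (duty * _pow_base(1.0 - u, p.p4) + (1.0 - duty))
    if k_fast == 0.0:
        raise ZeroDivisionError(
            "steady state undefined: fast recovery vanishes at this load"
        )
    x_fast = 1.0 - duty * p.p5 * u / k_fast
    return x_slow, x_fast


def steady_state_residual(u: float, params: ModelParameters, duty: float,
                          x_slow: float | None = None,
                          x_fast: float | None = None):
    """Duty-weighted steady-state residuals and the implied states.

    If states are not supplied, the closed-form states are used and the
    residuals vanish identically; explicit states keep the NLP mode honest.
    Returns ``((r_slow, r_fast), (x_slow, x_fast))``.
    """
    if x_slow is None or x_fast is None:
        x_slow, x_fast = steady_state_states(u, params, duty)
    p = params
    r_slow = duty * (p.p1 * (1.0 - x_slow) - p.p2 * u) + (1.0 - duty) * p.p1 * (
        1.0 - x_slow
    )
    r_fast = duty * (
        p.p3 * _pow_base(1.0 - u, p.p4) * (1.0 - x_fast) - p.p5 * u
    ) + (1.0 - duty) * p.p3 * (1.0 - x_fast)
    return (r_slow, r_fast), (x_slow, x_fast)


def _feasible(u: float, params: ModelParameters, duty: float,
              tol: float = _FEAS_TOL) -> bool:
    try:
        xs, xf = steady_state_states(u, params, duty)
    except ZeroDivisionError:
        return False
    if not (-tol <= xs <= 1 + tol and -tol <= xf <= 1 + tol):
        return False
    return u <= xs * xf + tol


def solve_ct_bisection(params: ModelParameters, duty: float,
                       n_scan: int = 10_000, width: float = 1e-10) -> CTSolution:
    """1-D oracle: scan u in [0, 1] for the largest feasible point, then
    bisect the bracketing interval down to ``width``."""
    if duty == 0.0:
        return CTSolution(1.0, 1.0, 1.0, duty, "bisection", False)
    p = params
    if p.p1 == 0.0 or p.p3 == 0.0:
        # no steady state exists under load; only u = 0 is sustainable
        return CTSolution(0.0, 1.0, 1.0, duty, "bisection", True)
    grid = np.linspace(0.0, 1.0, n_scan)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.where(grid < 1.0, 1.0 - grid, 0.0)
        A = np.where(base > 0, base ** p.p4, 1.0 if p.p4 == 0.0 else 0.0)
        xs = 1.0 - duty * p.p2 * grid / p.p1
        k_fast = p.p3 * (duty * A + (1.0 - duty))
        xf = np.where(k_fast > 0, 1.0 - duty * p.p5 * grid / np.where(k_fast > 0, k_fast, 1.0), -np.inf)
    tol = _FEAS_TOL
    feas = (
        (xs >= -tol) & (xs <= 1 + tol) & (xf >= -tol) & (xf <= 1 + tol)
        & (grid <= xs * xf + tol) & np.isfinite(xf)
    )
    if not feas[0]:
        raise RuntimeError("u = 0 infeasible; parameters are invalid")
    idx = int(np.max(np.flatnonzero(feas)))
    lo = float(grid[idx])
    if idx == len(grid) - 1:
        hi = 1.0
    else:
        hi = float(grid[idx + 1])
        while hi - lo > width:
            mid = 0.5 * (lo + hi)
            if _feasible(mid, params, duty):
                lo = mid
            else:
                hi = mid
    u_star = lo
    xs, xf = steady_state_states(u_star, params, duty)
    active = abs(u_star - xs * xf) <= 1e-6 or u_star >= 1.0 - 1e-9
    return CTSolution(u_star, float(np.clip(xs, 0, 1)), float(np.clip(xf, 0, 1)),
                      duty, "bisection", active)


def solve_ct_nlp_multistart(params: ModelParameters, duty: float,
                            grid_points_per_dim: int = 20,
                            ftol: float = 1e-12) -> CTSolution:
    """Multistart SLSQP on the 3-variable nonlinear program.

    The unit cube over (u, x_slow, x_fast) is sampled uniformly with
    ``grid_points_per_dim`` points per dimension; a local SLSQP solve is run
    from every grid point and the feasible solution with the highest load is
    kept (ties broken by grid order).
    """
    if grid_points_per_dim < 2:
        raise ValueError("need at least 2 grid points per dimension")
    if duty == 0.0:
        return CTSolution(1.0, 1.0, 1.0, duty, "nlp_multistart", False)

    def eq_constraints(z):
        (r1, r2), _ = steady_state_residual(z[0], params, duty,
                                            x_slow=z[1], x_fast=z[2])
        return np.array([r1, r2])

    def ineq_constraint(z):
        return z[1] * z[2] - z[0]

    constraints = [
        {"type": "eq", "fun": eq_constraints},
        {"type": "ineq", "fun": ineq_constraint},
    ]
    bounds = [(0.0, 1.0)] * 3
    axis = np.linspace(0.0, 1.0, grid_points_per_dim)
    best = None
    n_failed = 0
    for u0 in axis:
        for xs0 in axis:
            for xf0 in axis:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = minimize(
                        lambda z: -z[0],
                        np.array([u0, xs0, xf0]),
                        jac=lambda z: np.array([-1.0, 0.0, 0.0]),
                        method="SLSQP",
                        bounds=bounds,
                        constraints=constraints,
                        options={"ftol": ftol, "maxiter": 200},
                    )
                if not res.success:
                    n_failed += 1
                    continue
                z = res.x
                if np.max(np.abs(eq_constraints(z))) > 1e-8:
                    continue
                if ineq_constraint(z) < -1e-8:
                    continue
                if best is None or z[0] > best[0]:
                    best = z.copy()
    if best is None:
        raise RuntimeError("all multistart SLSQP solves failed")
    if n_failed:
        logger.warning("%d of %d multistart solves failed and were skipped",
                       n_failed, grid_points_per_dim ** 3)
    u_star, xs, xf = (float(v) for v in best)
    active = abs(u_star - xs * xf) <= 1e-6 or u_star >= 1.0 - 1e-9
    return CTSolution(u_star, xs, xf, duty, "nlp_multistart", active)


def solve_ct(params: ModelParameters, duty: float | None = None, *,
             t_c: float | None = None, t_r: float | None = None,
             method: str = "bisection",
             grid_points_per_dim: int = 20) -> CTSolution:
    """Critical torque for a duty cycle (or an explicit t_c / t_r pair).

    ``duty = 1`` is the sustained contraction; ``duty = 0`` returns u = 1 by
    convention (no loaded fraction).  ``method`` is ``"bisection"`` (default,
    closed-form 1-D search) or ``"nlp"`` (multistart SLSQP).
    """
    if duty is None:
        if t_c is None or t_r is None:
            raise ValueError("provide either duty or both t_c and t_r")
        duty = duty_from_times(t_c, t_r)
    elif t_c is not None or t_r is not None:
        raise ValueError("provide either duty or t_c/t_r, not both")
    if not 0.0 <= duty <= 1.0:
        raise ValueError(f"duty cycle must be in [0, 1], got {duty}")
    if method == "bisection":
        return solve_ct_bisection(params, duty)
    if method == "nlp":
        return solve_ct_nlp_multistart(params, duty,
                                       grid_points_per_dim=grid_points_per_dim)
    raise ValueError(f"unknown method {method!r}; use 'bisection' or 'nlp'")


def duty_cycle_sweep(params: ModelParameters, n: int = 100,
                     method: str = "bisection") -> DutyCycleCurve:
    """CT at ``n`` duty cycles distributed uniformly in [0, 1]."""
    if n < 2:
        raise ValueError("need at least 2 duty values")
    duties = np.linspace(0.0, 1.0, n)
    cts = np.array([solve_ct(params, float(d), method=method).u_star
                    for d in duties])
    return DutyCycleCurve(duty=duties, ct=cts)
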