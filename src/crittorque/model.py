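"""Phenomenological ODE model of MVIC torque under isometric loading.

The model tracks two dimensionless capacity states, ``x_slow`` and
``x_fast``, whose product is the current maximum voluntary isometric
contraction (MVIC) torque capacity ``h_MVIC``, normalized to the unfatigued
baseline.  An external load ``u_abs`` (also a fraction of baseline) drives
fatigue; recovery pulls each state back toward 1:

    dx_slow/dt = p1 (1 - x_slow) - p2 u_abs
    dx_fast/dt = p3 (1 - u_abs)^p4 (1 - x_fast) - p5 u_abs
    h_MVIC     = x_slow * x_fast

The five nonnegative parameters p1..p5 describe fatigue and recovery rates
(p4 is an exponent coupling load level to fast recovery).  Loading schemes
are ordered sequences of constant-load stages, either *relative* (the load
is a fraction ``u_rel`` of the current capacity, so maximal efforts are
``u_rel = 1``) or *absolute* (a fixed torque target).  Relative stages are
simulated via the substitution ``u_abs = u_rel * h_MVIC``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ModelParameters",
    "MuscleState",
    "Stage",
    "LoadingScheme",
    "Trajectory",
    "rhs",
    "simulate",
    "detect_plateau_sustained",
    "detect_plateau_intermittent",
    "detect_task_failure",
    "build_scenario",
    "concatenate_schemes",
    "tut",
    "SCENARIO_NAMES",
]

#: default integration tolerances
RTOL = 1e-8
ATOL = 1e-10

#: default simulation horizon for open-ended scenarios (60 min)
DEFAULT_HORIZON = 3600.0

_STATE_TOL = 1e-6


class InfeasibleLoadError(RuntimeError):
    """An absolute-mode stage demands more torque than the muscle can produce."""

    def __init__(self, stage_index: int, message: str):
        super().__init__(message)
        self.stage_index = stage_index


class IntegrationError(RuntimeError):
    """The ODE integrator failed; carries the offending stage index."""

    def __init__(self, stage_index: int, message: str):
        super().__init__(f"integration failed on stage {stage_index}: {message}")
        self.stage_index = stage_index


@dataclass(frozen=True)
class ModelParameters:
    """The five dimensionless fatigue/recovery parameters.

    All components live in [0, inf).  p1/p3 are slow/fast recovery rates
    (per second), p2/p5 the corresponding fatigue rates, and p4 the exponent
    that suppresses fast recovery under load.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float

    def __post_init__(self):
        for name, value in self.as_dict().items():
            if not math.isfinite(value):
                raise ValueError(f"parameter {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"parameter {name} must be nonnegative, got {value}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4, self.p5], dtype=float)

    def as_dict(self) -> dict:
        return {
            "p1": self.p1,
            "p2": self.p2,
            "p3": self.p3,
            "p4": self.p4,
            "p5": self.p5,
        }

    @classmethod
    def from_array(cls, values) -> "ModelParameters":
        values = np.asarray(values, dtype=float).ravel()
        if values.size != 5:
            raise ValueError(f"expected 5 parameters, got {values.size}")
        return cls(*values)


@dataclass(frozen=True)
class MuscleState:
    """Instantaneous capacity state; ``h_mvic`` is the product of the two."""

    x_slow: float
    x_fast: float

    def __post_init__(self):
        for name in ("x_slow", "x_fast"):
            v = getattr(self, name)
            if not (-_STATE_TOL <= v <= 1 + _STATE_TOL):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def h_mvic(self) -> float:
        return self.x_slow * self.x_fast

    def as_array(self) -> np.ndarray:
        return np.array([self.x_slow, self.x_fast], dtype=float)


@dataclass(frozen=True)
class Stage:
    """One constant-load interval of a loading scheme.

    ``mode`` is ``"relative"`` (level is u_rel, a fraction of current
    capacity) or ``"absolute"`` (level is u_abs, a fraction of baseline).
    A level of exactly 0 is a rest stage in either mode.
    """

    duration: float
    mode: str = "relative"
    level: float = 0.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError(f"stage duration must be > 0, got {self.duration}")
        if self.mode not in ("relative", "absolute"):
            raise ValueError(f"unknown stage mode {self.mode!r}")
        if not 0.0 <= self.level <= 1.0:
            raise ValueError(f"stage level must be in [0, 1], got {self.level}")

    @property
    def is_rest(self) -> bool:
        return self.level == 0.0


def rest(duration: float) -> Stage:
    return Stage(duration=duration, mode="relative", level=0.0)


def max_effort(duration: float) -> Stage:
    return Stage(duration=duration, mode="relative", level=1.0)


@dataclass(frozen=True)
class LoadingScheme:
    """An ordered sequence of stages with an initial muscle state."""

    stages: tuple
    x0: MuscleState = MuscleState(1.0, 1.0)
    name: str | None = None

    def __post_init__(self):
        if len(self.stages) == 0:
            raise ValueError("loading scheme needs at least one stage")
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.stages)

    @property
    def n_contractions(self) -> int:
        return sum(1 for s in self.stages if not s.is_rest)

    def stage_start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.stages])])


def concatenate_schemes(first: LoadingScheme, second: LoadingScheme) -> LoadingScheme:
    """Concatenate two schemes; the second scheme's x0 is ignored."""
    return LoadingScheme(stages=first.stages + second.stages, x0=first.x0,
                         name=None)


@dataclass
class Trajectory:
    """Time-resolved output of a simulation.

    ``tut`` is the cumulative time under tension (seconds of nonzero load up
    to each sample).  ``terminated_by`` is one of ``"horizon"`` (the scheme
    ran to its end), ``"plateau"`` or ``"task_failure"``.
    """

    times: np.ndarray
    x_slow: np.ndarray
    x_fast: np.ndarray
    u_abs: np.ndarray
    u_rel: np.ndarray
    tut: np.ndarray
    terminated_by: str = "horizon"
    termination_time: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def h_mvic(self) -> np.ndarray:
        return self.x_slow * self.x_fast

    @property
    def final_state(self) -> MuscleState:
        return MuscleState(
            float(np.clip(self.x_slow[-1], 0.0, 1.0)),
            float(np.clip(self.x_fast[-1], 0.0, 1.0)),
        )

    @property
    def end_h_mvic(self) -> float:
        return float(self.h_mvic[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "x_slow": self.x_slow,
                "x_fast": self.x_fast,
                "h_mvic": self.h_mvic,
                "u_abs": self.u_abs,
                "u_rel": self.u_rel,
                "tut_s": self.tut,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# right-hand side


def _pow_base(base: float, expo: float) -> float:
    """(1-u)^p4 with the conventions 0^0 = 1 and 0^p = 0 for p > 0."""
    if base <= 0.0:
        return 1.0 if expo == 0.0 else 0.0
    return base ** expo


def rhs(state, params: ModelParameters, u_abs: float):
    """Time derivatives (dx_slow/dt, dx_fast/dt) at a given state and load."""
    if isinstance(state, MuscleState):
        xs, xf = state.x_slow, state.x_fast
    else:
        xs, xf = float(state[0]), float(state[1])
    if not (-_STATE_TOL <= xs <= 1 + _STATE_TOL and -_STATE_TOL <= xf <= 1 + _STATE_TOL):
        raise ValueError(f"state ({xs}, {xf}) outside [0, 1]^2")
    if not (0.0 <= u_abs <= 1.0 + _STATE_TOL):
        raise ValueError(f"load u_abs={u_abs} outside [0, 1]")
    p = params
    d_slow = p.p1 * (1.0 - xs) - p.p2 * u_abs
    d_fast = p.p3 * _pow_base(1.0 - u_abs, p.p4) * (1.0 - xf) - p.p5 * u_abs
    return (d_slow, d_fast)


def _rhs_relative(xs: float, xf: float, p: ModelParameters, u_rel: float):
    """Unchecked RHS with the substitution u_abs = u_rel * x_slow * x_fast."""
    u = u_rel * xs * xf
    d_slow = p.p1 * (1.0 - xs) - p.p2 * u
    d_fast = p.p3 * _pow_base(1.0 - u, p.p4) * (1.0 - xf) - p.p5 * u
    return d_slow, d_fast


# ---------------------------------------------------------------------------
# constant-absolute-load stages have closed-form solutions (linear ODEs)


class _ConstLoadSolution:
    """Exact solution of both states under a constant absolute load u.

    Each state obeys dx/dt = k (1 - x) - c with constant k, c, hence
    x(t) = x_inf + (x0 - x_inf) exp(-k t) for k > 0, or linear decay for
    k = 0.  Rest (u = 0) is the special case c = 0.
    """

    def __init__(self, x0, params: ModelParameters, u: float):
        p = params
        self.u = u
        xs0, xf0 = float(x0[0]), float(x0[1])
        self._slow = self._affine(xs0, p.p1, p.p2 * u)
        k_fast = p.p3 * _pow_base(1.0 - u, p.p4)
        self._fast = self._affine(xf0, k_fast, p.p5 * u)

    @staticmethod
    def _affine(x0, k, c):
        if k > 0.0:
            x_inf = 1.0 - c / k
            return ("exp", x_inf, x0 - x_inf, k)
        return ("lin", x0, -c, 0.0)

    @staticmethod
    def _eval(coeffs, t):
        kind, a, b, k = coeffs
        if kind == "exp":
            return a + b * np.exp(-k * np.asarray(t, dtype=float))
        return a + b * np.asarray(t, dtype=float)

    def x_slow(self, t):
        return self._eval(self._slow, t)

    def x_fast(self, t):
        return self._eval(self._fast, t)

    def h(self, t):
        return self.x_slow(t) * self.x_fast(t)


# ---------------------------------------------------------------------------
# simulation


def _integrate_relative(x0, p: ModelParameters, u_rel: float, duration: float,
                        rtol: float, atol: float, stage_index: int,
                        events=None):
    def f(t, y):
        return _rhs_relative(y[0], y[1], p, u_rel)

    sol = solve_ivp(
        f,
        (0.0, duration),
        np.asarray(x0, dtype=float),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=events,
    )
    if not sol.success:
        raise IntegrationError(stage_index, sol.message)
    return sol


def _stage_samples(duration: float, output_dt: float, max_points: int = 400):
    n = int(np.ceil(duration / output_dt)) + 1
    n = min(max(n, 2), max_points)
    return np.linspace(0.0, duration, n)


def simulate(
    scheme: LoadingScheme,
    params: ModelParameters,
    *,
    rtol: float = RTOL,
    atol: float = ATOL,
    output_dt: float = 0.5,
    on_infeasible: str = "raise",
) -> Trajectory:
    """Integrate a loading scheme stage by stage.

    Relative-mode stages substitute ``u_abs = u_rel * h_MVIC`` into the
    dynamics and are integrated numerically; constant-absolute stages
    (including rests) use the exact linear-ODE solution.  State continuity
    is enforced across stage boundaries.

    ``on_infeasible`` controls what happens when an absolute stage demands
    more than the current capacity: ``"raise"`` (default) raises
    :class:`InfeasibleLoadError`; ``"continue"`` keeps integrating (the
    model stays evaluable), which is what the task-failure detector relies
    on.
    """
    x = np.array([scheme.x0.x_slow, scheme.x0.x_fast], dtype=float)
    t_acc: list = []
    xs_acc: list = []
    xf_acc: list = []
    ua_acc: list = []
    ur_acc: list = []
    tut_acc: list = []
    t0 = 0.0
    tut0 = 0.0
    for i, stage in enumerate(scheme.stages):
        ts = _stage_samples(stage.duration, output_dt)
        if stage.mode == "relative":
            if stage.level == 0.0:
                sol = _ConstLoadSolution(x, params, 0.0)
                xs = sol.x_slow(ts)
                xf = sol.x_fast(ts)
            else:
                ivp = _integrate_relative(x, params, stage.level, stage.duration,
                                          rtol, atol, i)
                y = ivp.sol(ts)
                xs, xf = y[0], y[1]
            ua = stage.level * xs * xf
            ur = np.full_like(ts, stage.level)
        else:
            h_start = x[0] * x[1]
            if stage.level > h_start + _STATE_TOL and on_infeasible == "raise":
                raise InfeasibleLoadError(
                    i,
                    f"stage {i}: absolute load {stage.level:.4f} exceeds "
                    f"current capacity {h_start:.4f}",
                )
            sol = _ConstLoadSolution(x, params, stage.level)
            xs = sol.x_slow(ts)
            xf = sol.x_fast(ts)
            ua = np.full_like(ts, stage.level)
            with np.errstate(divide="ignore", invalid="ignore"):
                h = xs * xf
                ur = np.where(h > 0, np.minimum(ua / np.where(h > 0, h, 1.0), 1.0), 0.0)
        tut_rate = 0.0 if stage.is_rest else 1.0
        skip = 1 if t_acc else 0  # avoid duplicating the shared boundary point
        t_acc.append(t0 + ts[skip:])
        xs_acc.append(xs[skip:])
        xf_acc.append(xf[skip:])
        ua_acc.append(ua[skip:])
        ur_acc.append(ur[skip:])
        tut_acc.append(tut0 + tut_rate * ts[skip:])
        x = np.array([xs[-1], xf[-1]], dtype=float)
        t0 += stage.duration
        tut0 += tut_rate * stage.duration
    return Trajectory(
        times=np.concatenate(t_acc),
        x_slow=np.concatenate(xs_acc),
        x_fast=np.concatenate(xf_acc),
        u_abs=np.concatenate(ua_acc),
        u_rel=np.concatenate(ur_acc),
        tut=np.concatenate(tut_acc),
        terminated_by="horizon",
        termination_time=t0,
    )


# ---------------------------------------------------------------------------
# all-out tests and task failure


def detect_plateau_sustained(
    params: ModelParameters,
    *,
    horizon: float = DEFAULT_HORIZON,
    threshold: float = 1e-6,
    rtol: float = RTOL,
    atol: float = ATOL,
    x0: MuscleState = MuscleState(1.0, 1.0),
) -> Trajectory:
    """Sustained maximal effort (u_rel = 1) until both state derivatives
    fall below ``threshold`` in magnitude, or the horizon is exhausted.

    The returned trajectory ends at the plateau (``terminated_by ==
    "plateau"``) or at the horizon; its last h_MVIC sample is the end-test
    torque.
    """

    def plateau_event(t, y):
        d_slow, d_fast = _rhs_relative(y[0], y[1], params, 1.0)
        return max(abs(d_slow), abs(d_fast)) - threshold

    plateau_event.terminal = True
    plateau_event.direction = -1

    sol = _integrate_relative(x0.as_array(), params, 1.0, horizon, rtol, atol,
                              0, events=[plateau_event])
    if sol.t_events[0].size:
        t_end = float(sol.t_events[0][0])
        terminated = "plateau"
    else:
        t_end = horizon
        terminated = "horizon"
    ts = np.linspace(0.0, t_end, 400)
    y = sol.sol(ts)
    return Trajectory(
        times=ts,
        x_slow=y[0],
        x_fast=y[1],
        u_abs=y[0] * y[1],
        u_rel=np.ones_like(ts),
        tut=ts.copy(),
        terminated_by=terminated,
        termination_time=t_end,
    )


def detect_plateau_intermittent(
    params: ModelParameters,
    *,
    t_c: float = 3.0,
    t_r: float = 2.0,
    horizon: float = DEFAULT_HORIZON,
    threshold: float = 1e-6,
    rtol: float = RTOL,
    atol: float = ATOL,
    x0: MuscleState = MuscleState(1.0, 1.0),
) -> Trajectory:
    """Intermittent maximal efforts (t_c on / t_r off) until the torque at
    the onsets of two successive contractions differs by <= ``threshold``.

    The end-test torque is h_MVIC at the last contraction onset; the
    trajectory records the onset samples (one point per cycle) plus the
    within-cycle detail of the final cycle simulated.
    """
    x = x0.as_array()
    t = 0.0
    onset_times = [0.0]
    onset_xs = [float(x[0])]
    onset_xf = [float(x[1])]
    cycle = t_c + t_r
    n_max = int(np.floor(horizon / cycle + 1e-9))
    terminated = "horizon"
    for k in range(n_max):
        ivp = _integrate_relative(x, params, 1.0, t_c, rtol, atol, 2 * k)
        x = ivp.y[:, -1].copy()
        sol = _ConstLoadSolution(x, params, 0.0)
        x = np.array([float(sol.x_slow(t_r)), float(sol.x_fast(t_r))])
        t += cycle
        onset_times.append(t)
        onset_xs.append(float(x[0]))
        onset_xf.append(float(x[1]))
        if abs(onset_xs[-1] * onset_xf[-1]
               - onset_xs[-2] * onset_xf[-2]) <= threshold:
            terminated = "plateau"
            break
    times = np.asarray(onset_times)
    xs = np.asarray(onset_xs)
    xf = np.asarray(onset_xf)
    h = xs * xf
    return Trajectory(
        times=times,
        x_slow=xs,
        x_fast=xf,
        u_abs=h,  # at an onset of a maximal effort the demanded load is h
        u_rel=np.ones_like(h),
        tut=np.arange(len(h)) * t_c,
        terminated_by=terminated,
        termination_time=float(times[-1]),
        extra={"end_test_torque": float(h[-1]), "n_cycles": len(h) - 1,
               "onset_h": h},
    )


def detect_task_failure(
    scheme: LoadingScheme,
    params: ModelParameters,
    *,
    output_dt: float = 0.5,
    refine_tol: float = 1e-9,
) -> Trajectory:
    """Simulate an absolute-target scheme until MVIC torque drops below the
    demanded load during a contraction (task failure).

    Stages must be absolute-mode (rests may be either mode).  The failure
    time is refined by root finding on the exact within-stage solution.  If
    capacity never falls below the target, the full scheme is returned with
    ``terminated_by == "horizon"``.
    """
    x = np.array([scheme.x0.x_slow, scheme.x0.x_fast], dtype=float)
    t_acc, xs_acc, xf_acc, ua_acc, tut_acc = [], [], [], [], []
    t0, tut0 = 0.0, 0.0
    failure_time = None
    for i, stage in enumerate(scheme.stages):
        if not stage.is_rest and stage.mode != "absolute":
            raise ValueError("task-failure detection requires absolute-mode "
                             f"contraction stages (stage {i} is relative)")
        u = stage.level if stage.mode == "absolute" else 0.0
        sol = _ConstLoadSolution(x, params, u)
        ts = _stage_samples(stage.duration, output_dt)
        if not stage.is_rest:
            h0 = float(x[0] * x[1])
            if h0 < u:
                failure_time = t0
                ts = ts[:1]
            else:
                g = sol.h(ts) - u
                below = np.flatnonzero(g < 0.0)
                if below.size:
                    j = below[0]
                    t_cross = brentq(lambda s: float(sol.h(s)) - u,
                                     ts[j - 1], ts[j], xtol=refine_tol)
                    failure_time = t0 + t_cross
                    ts = np.append(ts[:j], t_cross)
        xs = sol.x_slow(ts)
        xf = sol.x_fast(ts)
        tut_rate = 0.0 if stage.is_rest else 1.0
        skip = 1 if t_acc and ts.size > 0 else 0
        t_acc.append(t0 + ts[skip:] if skip else t0 + ts)
        xs_acc.append(xs[skip:] if skip else xs)
        xf_acc.append(xf[skip:] if skip else xf)
        ua_acc.append(np.full(len(ts) - skip, u))
        tut_acc.append(tut0 + tut_rate * (ts[skip:] if skip else ts))
        if failure_time is not None:
            break
        x = np.array([float(xs[-1]), float(xf[-1])])
        t0 += stage.duration
        tut0 += tut_rate * stage.duration
    times = np.concatenate(t_acc)
    xs = np.concatenate(xs_acc)
    xf = np.concatenate(xf_acc)
    ua = np.concatenate(ua_acc)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = xs * xf
        ur = np.where(h > 0, np.minimum(ua / np.where(h > 0, h, 1.0), 1.0), 0.0)
    return Trajectory(
        times=times,
        x_slow=xs,
        x_fast=xf,
        u_abs=ua,
        u_rel=ur,
        tut=np.concatenate(tut_acc),
        terminated_by="task_failure" if failure_time is not None else "horizon",
        termination_time=failure_time if failure_time is not None else float(times[-1]),
    )


# ---------------------------------------------------------------------------
# scenario library

#: recovery-probe start times of the intuitive testing session, in seconds
#: after cessation of the 3 min sustained maximal effort
ITS_PROBE_STARTS = (10.0, 30.0, 60.0, 120.0, 300.0, 600.0, 900.0, 1200.0,
                    1500.0, 1800.0)

SCENARIO_NAMES = ("SC", "SCmax", "IC", "ICmax", "IC80", "IC120", "ITS", "RTS")


def build_its() -> LoadingScheme:
    """Intuitive testing session: a 3 min maximal effort, then 2 s maximal
    probes starting 10 s, 30 s, 1, 2, 5, 10, 15, 20, 25 and 30 min after
    cessation.  Totals 1982 s with 200 s time under tension."""
    stages = [max_effort(180.0)]
    prev_end = 0.0  # time since cessation
    for start in ITS_PROBE_STARTS:
        stages.append(rest(start - prev_end))
        stages.append(max_effort(2.0))
        prev_end = start + 2.0
    return LoadingScheme(stages=tuple(stages), name="ITS")


def build_rts() -> LoadingScheme:
    """Resistance training session: 5 sets of 5 x (5 s maximal effort + 5 s
    rest) with 120 s between sets; the session ends at the end of the 25th
    contraction, where end-MVIC torque is read."""
    stages = []
    for set_idx in range(5):
        for rep in range(5):
            stages.append(max_effort(5.0))
            last = set_idx == 4 and rep == 4
            if not last:
                if rep == 4:
                    stages.append(rest(120.0))
                else:
                    stages.append(rest(5.0))
    return LoadingScheme(stages=tuple(stages), name="RTS")


def build_intermittent_max(t_c: float = 3.0, t_r: float = 2.0,
                           horizon: float = DEFAULT_HORIZON) -> LoadingScheme:
    """Repeated maximal (t_c on / t_r off) cycles filling the horizon."""
    n = int(np.floor(horizon / (t_c + t_r) + 1e-9))
    if n < 1:
        raise ValueError("horizon shorter than one contraction-rest cycle")
    stages = []
    for _ in range(n):
        stages.append(max_effort(t_c))
        stages.append(rest(t_r))
    return LoadingScheme(stages=tuple(stages), name="ICmax")


def build_intermittent_target(target: float, t_c: float = 3.0,
                              t_r: float = 2.0,
                              horizon: float = DEFAULT_HORIZON,
                              name: str | None = None) -> LoadingScheme:
    """Repeated constant-target (absolute) contractions, t_c on / t_r off."""
    n = int(np.floor(horizon / (t_c + t_r) + 1e-9))
    stages = []
    for _ in range(n):
        stages.append(Stage(duration=t_c, mode="absolute", level=target))
        stages.append(rest(t_r))
    return LoadingScheme(stages=tuple(stages), name=name)


def build_scenario(name: str, *, target: float | None = None,
                   horizon: float = DEFAULT_HORIZON,
                   t_c: float = 3.0, t_r: float = 2.0) -> LoadingScheme:
    """Construct a library scenario by name.

    ``SC``/``IC`` (constant-target sustained / intermittent) and
    ``IC80``/``IC120`` need ``target`` — an absolute torque as a fraction of
    baseline; for IC80/IC120 pass the already-scaled 0.8 x CT or 1.2 x CT
    value.  ``SCmax``/``ICmax`` are maximal-effort all-out layouts on the
    given horizon; ``ITS`` and ``RTS`` are fixed layouts.
    """
    key = name.upper()
    if key == "ITS":
        return build_its()
    if key == "RTS":
        return build_rts()
    if key == "SCMAX":
        return LoadingScheme(stages=(max_effort(horizon),), name="SCmax")
    if key == "ICMAX":
        return build_intermittent_max(t_c=t_c, t_r=t_r, horizon=horizon)
    if key in ("SC", "IC", "IC80", "IC120"):
        if target is None:
            raise ValueError(f"scenario {name} requires a target torque")
        if key == "SC":
            return LoadingScheme(
                stages=(Stage(duration=horizon, mode="absolute", level=target),),
                name="SC",
            )
        return build_intermittent_target(target, t_c=t_c, t_r=t_r,
                                         horizon=horizon, name=key)
    raise ValueError(
        f"unknown scenario {name!r}; known scenarios: {', '.join(SCENARIO_NAMES)}"
    )


def tut(obj) -> float:
    """Total time under tension: the integral of the indicator of nonzero
    load.  Accepts a LoadingScheme (exact sum over contraction stages) or a
    Trajectory (final cumulative value)."""
    if isinstance(obj, LoadingScheme):
        return float(sum(s.duration for s in obj.stages if not s.is_rest))
    if isinstance(obj, Trajectory):
        return float(obj.tut[-1])
    raise TypeError(f"cannot compute TUT of {type(obj).__name__}")
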