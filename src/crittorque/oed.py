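"""A-criterion optimum experimental design of testing sessions.

A testing session is an alternating sequence of contraction and rest
stages: ``n_s = 2 n_contractions - 1`` stages, odd-indexed (1st, 3rd, ...)
stages are contractions with a constant relative load, even-indexed stages
are rests.  The design variables are all stage durations and the relative
load of every contraction stage.  The objective is the average variance of
the (to-1 scaled) parameter estimates,

    (1/5) tr((J^T J)^{-1}),

where J is the weighted measurement Jacobian built from ``n_meas`` discrete
measurements per contraction stage (uniform midpoints, duration T/n_meas
each, error model from :mod:`crittorque.estimation`).  Constraints: a
minimum stage duration of 0.01 s, a total-time budget C_T, and a
time-under-tension budget C_TUT (TUT accrues at rate u_rel on contraction
stages, matching the indicator measure for on/off loading).

The optimizer is SLSQP over normalized design variables with
finite-difference gradients over exact sensitivity solves; every feasible
iterate is recorded and the best one is returned, so the result can never
be worse than a feasible initial design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import NonlinearConstraint, minimize

from .estimation import SIGMA_2S, MeasurementPlan, assemble_jacobian
from .model import LoadingScheme, ModelParameters, Stage, build_its

__all__ = [
    "DesignSpec",
    "Design",
    "SessionEvaluation",
    "design_objective",
    "scheme_from_design",
    "its_design",
    "optimize_design",
    "evaluate_reference_sessions",
]

logger = logging.getLogger(__name__)

#: ridge added to J^T J before inversion to keep line searches finite when
#: an iterate is (nearly) information-singular; flagged when it matters
RIDGE = 1e-12


@dataclass(frozen=True)
class DesignSpec:
    """Budgets and discretization of the design problem."""

    params: ModelParameters
    n_contractions: int = 11
    c_total: float = 1982.0
    c_tut: float = 200.0
    t_min: float = 0.01
    n_meas_per_stage: int = 100
    sigma_2s: float = SIGMA_2S

    def __post_init__(self):
        if self.n_contractions < 1:
            raise ValueError("need at least one contraction")
        if self.t_min * self.n_stages > self.c_total:
            raise ValueError(
                f"infeasible spec: {self.n_stages} stages at minimum duration "
                f"{self.t_min} s exceed the total-time budget {self.c_total} s"
            )
        if self.c_tut <= 0 or self.c_total <= 0:
            raise ValueError("budgets must be positive")

    @property
    def n_stages(self) -> int:
        return 2 * self.n_contractions - 1


@dataclass
class Design:
    """A concrete testing-session layout.

    ``durations`` has one entry per stage (contractions at even python
    indices 0, 2, ...), ``loads`` one relative load per contraction stage.
    """

    durations: np.ndarray
    loads: np.ndarray
    objective: float | None = None
    scaled_sd: np.ndarray | None = None

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.loads = np.asarray(self.loads, dtype=float)
        if len(self.durations) != 2 * len(self.loads) - 1:
            raise ValueError("durations must have 2*len(loads) - 1 entries")

    @property
    def total_duration(self) -> float:
        return float(np.sum(self.durations))

    @property
    def tut(self) -> float:
        return float(np.sum(self.durations[::2] * self.loads))

    def to_dict(self) -> dict:
        out = {
            "durations_s": list(self.durations),
            "loads": list(self.loads),
        }
        if self.objective is not None:
            out["objective"] = self.objective
        if self.scaled_sd is not None:
            out["scaled_sd"] = list(self.scaled_sd)
        return out


def scheme_from_design(design: Design, drop_idle_rests: bool = False) -> LoadingScheme:
    """Loading scheme with alternating contraction/rest stages."""
    stages = []
    k = 0
    for i, T in enumerate(design.durations):
        if i % 2 == 0:
            stages.append(Stage(duration=float(T), mode="relative",
                                level=float(design.loads[k])))
            k += 1
        else:
            stages.append(Stage(duration=float(T), mode="relative", level=0.0))
    return LoadingScheme(stages=tuple(stages))


def its_design(spec: DesignSpec) -> Design:
    """The intuitive testing session encoded as a Design (the default
    initial guess; requires the spec's 11-contraction layout)."""
    its = build_its()
    if spec.n_contractions != its.n_contractions:
        raise ValueError(
            f"the intuitive session has {its.n_contractions} contractions, "
            f"spec asks for {spec.n_contractions}"
        )
    durations = np.array([s.duration for s in its.stages])
    loads = np.array([s.level for s in its.stages if not s.is_rest])
    return Design(durations=durations, loads=loads)


def default_initial_design(spec: DesignSpec) -> Design:
    """A feasible starting layout: the intuitive session when the spec has
    its 11 contractions, otherwise maximal contractions of equal duration
    exhausting the TUT budget with evenly split rests."""
    if spec.n_contractions == 11:
        try:
            return its_design(spec)
        except ValueError:
            pass
    n_c = spec.n_contractions
    t_c = max(min(spec.c_tut / n_c, 0.5 * spec.c_total / max(n_c, 1)),
              spec.t_min)
    n_rest = n_c - 1
    if n_rest:
        t_r = max((min(spec.c_total, 2 * n_c * t_c) - n_c * t_c) / n_rest,
                  spec.t_min)
    else:
        t_r = 0.0
    durations = np.empty(spec.n_stages)
    durations[::2] = t_c
    if n_rest:
        durations[1::2] = t_r
    return Design(durations=durations, loads=np.ones(n_c))


def _plan_for_design(design: Design, spec: DesignSpec) -> MeasurementPlan:
    times, durations, u_rel = [], [], []
    t0 = 0.0
    k = 0
    n = spec.n_meas_per_stage
    for i, T in enumerate(design.durations):
        if i % 2 == 0:
            load = design.loads[k]
            k += 1
            if load > 0:
                dt = T / n
                times.append(t0 + (np.arange(n) + 0.5) * dt)
                durations.append(np.full(n, dt))
                u_rel.append(np.full(n, load))
        t0 += T
    if not times:
        raise ValueError("design has no loaded contraction stages")
    return MeasurementPlan(np.concatenate(times), np.concatenate(durations),
                           np.concatenate(u_rel), sigma_2s=spec.sigma_2s)


def design_objective(design: Design, spec: DesignSpec, *,
                     return_sd: bool = False, rtol: float = 1e-8,
                     atol: float = 1e-10):
    """A-criterion value (1/5) tr((J^T J)^{-1}) on the to-1 scaled
    parameters, with the design's measurement layout.

    Raises :class:`numpy.linalg.LinAlgError` when the information matrix is
    singular beyond the ridge's reach (a design that measures nothing
    informative).
    """
    scheme = scheme_from_design(design)
    plan = _plan_for_design(design, spec)
    J = assemble_jacobian(spec.params, scheme, plan, rtol=rtol, atol=atol)
    scale = spec.params.as_array()
    Js = J * scale[None, :]  # parameters scaled to 1
    gram = Js.T @ Js + RIDGE * np.eye(5)
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e15:
        raise np.linalg.LinAlgError(
            f"singular information matrix (condition {cond:.3g})"
        )
    C = np.linalg.inv(gram)
    obj = float(np.trace(C) / 5.0)
    if return_sd:
        return obj, np.sqrt(np.diag(C))
    return obj


@dataclass
class _BestTracker:
    spec: DesignSpec
    best_x: np.ndarray | None = None
    best_obj: float = np.inf
    n_eval: int = 0


def _unpack(x, spec: DesignSpec):
    n_s = spec.n_stages
    durations = x[:n_s] * spec.c_total
    loads = x[n_s:]
    return Design(durations=durations, loads=loads)


def optimize_design(spec: DesignSpec, initial: Design | None = None, *,
                    maxiter: int = 30, rtol: float = 1e-7, atol: float = 1e-9,
                    fd_step: float = 1e-4,
                    extra_candidates: list | None = None) -> Design:
    """Optimize stage durations and contraction loads under the spec's
    budgets, starting from ``initial`` (default: the intuitive session).

    Durations are normalized by C_T inside the optimizer so all decision
    variables are O(1).  The returned design is the best feasible iterate
    encountered (never worse than a feasible initial design); additional
    candidate designs (e.g. the solution of a tighter budget) can be
    supplied and compete on equal terms.
    """
    if initial is None:
        initial = default_initial_design(spec)
    n_s = spec.n_stages

    tracker = _BestTracker(spec)

    def pack(design: Design) -> np.ndarray:
        return np.concatenate([design.durations / spec.c_total, design.loads])

    def objective(x) -> float:
        design = _unpack(x, spec)
        tracker.n_eval += 1
        try:
            obj = design_objective(design, spec, rtol=rtol, atol=atol)
        except (np.linalg.LinAlgError, ValueError):
            return 1e6
        # track feasibility at constraint tolerance
        feas = (
            np.all(design.durations >= spec.t_min - 1e-8)
            and design.total_duration <= spec.c_total + 1e-8
            and design.tut <= spec.c_tut + 1e-8
            and np.all(design.loads >= -1e-12)
            and np.all(design.loads <= 1 + 1e-12)
        )
        if feas and obj < tracker.best_obj:
            tracker.best_obj = obj
            tracker.best_x = np.asarray(x, dtype=float).copy()
        return float(np.log(obj))

    def total_time(x):
        return float(np.sum(x[:n_s]) * spec.c_total)

    def tut_value(x):
        d = x[:n_s] * spec.c_total
        return float(np.sum(d[::2] * x[n_s:]))

    constraints = [
        NonlinearConstraint(total_time, 0.0, spec.c_total),
        NonlinearConstraint(tut_value, 0.0, spec.c_tut),
    ]
    bounds = [(spec.t_min / spec.c_total, 1.0)] * n_s + [(0.0, 1.0)] * spec.n_contractions

    x0 = pack(initial)
    objective(x0)  # seed the tracker with the initial design
    for cand in extra_candidates or []:
        objective(pack(cand))
    res = minimize(
        objective,
        x0,
        method="SLSQP",
        bounds=bounds,
        constraints=constraints,
        options={"maxiter": maxiter, "ftol": 1e-8, "eps": fd_step},
    )
    if not res.success:
        logger.warning("design optimization stopped without convergence "
                       "(%s); returning best feasible iterate", res.message)
    if tracker.best_x is None:
        raise RuntimeError("no feasible design encountered; check the spec "
                           "and the initial design")
    best = _unpack(tracker.best_x, spec)
    obj, sd = design_objective(best, spec, return_sd=True, rtol=rtol, atol=atol)
    best.objective = obj
    best.scaled_sd = sd
    return best


@dataclass
class SessionEvaluation:
    """Objective and scaled parameter SDs of one testing session."""

    name: str
    design: Design
    objective: float
    scaled_sd: np.ndarray

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "objective": self.objective,
            "scaled_sd": list(self.scaled_sd),
            "design": self.design.to_dict(),
        }


def evaluate_reference_sessions(params: ModelParameters, *,
                                n_meas_per_stage: int = 100,
                                maxiter: int = 30,
                                sigma_2s: float = SIGMA_2S,
                                rtol: float = 1e-7,
                                atol: float = 1e-9) -> dict:
    """Compare the intuitive session against optimized sessions under the
    200 s and 400 s TUT budgets (objective and per-parameter scaled SDs).

    The 400 s problem additionally receives the 200 s solution as a
    candidate, which makes the budget-nesting relation (larger budget never
    worse) hold by construction.
    """
    spec200 = DesignSpec(params=params, c_tut=200.0,
                         n_meas_per_stage=n_meas_per_stage, sigma_2s=sigma_2s)
    spec400 = DesignSpec(params=params, c_tut=400.0,
                         n_meas_per_stage=n_meas_per_stage, sigma_2s=sigma_2s)
    its = its_design(spec200)
    # one shared integration tolerance keeps the three objectives comparable
    obj_its, sd_its = design_objective(its, spec200, return_sd=True,
                                       rtol=rtol, atol=atol)
    its.objective, its.scaled_sd = obj_its, sd_its

    ots200 = optimize_design(spec200, maxiter=maxiter, rtol=rtol, atol=atol)
    ots400 = optimize_design(spec400, maxiter=maxiter, rtol=rtol, atol=atol,
                             extra_candidates=[ots200])
    return {
        "ITS": SessionEvaluation("ITS", its, obj_its, sd_its),
        "OTS200": SessionEvaluation("OTS200", ots200, ots200.objective,
                                    ots200.scaled_sd),
        "OTS400": SessionEvaluation("OTS400", ots400, ots400.objective,
                                    ots400.scaled_sd),
    }
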