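"""Monte-Carlo propagation of parameter uncertainty through the model.

Parameter estimates carry statistical uncertainty (per-parameter standard
deviations ``sigma_p`` from a testing session's covariance analysis).  To
see how that uncertainty affects predictions, parameter vectors are sampled
from independent normals N(p_i, sigma_p_i^2) — whole vectors with any
negative component are rejected and redrawn, since the model is not
evaluable there — a scenario is re-simulated per draw, and the differences
of end-MVIC torque to the nominal run are summarized by their standard
deviation and a Gaussian kernel density estimate (Scott's bandwidth rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import (
    DEFAULT_HORIZON,
    LoadingScheme,
    ModelParameters,
    build_intermittent_max,
    build_rts,
    simulate,
)

__all__ = [
    "PropagationResult",
    "sample_parameters",
    "end_mvic_torque",
    "propagate",
    "gaussian_kde",
    "scott_bandwidth",
]


@dataclass
class PropagationResult:
    """Distribution of end-MVIC-torque differences under parameter noise."""

    scenario: str
    n_samples: int
    nominal_end_torque: float
    differences: np.ndarray
    sd: float
    redraw_count: int
    seed: int | None
    kde_grid: np.ndarray | None = None
    kde_density: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "scenario": self.scenario,
            "n_samples": self.n_samples,
            "nominal_end_torque": self.nominal_end_torque,
            "sd": self.sd,
            "redraw_count": self.redraw_count,
            "seed": self.seed,
        }
        if self.kde_grid is not None:
            out["kde_grid"] = list(self.kde_grid)
            out["kde_density"] = list(self.kde_density)
        return out


def sample_parameters(p: ModelParameters, sigma_p, n: int, seed=None,
                      rng: np.random.Generator | None = None,
                      covariance: np.ndarray | None = None):
    """Draw ``n`` nonnegative parameter vectors from N(p, sigma_p^2).

    Components are independent normals by default; passing a full
    ``covariance`` samples the multivariate normal N(p, C) instead.  Any
    realization with a negative component is rejected and redrawn whole,
    which preserves the stated distribution conditional on nonnegativity.
    Returns ``(samples, redraw_count)``; reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    sigma_p = np.asarray(sigma_p, dtype=float)
    if sigma_p.shape != (5,):
        raise ValueError("sigma_p must have 5 components")
    if np.any(sigma_p < 0):
        raise ValueError("sigma_p must be nonnegative")
    mean = p.as_array()
    # acceptance probability of one draw; guard against hopeless inputs
    with np.errstate(divide="ignore"):
        z = np.where(sigma_p > 0, mean / np.where(sigma_p > 0, sigma_p, 1.0),
                     np.inf)
    accept_prob = float(np.prod(stats.norm.cdf(z)))
    if accept_prob < 1e-6:
        raise ValueError(
            f"practically all probability mass has negative components "
            f"(acceptance probability {accept_prob:.2e})"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    out = np.empty((n, 5))
    filled = 0
    redraws = 0
    while filled < n:
        m = n - filled
        if covariance is not None:
            draws = rng.multivariate_normal(mean, covariance, size=m)
        else:
            draws = mean[None, :] + rng.normal(size=(m, 5)) * sigma_p[None, :]
        ok = np.all(draws >= 0.0, axis=1)
        k = int(np.sum(ok))
        out[filled:filled + k] = draws[ok]
        filled += k
        redraws += m - k
    return out, redraws


def end_mvic_torque(params: ModelParameters, scheme: LoadingScheme,
                    *, output_dt: float = 2.0) -> float:
    """MVIC torque capacity at the final instant of a scenario."""
    traj = simulate(scheme, params, output_dt=output_dt)
    return traj.end_h_mvic


def _resolve_scenario(scenario) -> tuple[str, LoadingScheme]:
    if isinstance(scenario, LoadingScheme):
        return scenario.name or "custom", scenario
    key = str(scenario).lower()
    if key in ("icmax", "icmax-60min"):
        return "ICmax", build_intermittent_max(horizon=DEFAULT_HORIZON)
    if key == "rts":
        return "RTS", build_rts()
    raise ValueError(f"unknown scenario {scenario!r}; use 'icmax', 'rts' or "
                     "pass a LoadingScheme")


def propagate(p: ModelParameters, sigma_p, scenario, n: int = 10_000,
              seed=None, *, covariance: np.ndarray | None = None,
              kde_points: int = 201, output_dt: float = 5.0) -> PropagationResult:
    """Re-simulate a scenario under perturbed parameters and collect the
    end-MVIC-torque differences to the nominal run.

    The scenario is ``"icmax"`` (60 min of maximal 3 s / 2 s efforts),
    ``"rts"`` (the resistance training session), or any loading scheme.
    The KDE is omitted when the differences are degenerate (all equal).
    """
    name, scheme = _resolve_scenario(scenario)
    nominal = end_mvic_torque(p, scheme, output_dt=output_dt)
    samples, redraws = sample_parameters(p, sigma_p, n, seed=seed,
                                         covariance=covariance)
    diffs = np.empty(n)
    for i in range(n):
        try:
            pi = ModelParameters.from_array(samples[i])
            diffs[i] = end_mvic_torque(pi, scheme, output_dt=output_dt) - nominal
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"simulation failed for perturbed draw {i}: "
                f"parameters {samples[i]!r}"
            ) from exc
    sd = float(np.std(diffs))
    grid = density = None
    if np.ptp(diffs) > 0:
        lo, hi = float(np.min(diffs)), float(np.max(diffs))
        pad = 3.0 * scott_bandwidth(diffs)
        grid = np.linspace(lo - pad, hi + pad, kde_points)
        density = gaussian_kde(diffs, grid)
    return PropagationResult(
        scenario=name,
        n_samples=n,
        nominal_end_torque=nominal,
        differences=diffs,
        sd=sd,
        redraw_count=redraws,
        seed=seed if isinstance(seed, int) else None,
        kde_grid=grid,
        kde_density=density,
    )


def scott_bandwidth(samples) -> float:
    """Scott's rule of thumb: h = n^(-1/5) * sample standard deviation."""
    samples = np.asarray(samples, dtype=float)
    sd = float(np.std(samples, ddof=1))
    if sd == 0:
        raise ValueError("degenerate sample: all values identical")
    return len(samples) ** (-0.2) * sd


def gaussian_kde(samples, grid) -> np.ndarray:
    """1-D Gaussian kernel density estimate with Scott's bandwidth.

    Delegates to :class:`scipy.stats.gaussian_kde` (Scott's factor is its
    default), which matches the direct kernel sum
    (1/(n h)) sum_i phi((x - s_i)/h) with h from :func:`scott_bandwidth`.
    """
    samples = np.asarray(samples, dtype=float)
    if len(np.unique(samples)) < 2:
        raise ValueError("degenerate sample: need at least 2 distinct values")
    kde = stats.gaussian_kde(samples, bw_method="scott")
    return kde(np.asarray(grid, dtype=float))
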