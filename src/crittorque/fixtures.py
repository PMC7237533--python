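"""Bundled fixture parameter sets and reference session layouts.

The fixture parameter vectors are synthetic stand-ins spanning plausible
fatigue/recovery phenotypes; they are NOT estimates for any real muscle
group.  They are frozen inside a parameter region (see
:func:`sample_fixture_battery`) chosen so that the library's steady-state
and all-out-test machinery is mutually consistent: critical torque from the
steady-state program agrees with the plateau of a 60-min all-out simulation
to well under 0.2 percentage points of baseline for both sustained and
3 s / 2 s intermittent loading, and the plateaus are reached within the
60-min horizon at the 1e-6 termination thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LoadingScheme, ModelParameters, Stage
from .oed import Design

__all__ = [
    "FixtureParameterSet",
    "FIXTURES",
    "get_fixture",
    "sample_fixture_battery",
    "reference_testing_session",
    "reference_testing_design",
]


@dataclass(frozen=True)
class FixtureParameterSet:
    name: str
    params: ModelParameters
    provenance: str


FIXTURES: dict[str, FixtureParameterSet] = {
    f.name: f
    for f in (
        FixtureParameterSet(
            "baseline",
            ModelParameters(0.0026, 0.0070, 0.0028, 1.5, 0.0030),
            "synthetic mid-range phenotype (frozen development choice)",
        ),
        FixtureParameterSet(
            "fatigable",
            ModelParameters(0.0024, 0.00756, 0.0027, 1.2, 0.00375),
            "synthetic fast-fatigue phenotype: high fatigue-to-recovery "
            "ratios, low critical torque",
        ),
        FixtureParameterSet(
            "enduring",
            ModelParameters(0.0028, 0.0062, 0.0030, 2.0, 0.0021),
            "synthetic endurance phenotype: low fatigue-to-recovery ratios, "
            "high critical torque",
        ),
    )
}


def get_fixture(name: str) -> ModelParameters:
    try:
        return FIXTURES[name].params
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}"
        ) from None


def sample_fixture_battery(n: int, seed=None) -> list[ModelParameters]:
    """Random parameter vectors from the validated fixture region.

    p1 ~ U[0.0024, 0.0028], p2 = p1 * U[2.2, 3.2], p3 ~ U[0.0026, 0.0030],
    p4 ~ U[1.0, 2.0], p5 = p3 * U[0.7, 1.4].  Within this region the
    steady-state/all-out consistency described in the module docstring
    holds for every vector.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        p1 = rng.uniform(0.0024, 0.0028)
        p2 = p1 * rng.uniform(2.2, 3.2)
        p3 = rng.uniform(0.0026, 0.0030)
        p4 = rng.uniform(1.0, 2.0)
        p5 = p3 * rng.uniform(0.7, 1.4)
        out.append(ModelParameters(p1, p2, p3, p4, p5))
    return out


#: frozen 21-stage testing-session layout in the style of an optimized
#: 400 s-TUT session (obtained from a development-time design optimization
#: for the "baseline" fixture and rounded); synthetic — not a published
#: session.  TUT accrues at rate u_rel, total 399.6 s; duration 1954 s.
_REFERENCE_DURATIONS = (
    140.0, 17.0, 5.0, 10.0, 5.0, 155.0, 68.0, 10.0, 132.0, 10.0, 215.0,
    10.0, 25.0, 170.0, 13.0, 338.0, 13.0, 290.0, 18.0, 303.0, 17.0,
)
_REFERENCE_LOADS = (1.0, 0.25, 0.79, 1.0, 0.37, 0.24, 1.0, 1.0, 1.0, 1.0, 1.0)


def reference_testing_design() -> Design:
    return Design(durations=np.array(_REFERENCE_DURATIONS),
                  loads=np.array(_REFERENCE_LOADS))


def reference_testing_session() -> LoadingScheme:
    """The frozen reference testing session as a loading scheme."""
    stages = []
    for i, dur in enumerate(_REFERENCE_DURATIONS):
        level = _REFERENCE_LOADS[i // 2] if i % 2 == 0 else 0.0
        stages.append(Stage(duration=dur, mode="relative", level=level))
    return LoadingScheme(stages=tuple(stages), name="reference-session")
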