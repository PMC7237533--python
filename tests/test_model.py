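"""Core dynamics: right-hand side, simulation, scenarios, termination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crittorque.model import (
    LoadingScheme,
    ModelParameters,
    MuscleState,
    Stage,
    build_scenario,
    concatenate_schemes,
    detect_plateau_intermittent,
    detect_plateau_sustained,
    detect_task_failure,
    max_effort,
    rest,
    rhs,
    simulate,
    tut,
)

P = ModelParameters(0.1, 0.2, 0.3, 2.0, 0.4)


class TestParameters:
    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="nonnegative"):
            ModelParameters(0.1, -0.2, 0.3, 2.0, 0.4)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError, match="finite"):
            ModelParameters(0.1, np.nan, 0.3, 2.0, 0.4)

    def test_array_round_trip(self):
        assert ModelParameters.from_array(P.as_array()) == P


class TestRhs:
    @pytest.mark.parametrize(
        "state,u,expected",
        [
            ((1.0, 1.0), 0.0, (0.0, 0.0)),       # unfatigued rest: fixed point
            ((1.0, 1.0), 0.5, (-0.1, -0.2)),     # only the -p2 u / -p5 u terms
            ((0.5, 0.5), 0.0, (0.05, 0.15)),     # pure recovery p1(1-xs), p3(1-xf)
        ],
    )
    def test_hand_values(self, state, u, expected):
        d = rhs(MuscleState(*state), P, u)
        assert d == pytest.approx(expected, abs=1e-15)

    def test_zero_power_convention(self):
        # (1-u)^p4 at u=1, p4=0 is taken as 1
        p = ModelParameters(0.1, 0.2, 0.3, 0.0, 0.4)
        d = rhs((0.5, 0.5), p, 1.0)
        assert d[1] == pytest.approx(0.3 * 0.5 - 0.4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rhs((0.5, 0.5), P, 1.5)
        with pytest.raises(ValueError):
            rhs((1.5, 0.5), P, 0.2)


class TestSimulate:
    def test_unfatigued_rest_is_fixed_point(self):
        scheme = LoadingScheme(stages=(rest(100.0),))
        traj = simulate(scheme, P)
        assert np.allclose(traj.x_slow, 1.0, atol=1e-9)
        assert np.allclose(traj.x_fast, 1.0, atol=1e-9)
        assert np.all(traj.tut == 0.0)

    def test_rest_recovery_closed_form(self):
        # under zero load the ODEs are linear: x = 1 - (1-x0) exp(-rate t)
        x0 = MuscleState(0.5, 0.5)
        scheme = LoadingScheme(stages=(rest(30.0),), x0=x0)
        traj = simulate(scheme, P)
        t = traj.times
        assert np.allclose(traj.x_slow, 1 - 0.5 * np.exp(-P.p1 * t), atol=1e-6)
        assert np.allclose(traj.x_fast, 1 - 0.5 * np.exp(-P.p3 * t), atol=1e-6)

    def test_monotone_fatigue_under_sustained_max(self, baseline_params):
        scheme = LoadingScheme(stages=(max_effort(600.0),))
        traj = simulate(scheme, baseline_params)
        assert np.all(np.diff(traj.h_mvic) <= 1e-12)

    def test_states_bounded_and_load_feasible(self, any_fixture_params):
        scheme = build_scenario("ITS")
        traj = simulate(scheme, any_fixture_params)
        tol = 1e-6
        assert np.all((traj.x_slow >= -tol) & (traj.x_slow <= 1 + tol))
        assert np.all((traj.x_fast >= -tol) & (traj.x_fast <= 1 + tol))
        assert np.all(traj.u_abs <= traj.h_mvic + tol)
        assert np.all(np.diff(traj.tut) >= -1e-12)
        assert np.all(traj.tut <= traj.times + 1e-9)

    def test_state_continuity_across_stages(self, baseline_params):
        scheme = LoadingScheme(stages=(max_effort(10.0), rest(5.0),
                                       max_effort(10.0)))
        traj = simulate(scheme, baseline_params, output_dt=0.1)
        assert np.all(np.abs(np.diff(traj.x_slow)) < 0.01)
        assert np.all(np.abs(np.diff(traj.x_fast)) < 0.01)

    def test_infeasible_absolute_stage_raises(self, baseline_params):
        # demand more torque than a heavily fatigued muscle can produce
        stages = (max_effort(600.0), Stage(10.0, "absolute", 0.95))
        scheme = LoadingScheme(stages=stages)
        from crittorque.model import InfeasibleLoadError

        with pytest.raises(InfeasibleLoadError) as err:
            simulate(scheme, baseline_params)
        assert err.value.stage_index == 1

    def test_trajectory_csv_columns(self, tmp_path, baseline_params):
        traj = simulate(build_scenario("RTS"), baseline_params)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        import pandas as pd

        frame = pd.read_csv(out)
        assert list(frame.columns) == [
            "time_s", "x_slow", "x_fast", "h_mvic", "u_abs", "u_rel", "tut_s"
        ]
        assert frame["time_s"].is_monotonic_increasing


class TestScenarios:
    def test_its_layout(self):
        its = build_scenario("ITS")
        assert its.total_duration == pytest.approx(1982.0)
        assert tut(its) == pytest.approx(200.0)
        assert its.n_contractions == 11

    def test_rts_layout(self):
        rts = build_scenario("RTS")
        assert rts.n_contractions == 25
        assert tut(rts) == pytest.approx(125.0)
        # 5 sets of 5x5 s efforts, 5 s intra rests, 120 s between sets,
        # ending on the last contraction
        assert rts.total_duration == pytest.approx(5 * 45 + 4 * 120)

    def test_icmax_five_minutes(self):
        icmax = build_scenario("ICmax", horizon=300.0)
        assert icmax.n_contractions == 60

    def test_unknown_scenario(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            build_scenario("XYZ")

    def test_target_scenarios_require_target(self):
        with pytest.raises(ValueError, match="target"):
            build_scenario("IC80")


class TestTut:
    def test_rest_scheme_zero(self):
        assert tut(LoadingScheme(stages=(rest(100.0),))) == 0.0

    def test_additive_under_concatenation(self):
        a = build_scenario("ITS")
        b = build_scenario("RTS")
        assert tut(concatenate_schemes(a, b)) == pytest.approx(tut(a) + tut(b))

    def test_trajectory_matches_scheme(self, baseline_params):
        scheme = build_scenario("RTS")
        traj = simulate(scheme, baseline_params)
        assert tut(traj) == pytest.approx(tut(scheme), abs=1e-6)

    def test_its_trajectory_accounting(self, baseline_params):
        traj = simulate(build_scenario("ITS"), baseline_params)
        assert traj.times[-1] == pytest.approx(1982.0)
        assert tut(traj) == pytest.approx(200.0, abs=1e-9)


class TestTermination:
    def test_sustained_plateau_reaches_derivative_threshold(self, baseline_params):
        traj = detect_plateau_sustained(baseline_params)
        assert traj.terminated_by == "plateau"
        d = rhs(traj.final_state, baseline_params,
                min(traj.end_h_mvic, 1.0))
        assert max(abs(d[0]), abs(d[1])) <= 2e-6

    def test_sustained_horizon_exhausted(self, baseline_params):
        traj = detect_plateau_sustained(baseline_params, horizon=10.0)
        assert traj.terminated_by == "horizon"

    def test_intermittent_plateau_onset_criterion(self, baseline_params):
        traj = detect_plateau_intermittent(baseline_params)
        assert traj.terminated_by == "plateau"
        h = traj.extra["onset_h"]
        assert abs(h[-1] - h[-2]) <= 1e-6

    def test_task_failure_zero_target_never_fails(self, baseline_params):
        scheme = build_scenario("SC", target=0.0, horizon=100.0)
        traj = detect_task_failure(scheme, baseline_params)
        assert traj.terminated_by == "horizon"

    def test_task_failure_above_capacity(self, baseline_params):
        # a sustained demand close to baseline must fail in finite time
        scheme = build_scenario("SC", target=0.9, horizon=3600.0)
        traj = detect_task_failure(scheme, baseline_params)
        assert traj.terminated_by == "task_failure"
        assert 0 < traj.termination_time < 3600.0
        # at the failure instant capacity has just crossed the target
        assert traj.h_mvic[-1] == pytest.approx(0.9, abs=1e-6)


@settings(max_examples=20, deadline=None)
@given(
    xs0=st.floats(0.0, 1.0),
    xf0=st.floats(0.0, 1.0),
    p1=st.floats(0.01, 0.5),
    p3=st.floats(0.01, 0.5),
)
def test_recovery_limit_property(xs0, xf0, p1, p3):
    """From any start, rest drives both states back toward 1 along the
    exact exponentials."""
    p = ModelParameters(p1, 0.1, p3, 2.0, 0.1)
    scheme = LoadingScheme(stages=(rest(50.0),), x0=MuscleState(xs0, xf0))
    traj = simulate(scheme, p)
    t = traj.times
    assert np.allclose(traj.x_slow, 1 - (1 - xs0) * np.exp(-p1 * t), atol=1e-6)
    assert np.allclose(traj.x_fast, 1 - (1 - xf0) * np.exp(-p3 * t), atol=1e-6)
    assert traj.x_slow[-1] >= xs0 - 1e-9
    assert traj.x_fast[-1] >= xf0 - 1e-9
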