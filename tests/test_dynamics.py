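"""Replicator integration, convergence detection and trajectory IO."""

import numpy as np
import pytest
from hypothesis import given

from ehrgame import (
    BASELINE,
    IntegratorConfig,
    MixedState,
    StepTooCoarseError,
    Trajectory,
    VERTICES,
    detect_convergence,
    gain_closed_form,
    integrate,
    nudge_interior,
    read_trajectory_csv,
    rhs,
    time_to_threshold,
    write_trajectory_csv,
)
from ehrgame.params import ConstraintError

from conftest import mixed_states, parameter_sets, random_parameter_set

ADAPTIVE = IntegratorConfig(method="adaptive-rk")


class TestRhs:
    @given(params=parameter_sets())
    def test_vertices_are_fixed_points(self, params):
        for vertex in VERTICES:
            assert rhs(MixedState(*vertex), params) == (0.0, 0.0, 0.0)

    def test_vertices_fixed_for_many_seeded_parameter_sets(self, rng):
        for _ in range(100):
            params = random_parameter_set(rng)
            for vertex in VERTICES:
                assert rhs(MixedState(*vertex), params) == (0.0, 0.0, 0.0)

    def test_center_rates_at_baseline(self, baseline):
        assert rhs(MixedState(0.5, 0.5, 0.5), baseline) == (7.375, 14.25, 0.375)

    @given(state=mixed_states(margin=0.01), params=parameter_sets())
    def test_interior_rate_signs_follow_gains(self, state, params):
        rates = rhs(state, params)
        gains = gain_closed_form(state, params).as_tuple()
        for r, g in zip(rates, gains):
            assert np.sign(r) == np.sign(g)

    def test_state_outside_cube_rejected(self, baseline):
        with pytest.raises(ConstraintError):
            rhs((-0.1, 0.5, 0.5), baseline)


class TestIntegrate:
    def test_vertex_start_stays_constant(self, baseline):
        traj = integrate(MixedState(0, 0, 0), baseline)
        assert np.all(traj.states == 0.0)

    @pytest.mark.parametrize("start", [(0.45, 0.35, 0.4), (0.01, 0.01, 0.01)])
    def test_baseline_interior_starts_reach_full_cooperation(self, start, baseline):
        traj = integrate(MixedState(*start), baseline)
        assert np.max(np.abs(traj.states[-1] - 1.0)) < 1e-3

    def test_trajectory_structure(self, baseline):
        traj = integrate(MixedState(0.45, 0.35, 0.4), baseline)
        assert len(traj) == 161  # 160 steps of 0.125 years over [0, 20]
        assert np.all(np.diff(traj.times) > 0)
        assert traj.states.min() >= 0.0 and traj.states.max() <= 1.0

    def test_deterministic_for_fixed_inputs(self, baseline):
        a = integrate(MixedState(0.45, 0.35, 0.4), baseline)
        b = integrate(MixedState(0.45, 0.35, 0.4), baseline)
        assert np.array_equal(a.states, b.states)

    def test_coarse_step_diagnostic_names_time(self, baseline):
        config = IntegratorConfig(clamp_tolerance=1e-9)
        with pytest.raises(StepTooCoarseError) as err:
            integrate(MixedState(0.45, 0.35, 0.4), baseline, config)
        assert err.value.time == pytest.approx(0.125)

    def test_adaptive_stays_in_cube_without_clamping(self, baseline):
        config = IntegratorConfig(method="adaptive-rk", clamp_tolerance=1e-6)
        traj = integrate(MixedState(0.45, 0.35, 0.4), baseline, config)
        assert traj.max_clamp <= 1e-6

    def test_integrators_agree_on_converged_vertex(self, baseline):
        for start in [(0.01, 0.01, 0.01), (0.45, 0.35, 0.4), (0.99, 0.01, 0.01),
                      (0.05, 0.5, 0.01)]:
            euler = detect_convergence(integrate(MixedState(*start), baseline))
            rk = detect_convergence(integrate(MixedState(*start), baseline, ADAPTIVE))
            assert euler == rk == (1, 1, 1)

    def test_boundary_coordinate_invariant(self, baseline):
        """x = 0 exactly is invariant; the rest still evolves to (0, 1, 0)."""
        traj = integrate(MixedState(0.0, 0.8, 0.01), baseline)
        assert np.all(traj.coordinate("x") == 0.0)
        assert detect_convergence(traj) == (0, 1, 0)

    def test_monotone_coordinate_when_gain_sign_constant(self, baseline):
        """g_z > 0 along the baseline flow from this start, so z is monotone."""
        traj = integrate(MixedState(0.45, 0.35, 0.4), baseline, ADAPTIVE)
        gains = [
            gain_closed_form(MixedState(*np.clip(s, 0, 1)), baseline).g_z
            for s in traj.states
        ]
        assert all(g > 0 for g in gains[:-1])
        assert np.all(np.diff(traj.coordinate("z")) >= -1e-12)

    def test_cube_invariance_of_adaptive_runs(self, rng):
        for _ in range(20):
            params = random_parameter_set(rng)
            start = MixedState(*rng.uniform(0.05, 0.95, 3))
            traj = integrate(start, params, ADAPTIVE)
            assert traj.max_clamp <= 1e-7

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            IntegratorConfig(t_end=0.0)
        with pytest.raises(ValueError):
            IntegratorConfig(step=30.0)
        with pytest.raises(ValueError):
            IntegratorConfig(method="rk4")


class TestDetectConvergence:
    def test_baseline_run_converges_to_full_cooperation(self, baseline):
        traj = integrate(MixedState(0.45, 0.35, 0.4), baseline)
        assert detect_convergence(traj, tol=1e-3) == (1, 1, 1)

    def test_constant_interior_trajectory_has_no_verdict(self):
        times = np.linspace(0, 20, 50)
        states = np.full((50, 3), 0.5)
        traj = Trajectory(times, states, IntegratorConfig())
        assert detect_convergence(traj, tol=1e-3) is None

    def test_passing_near_vertex_does_not_count(self):
        """Distance must be nonincreasing on the tail, not just small at the end."""
        times = np.linspace(0, 20, 100)
        z = np.concatenate([np.full(90, 1e-4), np.linspace(1e-4, 9e-4, 10)])
        states = np.column_stack([np.ones(100), np.ones(100), 1 - z])
        traj = Trajectory(times, states, IntegratorConfig())
        assert detect_convergence(traj, tol=1e-3) is None

    def test_empty_trajectory_rejected(self):
        traj = Trajectory(np.array([0.0]), np.array([[0.5, 0.5, 0.5]]),
                          IntegratorConfig())
        with pytest.raises(ValueError):
            detect_convergence(traj, tol=-1.0)


class TestTimeToThreshold:
    def test_never_crossing_returns_none(self):
        times = np.linspace(0, 20, 30)
        states = np.zeros((30, 3))
        traj = Trajectory(times, states, IntegratorConfig())
        assert time_to_threshold(traj, "x", 0.5) is None

    def test_hospital_reaches_threshold_before_patient(self, baseline):
        traj = integrate(MixedState(0.45, 0.35, 0.4), baseline)
        t_y = time_to_threshold(traj, "y", 0.99)
        t_z = time_to_threshold(traj, "z", 0.99)
        assert t_y is not None and t_z is not None
        assert t_y < t_z

    def test_nondecreasing_in_threshold_on_monotone_trajectory(self, baseline):
        traj = integrate(MixedState(0.45, 0.35, 0.4), baseline, ADAPTIVE)
        thresholds = [0.5, 0.7, 0.9, 0.99]
        times = [time_to_threshold(traj, "z", thr) for thr in thresholds]
        assert all(t is not None for t in times)
        assert all(b >= a for a, b in zip(times, times[1:]))

    def test_linear_interpolation_between_samples(self):
        times = np.array([0.0, 1.0])
        states = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        traj = Trajectory(times, states, IntegratorConfig(step=1.0, t_end=1.0))
        assert time_to_threshold(traj, "x", 0.25) == pytest.approx(0.25)

    def test_threshold_domain_checked(self, baseline):
        traj = integrate(MixedState(0.45, 0.35, 0.4), baseline)
        with pytest.raises(ValueError):
            time_to_threshold(traj, "x", 1.5)


class TestNudgeAndIO:
    def test_nudge_moves_only_boundary_coordinates(self):
        nudged = nudge_interior(MixedState(0.0, 0.8, 1.0), 1e-6)
        assert nudged.as_tuple() == (1e-6, 0.8, 1 - 1e-6)

    def test_trajectory_csv_round_trip(self, baseline, tmp_path):
        traj = integrate(MixedState(0.45, 0.35, 0.4), baseline)
        path = tmp_path / "traj.csv"
        write_trajectory_csv(traj, path)
        back = read_trajectory_csv(path, traj.config)
        assert np.array_equal(back.times, traj.times)
        assert np.array_equal(back.states, traj.states)
        assert path.read_text().splitlines()[0] == "t,x,y,z"
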