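import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catloop import (
    DerivedScales,
    InitialState,
    InvalidStateError,
    ModelParameters,
    integrate,
    rhs,
    steady_state_check,
)
from catloop.model_core import DegenerateScaleError

from oracles import rk4_trajectory


class TestRhs:
    def test_hand_substitution(self):
        """dA, dY, dC at (1, 1, 0.1) match direct substitution into the equations."""
        params = ModelParameters(v_Y=0.5)
        init = InitialState(alpha_cat_init=0.1)
        scales = DerivedScales.from_run(params, init)
        dA, dY, dC = rhs((1.0, 1.0, 0.1), params, scales)
        e1 = 1.0 - math.exp(-1.0)
        assert dA == pytest.approx(-0.1 - 0.5 * e1, abs=1e-15)
        assert dY == pytest.approx(-0.1 + 1.2 * e1 * 0.75, abs=1e-15)
        assert dC == pytest.approx(3.0 * 0.1 * 0.5 * e1 * (2.0 / 3.0) * 0.1, abs=1e-15)

    def test_zero_y_zero_c(self):
        """With Y = C = 0 only the primary depletion acts on A."""
        params = ModelParameters(v_Y=0.5)
        scales = DerivedScales.from_run(params, InitialState(alpha_cat_init=0.0))
        dA, dY, dC = rhs((1.0, 0.0, 0.0), params, scales)
        assert dA == pytest.approx(-params.c)
        assert dY == 0.0
        assert dC == 0.0

    def test_extinguished_autophagy(self):
        """With A = 0, only α-catenin sequestration moves Y (downward)."""
        params = ModelParameters()
        scales = DerivedScales.from_run(params, InitialState(alpha_cat_init=0.5))
        dA, dY, dC = rhs((0.0, 1.0, 0.5), params, scales)
        assert dA == 0.0
        assert dC == 0.0
        assert dY == pytest.approx(-params.r1 * 0.5 * 1.0)
        assert dY < 0

    def test_invalid_and_degenerate_states(self):
        params = ModelParameters()
        scales = DerivedScales.from_run(params, InitialState(alpha_cat_init=0.5))
        with pytest.raises(InvalidStateError):
            rhs((math.nan, 1.0, 0.1), params, scales)
        with pytest.raises(InvalidStateError):
            rhs((-0.1, 1.0, 0.1), params, scales)
        zero_scales = DerivedScales(v_C=0.0, C_max=0.0, Y_max=4.0)
        with pytest.raises(DegenerateScaleError):
            rhs((1.0, 1.0, 0.2), params, zero_scales)


class TestDerivedScales:
    def test_from_run(self):
        s = DerivedScales.from_run(ModelParameters(), InitialState(alpha_cat_init=0.4))
        assert s.v_C == pytest.approx(0.4)
        assert s.C_max == pytest.approx(1.2)
        assert s.Y_max == pytest.approx(4.0)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ModelParameters(c=-0.1)
        with pytest.raises(ValueError):
            InitialState(A_init=-1.0)


class TestIntegrate:
    def test_pure_decay_closed_form(self):
        """v_Y = 0, C(0) = 0 reduces the A equation to dA/dt = -cA."""
        traj = integrate(
            ModelParameters(v_Y=0.0),
            InitialState(alpha_cat_init=0.0),
            t_end=10.0,
            n_samples=400,
        )
        for idx in np.linspace(0, 399, 20, dtype=int):
            t = traj.times[idx]
            assert traj.A[idx] == pytest.approx(math.exp(-0.1 * t), abs=1e-7)
        assert traj.A[-1] == pytest.approx(math.exp(-1.0), abs=1e-7)

    def test_sequestration_closed_form(self):
        """A = 0 freezes C, so Y decays exponentially at rate r1*C(0)."""
        traj = integrate(
            ModelParameters(),
            InitialState(A_init=0.0, Y_init=1.0, alpha_cat_init=0.5),
            t_end=10.0,
            n_samples=200,
        )
        for idx in (0, 50, 120, 199):
            t = traj.times[idx]
            assert traj.Y[idx] == pytest.approx(math.exp(-0.5 * t), abs=1e-7)

    def test_matches_rk4_oracle_at_reference_point(self):
        params = ModelParameters(v_Y=0.5)
        init = InitialState(alpha_cat_init=0.3)
        traj = integrate(params, init, t_end=3.0, n_samples=301)
        oracle = rk4_trajectory(params, init, t_end=3.0, step=1e-4,
                                sample_times=np.array([3.0]))
        assert traj.Y[-1] == pytest.approx(oracle["Y"][0], abs=1e-6)

    def test_matches_rk4_oracle_random_draws(self, rng):
        """Adaptive solution within 1e-6 sup-norm of fixed-step RK4 on [0, 10]."""
        check_times = np.linspace(0.0, 10.0, 21)
        for _ in range(10):
            params = ModelParameters(
                c=rng.uniform(0.05, 0.2),
                r1=rng.uniform(0.5, 1.5),
                r2=rng.uniform(0.8, 1.6),
                r3=rng.uniform(1.0, 4.0),
                v_Y=rng.uniform(0.1, 1.0),
            )
            init = InitialState(
                A_init=rng.uniform(0.5, 1.5),
                Y_init=rng.uniform(0.5, 1.5),
                alpha_cat_init=rng.uniform(0.05, 1.0),
            )
            traj = integrate(params, init, t_end=10.0, n_samples=401)
            oracle = rk4_trajectory(params, init, t_end=10.0, step=1e-3,
                                    sample_times=check_times)
            for name in ("A", "Y", "C"):
                ours = np.interp(check_times, traj.times, getattr(traj, name))
                assert np.max(np.abs(ours - oracle[name])) < 1e-6

    def test_input_validation(self):
        with pytest.raises(ValueError):
            integrate(t_end=0.0)
        with pytest.raises(ValueError):
            integrate(n_samples=1)

    def test_long_horizon_yap_extinction(self):
        """With α-catenin present and feedback on, Y eventually decays to ~0."""
        traj = integrate(
            ModelParameters(v_Y=0.5),
            InitialState(alpha_cat_init=0.1),
            t_end=200.0,
            n_samples=400,
        )
        assert traj.Y[-1] < 1e-2
        assert traj.Y[-1] < 0.01 * np.max(traj.Y)


class TestTrajectoryInvariants:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        v_Y=st.floats(0.1, 1.0),
        alpha=st.floats(0.05, 1.0),
        a0=st.floats(0.1, 2.0),
        y0=st.floats(0.1, 2.0),
    )
    def test_positivity_and_monotonicity(self, v_Y, alpha, a0, y0):
        """All components stay non-negative; A strictly decreases; C is
        non-decreasing and capped by C_max; Y is capped by Y_max."""
        params = ModelParameters(v_Y=v_Y)
        init = InitialState(A_init=a0, Y_init=y0, alpha_cat_init=alpha)
        traj = integrate(params, init, t_end=10.0, n_samples=200)
        assert np.all(traj.A >= 0) and np.all(traj.Y >= 0) and np.all(traj.C >= 0)
        assert np.all(np.diff(traj.A) < 0)
        assert np.all(np.diff(traj.C) >= -1e-10)
        assert np.all(traj.C <= params.k_C * alpha * (1 + 1e-9))
        assert np.all(traj.Y <= params.k_Y * y0 * (1 + 1e-9))

    def test_csv_round_trip(self, low_alpha_traj, tmp_path):
        import json

        path = low_alpha_traj.to_csv(tmp_path / "traj.csv")
        header, first = path.read_text().splitlines()[:2]
        assert header == "t,A,Y,C"
        assert len(first.split(",")) == 4
        sidecar = json.loads((tmp_path / "traj.json").read_text())
        assert sidecar["params"]["v_Y"] == 0.5
        assert sidecar["init"]["alpha_cat_init"] == 0.1


class TestSteadyStateCheck:
    def test_decayed_autophagy(self):
        traj = integrate(
            ModelParameters(v_Y=0.0), InitialState(alpha_cat_init=0.0),
            t_end=100.0, n_samples=400,
        )
        report = steady_state_check(traj, epsilon=1e-4)
        assert report.autophagy_decayed

    def test_insufficient_samples_flag(self):
        traj = integrate(t_end=1.0, n_samples=2)
        assert steady_state_check(traj).insufficient_samples

    def test_terminal_decline_low_alpha(self, low_alpha_traj):
        """After the Y peak the terminal phase has dY < 0."""
        report = steady_state_check(low_alpha_traj)
        assert report.terminal_dY_sign == -1
        assert report.terminal_monotone
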