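import numpy as np
import pytest

from catloop import (
    InitialState,
    ModelParameters,
    Trajectory,
    classify_direction,
    find_flip_boundary,
    integrate,
    windowed_correlation,
    yap_peak_time,
)
from catloop.response import DEFAULT_HORIZON, UndefinedCorrelationError


def _traj(alpha, v_Y=0.5, t_end=DEFAULT_HORIZON, **params):
    return integrate(
        ModelParameters(v_Y=v_Y, **params),
        InitialState(alpha_cat_init=alpha),
        t_end=t_end,
        n_samples=400,
    )


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(0.8, "decrease"), (0.6, "decrease"), (0.1, "increase"), (0.2, "increase")],
    )
    def test_regime_labels(self, alpha, expected):
        """High basal α-catenin flips the YAP/TAZ response to a decrease,
        low basal α-catenin to an increase."""
        assert classify_direction(_traj(alpha)).label == expected

    def test_frozen_y_is_unchanged(self):
        traj = _traj(0.5, r1=0.0, r2=0.0)
        assert classify_direction(traj).label == "unchanged"

    def test_horizon_outside_span_raises(self):
        with pytest.raises(ValueError):
            classify_direction(_traj(0.5, t_end=2.0), T=5.0)


class TestFlipBoundary:
    def test_boundary_in_published_band(self):
        """The direction flip sits between the published regime thresholds
        0.3 (below: increase) and 0.5 (above: decrease)."""
        b = find_flip_boundary()
        assert b is not None
        assert 0.3 < b < 0.5

    def test_bisection_matches_brute_force_scan(self):
        b = find_flip_boundary(tol=1e-4)
        grid = np.arange(0.05, 1.0, 1e-3)
        excess = []
        for alpha in grid:
            traj = integrate(
                ModelParameters(v_Y=0.5),
                InitialState(alpha_cat_init=float(alpha)),
                t_end=DEFAULT_HORIZON,
                n_samples=200,
            )
            excess.append(float(traj.Y[-1]) - 1.0)
        excess = np.asarray(excess)
        sign_flip = np.where(np.diff(np.sign(excess)) < 0)[0]
        assert len(sign_flip) == 1
        brute = float(grid[sign_flip[0]])
        assert abs(b - brute) < 2e-3

    def test_boundary_brackets_direction_flip(self):
        b = find_flip_boundary()
        assert classify_direction(_traj(b - 0.01)).label == "increase"
        assert classify_direction(_traj(b + 0.01)).label == "decrease"

    def test_no_sequestration_gives_none(self):
        """With r1 = 0 the Y equation only grows: no flip exists."""
        assert find_flip_boundary(ModelParameters(r1=0.0)) is None


class TestYapPeakTime:
    def test_high_alpha_peaks_at_zero(self, high_alpha_traj):
        assert yap_peak_time(high_alpha_traj) == 0.0

    def test_low_alpha_interior_peak_matches_sign_change(self, low_alpha_traj):
        t_peak = yap_peak_time(low_alpha_traj)
        assert 0.0 < t_peak < low_alpha_traj.times[-1]
        dY = np.diff(low_alpha_traj.Y)
        flip = np.where(np.sign(dY[:-1]) > np.sign(dY[1:]))[0]
        assert low_alpha_traj.times[flip[0] + 1] == pytest.approx(
            t_peak, abs=float(np.diff(low_alpha_traj.times)[0])
        )

    def test_peak_time_stable_under_refinement(self):
        coarse = integrate(
            ModelParameters(v_Y=0.5), InitialState(alpha_cat_init=0.1),
            t_end=10.0, n_samples=400,
        )
        fine = integrate(
            ModelParameters(v_Y=0.5), InitialState(alpha_cat_init=0.1),
            t_end=10.0, n_samples=800,
        )
        step = float(np.diff(coarse.times)[0])
        assert abs(yap_peak_time(coarse) - yap_peak_time(fine)) <= step


class TestWindowedCorrelation:
    def test_low_alpha_biphasic_correlations(self, low_alpha_traj):
        """Early window: Y rises as A falls (R <= −0.5); late window: both
        fall together (R >= 0.5)."""
        res = windowed_correlation(low_alpha_traj)
        assert res.interior_peak
        assert res.R_early <= -0.5
        assert res.R_late >= 0.5
        assert res.n_early >= 10 and res.n_late >= 10

    def test_perfect_anticorrelation(self):
        times = np.linspace(0, 1, 50)
        A = np.linspace(1.0, 0.2, 50)
        traj = Trajectory(times=times, A=A, Y=2.0 - A, C=np.zeros(50))
        res = windowed_correlation(traj)
        # Y peaks at the last sample -> only the early window is defined
        assert res.R_early == pytest.approx(-1.0)
        assert res.R_late is None

    def test_constant_y_raises(self):
        times = np.linspace(0, 1, 50)
        traj = Trajectory(
            times=times, A=np.linspace(1, 0.5, 50), Y=np.ones(50), C=np.zeros(50)
        )
        with pytest.raises(UndefinedCorrelationError):
            windowed_correlation(traj)

    def test_high_alpha_full_trajectory_positive_correlation(self):
        """In the high-α-catenin regime Y and A co-decrease over [0, T]: the
        full-window correlation is positive at any experimental horizon."""
        for alpha in (0.8, 1.0):
            traj = integrate(
                ModelParameters(v_Y=0.5), InitialState(alpha_cat_init=alpha),
                t_end=DEFAULT_HORIZON, n_samples=200,
            )
            assert np.all(np.diff(traj.Y) <= 1e-12)
            r = float(np.corrcoef(traj.Y, traj.A)[0, 1])
            assert r > 0.5

    def test_initial_slope_sign_matches_rhs(self):
        """Sign of the first finite difference of Y equals the sign of dY/dt
        at t = 0 from the right-hand side."""
        from catloop import DerivedScales, rhs

        for alpha in (0.1, 0.8):
            params = ModelParameters(v_Y=0.5)
            init = InitialState(alpha_cat_init=alpha)
            traj = integrate(params, init, t_end=1.0, n_samples=400)
            _, dY0, _ = rhs(
                (init.A_init, init.Y_init, alpha),
                params,
                DerivedScales.from_run(params, init),
            )
            assert np.sign(traj.Y[1] - traj.Y[0]) == np.sign(dY0)
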