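import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gema.control import (
    ControllerState,
    CVPoint,
    coefficient_of_variation,
    fit_regression,
    schedule_threshold,
    update_controller,
)
from gema.errors import DegenerateFitError, OrderingError, UndefinedCVError

from .oracles import ols_grid_search


class TestCoefficientOfVariation:
    def test_constant_image_is_zero(self):
        assert coefficient_of_variation(np.full((10, 10), 42)) == 0.0

    def test_known_multiset(self):
        """{2,4,4,4,5,5,7,9}: μ=5, population σ=2, CV=0.4."""
        img = np.array([[2, 4, 4, 4], [5, 5, 7, 9]])
        assert coefficient_of_variation(img) == pytest.approx(0.4, abs=1e-12)

    def test_scale_invariance(self, rng):
        img = rng.integers(1, 100, (16, 16)).astype(float)
        cv = coefficient_of_variation(img)
        for a in (0.5, 2.0, 13.7):
            assert coefficient_of_variation(a * img) == pytest.approx(cv, rel=1e-12)

    def test_zero_mean_raises(self):
        with pytest.raises(UndefinedCVError):
            coefficient_of_variation(np.zeros((4, 4)))

    def test_strictly_positive_unless_constant(self, rng):
        img = rng.integers(0, 256, (8, 8))
        if img.max() > img.min():
            assert coefficient_of_variation(img) > 0


class TestFitRegression:
    def test_exact_line_recovered_with_zero_error(self):
        pts = [CVPoint(0, 1.0), CVPoint(1, 3.0), CVPoint(2, 5.0)]
        model = fit_regression(pts)
        assert model.m == pytest.approx(2.0, abs=1e-12)
        assert model.b == pytest.approx(1.0, abs=1e-12)
        assert model.fit_error == pytest.approx(0.0, abs=1e-12)

    def test_hand_derived_normal_equations(self):
        """(0,0),(1,1),(2,0): Sxy = 0 so m = 0 and b = mean(y) = 1/3."""
        model = fit_regression([CVPoint(0, 0.0), CVPoint(1, 1.0), CVPoint(2, 0.0)])
        assert model.m == pytest.approx(0.0, abs=1e-12)
        assert model.b == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_single_point_and_repeated_x_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_regression([CVPoint(0, 1.0)])
        with pytest.raises(DegenerateFitError):
            fit_regression([CVPoint(3, 1.0), CVPoint(3, 2.0)])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_grid_search_oracle_on_small_sets(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 6))
        xs = np.sort(r.choice(np.arange(10), size=n, replace=False))
        ys = r.uniform(0.1, 5.0, n)
        model = fit_regression([CVPoint(int(x), float(y)) for x, y in zip(xs, ys)])
        m_o, b_o = ols_grid_search(xs, ys)
        assert model.m == pytest.approx(m_o, abs=1e-3)
        assert model.b == pytest.approx(b_o, abs=1e-3)

    def test_noisy_parameter_recovery(self):
        """m, b recovered within 5% in ≥95/100 seeded replicates (noise sd 1% of b)."""
        m_true, b_true = 0.002, 0.25
        good = 0
        for rep in range(100):
            r = np.random.default_rng(1000 + rep)
            xs = np.arange(200)
            ys = m_true * xs + b_true + r.normal(0, 0.01 * abs(b_true), 200)
            model = fit_regression([CVPoint(int(x), float(y)) for x, y in zip(xs, ys)])
            if abs(model.m - m_true) <= 0.05 * abs(m_true) and abs(
                model.b - b_true
            ) <= 0.05 * abs(b_true):
                good += 1
        assert good >= 95


class TestScheduleThreshold:
    @staticmethod
    def _state(mode, cv_min=0.1, cv_max=0.3):
        return ControllerState(mode=mode, cv_min=cv_min, cv_max=cv_max)

    def test_growth_low_cv_maps_to_confluence_threshold_5(self):
        assert schedule_threshold(self._state("growth"), 0.1) == 5

    def test_growth_high_cv_maps_to_11(self):
        assert schedule_threshold(self._state("growth"), 0.3) == 11

    def test_apoptosis_low_cv_maps_to_11(self):
        assert schedule_threshold(self._state("apoptosis"), 0.1) == 11

    def test_apoptosis_high_cv_maps_to_5(self):
        assert schedule_threshold(self._state("apoptosis"), 0.3) == 5

    def test_growth_midpoint_maps_to_8(self):
        assert schedule_threshold(self._state("growth"), 0.2) == 8

    def test_clamped_outside_calibration(self):
        assert schedule_threshold(self._state("growth"), -1.0) == 5
        assert schedule_threshold(self._state("growth"), 99.0) == 11

    def test_uncalibrated_returns_mode_endpoint(self):
        assert schedule_threshold(ControllerState(mode="growth"), 0.2) == 11
        assert schedule_threshold(ControllerState(mode="apoptosis"), 0.2) == 5

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    def test_monotone_in_predicted_cv(self, cvs):
        state = self._state("growth", 0.05, 0.95)
        cvs = sorted(cvs)
        ts = [schedule_threshold(state, cv) for cv in cvs]
        assert all(t2 >= t1 for t1, t2 in zip(ts, ts[1:]))
        assert all(5 <= t <= 11 for t in ts)
        state_a = self._state("apoptosis", 0.05, 0.95)
        ts_a = [schedule_threshold(state_a, cv) for cv in cvs]
        assert all(t2 <= t1 for t1, t2 in zip(ts_a, ts_a[1:]))


class TestUpdateController:
    def test_cold_start_uses_mode_endpoint(self):
        state = ControllerState(mode="growth")
        state = update_controller(state, CVPoint(0, 0.2))
        assert state.model is None
        assert state.current_threshold == 11

    def test_points_on_a_line_fit_once_and_never_refit(self):
        state = ControllerState(mode="growth")
        for x in range(30):
            state = update_controller(state, CVPoint(x, 0.1 + 0.004 * x))
        # a single fit at x=1 covered the whole line; no refit ever triggered
        assert state.last_refit_at == 2
        assert state.model.m == pytest.approx(0.004, rel=1e-6)
        assert state.model.b == pytest.approx(0.1, rel=1e-6)

    def test_level_shift_triggers_refit_within_two_frames(self):
        state = ControllerState(mode="growth")
        for x in range(20):
            state = update_controller(state, CVPoint(x, 0.2))
        fit_before = state.last_refit_at
        # CV doubles at frame 20
        state = update_controller(state, CVPoint(20, 0.4))
        state = update_controller(state, CVPoint(21, 0.4))
        assert state.last_refit_at > fit_before

    def test_thresholds_always_integers_in_range(self):
        state = ControllerState(mode="growth")
        r = np.random.default_rng(0)
        for x in range(50):
            state = update_controller(state, CVPoint(x, float(r.uniform(0.05, 0.4))))
            assert state.current_threshold in range(5, 12)

    def test_out_of_order_frame_rejected(self):
        state = ControllerState(mode="growth")
        state = update_controller(state, CVPoint(5, 0.2))
        with pytest.raises(OrderingError):
            update_controller(state, CVPoint(5, 0.3))

    def test_update_is_functional_not_in_place(self):
        state0 = ControllerState(mode="growth")
        state1 = update_controller(state0, CVPoint(0, 0.2))
        assert state0.history == ()
        assert len(state1.history) == 1
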