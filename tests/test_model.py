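import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from fsrcop.geometry import Sensor, SensorLayout
from fsrcop.model import (
    ZeroLoadError,
    build_design_matrix,
    fit_cop_model,
    initial_coefficients,
    predict_cop,
    training_gradient,
    weighted_mean_cop,
)
from fsrcop.recording import CopTrajectory


def make_layout(xs, ys):
    return SensorLayout(
        sensors=tuple(
            Sensor(sensor_id=i + 1, x=float(x), y=float(y))
            for i, (x, y) in enumerate(zip(xs, ys))
        )
    )


def normal_equation_oracle(forces, target):
    """Independent 12-column normal-equation solve (drops the rank-deficient
    total-force column); used only to cross-check predictions."""
    f = np.asarray(forces, dtype=float)
    c = np.linalg.solve(f.T @ f, f.T @ target)
    return f @ c


forces_strategy = hnp.arrays(
    np.float64,
    st.tuples(st.integers(3, 40), st.just(12)),
    elements=st.floats(0.0, 100.0),
)


class TestWeightedMean:
    def test_point_load_returns_sensor_coordinate(self, layout):
        forces = np.zeros((1, 12))
        forces[0, 4] = 37.0  # all load on sensor 5
        traj = weighted_mean_cop(forces, layout)
        assert (traj.x[0], traj.y[0]) == tuple(layout.coords[4])

    def test_equal_loads_give_midpoint(self):
        lay = make_layout(
            [30, 60] + [5 * i for i in range(2, 12)],
            [50, 250] + [10 * i for i in range(2, 12)],
        )
        forces = np.zeros((1, 12))
        forces[0, 0] = forces[0, 1] = 3.0
        traj = weighted_mean_cop(forces, lay)
        assert traj.x[0] == pytest.approx(45.0)
        assert traj.y[0] == pytest.approx(150.0)

    def test_three_point_centroid(self):
        lay = make_layout([0, 10, 20] + [30] * 9, list(range(10, 130, 10)))
        forces = np.zeros((1, 12))
        forces[0, :3] = [1.0, 2.0, 3.0]
        traj = weighted_mean_cop(forces, lay)
        assert traj.x[0] == pytest.approx(80.0 / 6.0)

    def test_zero_load_frame_identified(self, layout):
        forces = np.ones((3, 12))
        forces[1] = 0.0
        with pytest.raises(ZeroLoadError, match="frame 1"):
            weighted_mean_cop(forces, layout)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(forces=forces_strategy)
    def test_cop_in_sensor_bounding_box(self, layout, forces):
        forces = forces + 1e-6  # keep every frame loaded
        traj = weighted_mean_cop(forces, layout)
        assert (traj.x >= layout.x.min() - 1e-9).all()
        assert (traj.x <= layout.x.max() + 1e-9).all()
        assert (traj.y >= layout.y.min() - 1e-9).all()
        assert (traj.y <= layout.y.max() + 1e-9).all()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(forces=forces_strategy, scale=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, layout, forces, scale):
        forces = forces + 1.0
        a = weighted_mean_cop(forces, layout)
        b = weighted_mean_cop(forces * scale, layout)
        assert np.allclose(a.x, b.x, rtol=1e-10)
        assert np.allclose(a.y, b.y, rtol=1e-10)

    def test_translation_equivariance(self, layout, rng):
        forces = rng.uniform(0.1, 50, (30, 12))
        shifted = make_layout(layout.x + 7.0, layout.y + 11.0)
        a = weighted_mean_cop(forces, layout)
        b = weighted_mean_cop(forces, shifted)
        assert np.allclose(b.x - a.x, 7.0)
        assert np.allclose(b.y - a.y, 11.0)


class TestDesignMatrix:
    def test_single_unit_frame(self):
        f = build_design_matrix(np.ones((1, 12)))
        assert f.shape == (1, 13)
        assert np.array_equal(f[0], np.r_[np.ones(12), 12.0])

    def test_last_column_is_exact_row_sum(self, rng):
        forces = rng.uniform(0, 80, (50, 12))
        f = build_design_matrix(forces)
        assert np.array_equal(f[:, 12], forces.sum(axis=1))

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix(np.empty((0, 12)))


class TestFit:
    def test_recovers_noise_free_linear_data(self, rng):
        forces = rng.uniform(0, 60, (200, 12))
        f = build_design_matrix(forces)
        c_true_x, c_true_y = rng.normal(0, 1, 13), rng.normal(0, 1, 13)
        ref = CopTrajectory(np.arange(200.0), f @ c_true_x, f @ c_true_y)
        model = fit_cop_model(forces, ref)
        pred = predict_cop(model, forces)
        assert np.allclose(pred.x, ref.x, atol=1e-9)
        assert np.allclose(pred.y, ref.y, atol=1e-9)

    def test_constant_target_with_constant_total_force(self, rng):
        # constant F_tot puts a constant target in the predictor span
        raw = rng.uniform(1, 10, (50, 12))
        forces = raw / raw.sum(axis=1, keepdims=True) * 300.0
        ref = CopTrajectory(np.arange(50.0), np.full(50, 45.0), np.full(50, 190.0))
        model = fit_cop_model(forces, ref)
        assert np.sqrt(model.training_sse[0] / 50) < 1e-9
        assert np.sqrt(model.training_sse[1] / 50) < 1e-9

    def test_two_frames_interpolated_exactly(self, rng):
        forces = rng.uniform(1, 50, (2, 12))
        ref = CopTrajectory(np.arange(2.0), np.array([40.0, 52.0]), np.array([180.0, 210.0]))
        model = fit_cop_model(forces, ref)
        pred = predict_cop(model, forces)
        assert np.allclose(pred.x, ref.x, atol=1e-9)
        assert np.allclose(pred.y, ref.y, atol=1e-9)

    def test_stationarity_of_normal_equations(self, rng):
        forces = rng.uniform(0, 60, (300, 12))
        f = build_design_matrix(forces)
        ref = CopTrajectory(
            np.arange(300.0),
            f @ rng.normal(0, 1, 13) + rng.normal(0, 2, 300),
            f @ rng.normal(0, 1, 13) + rng.normal(0, 2, 300),
        )
        model = fit_cop_model(forces, ref)
        scale = np.abs(f).sum(axis=0).max() * max(
            np.abs(ref.x).max(), np.abs(ref.y).max()
        )
        assert training_gradient(model, forces, ref) <= 1e-6 * scale

    def test_predictions_match_normal_equation_oracle(self, rng):
        forces = rng.uniform(0.5, 60, (150, 12))
        target = forces @ rng.normal(0, 1, 12) + rng.normal(0, 1, 150)
        ref = CopTrajectory(np.arange(150.0), target, target)
        model = fit_cop_model(forces, ref)
        pred = predict_cop(model, forces)
        oracle = normal_equation_oracle(forces, target)
        assert np.allclose(pred.x, oracle, atol=1e-8)

    def test_perturbed_coefficients_never_beat_the_fit(self, rng):
        forces = rng.uniform(0, 60, (120, 12))
        f = build_design_matrix(forces)
        ref_x = f @ rng.normal(0, 1, 13) + rng.normal(0, 1, 120)
        ref = CopTrajectory(np.arange(120.0), ref_x, ref_x)
        model = fit_cop_model(forces, ref)
        sse0 = model.training_sse[0]
        scale = np.linalg.norm(model.cx)
        for _ in range(200):
            c = model.cx + rng.normal(0, 1e-3 * scale, 13)
            sse = float(np.sum((f @ c - ref.x) ** 2))
            assert sse >= sse0 * (1 - 1e-9)

    @pytest.mark.parametrize("delta", [1.0, -1.0, 100.0, -100.0])
    def test_gauge_direction_changes_no_prediction(self, rng, delta):
        forces = rng.uniform(0, 60, (80, 12))
        f = build_design_matrix(forces)
        ref_x = f @ rng.normal(0, 1, 13)
        ref = CopTrajectory(np.arange(80.0), ref_x, ref_x)
        model = fit_cop_model(forces, ref)
        base = predict_cop(model, forces)
        model.cx = model.cx + np.r_[np.full(12, -delta), delta]
        model.cy = model.cy + np.r_[np.full(12, -delta), delta]
        shifted = predict_cop(model, forces)
        assert np.allclose(shifted.x, base.x, atol=1e-8)
        assert np.allclose(shifted.y, base.y, atol=1e-8)

    def test_error_cases(self, rng):
        forces = rng.uniform(0, 10, (5, 12))
        ref = CopTrajectory(np.arange(4.0), np.ones(4), np.ones(4))
        with pytest.raises(ValueError, match="does not match"):
            fit_cop_model(forces, ref)
        ref5 = CopTrajectory(np.arange(5.0), np.ones(5), np.ones(5))
        with pytest.raises(ValueError, match="all-zero"):
            fit_cop_model(np.zeros((5, 12)), ref5)
        bad = forces.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_cop_model(bad, ref5)


class TestNormalizedVariant:
    def test_prediction_is_scale_invariant(self, rng):
        forces = rng.uniform(0.5, 40, (60, 12))
        ref = CopTrajectory(
            np.arange(60.0), rng.uniform(30, 60, 60), rng.uniform(150, 220, 60)
        )
        model = fit_cop_model(forces, ref, variant="normalized")
        a = predict_cop(model, forces)
        b = predict_cop(model, forces * 3.7)
        assert np.allclose(a.x, b.x, rtol=1e-10)
        assert np.allclose(a.y, b.y, rtol=1e-10)

    def test_zero_load_frame_rejected(self, rng):
        forces = rng.uniform(0.5, 40, (10, 12))
        forces[3] = 0.0
        ref = CopTrajectory(np.arange(10.0), np.ones(10), np.ones(10))
        with pytest.raises(ZeroLoadError, match="frame 3"):
            fit_cop_model(forces, ref, variant="normalized")


class TestPredictAndInit:
    def test_zero_coefficients_predict_origin(self, layout, rng):
        forces = rng.uniform(0, 10, (7, 12))
        ref = CopTrajectory(np.arange(7.0), np.zeros(7), np.zeros(7))
        model = fit_cop_model(forces, ref)
        model.cx[:] = 0.0
        model.cy[:] = 0.0
        pred = predict_cop(model, forces)
        assert np.array_equal(pred.x, np.zeros(7))
        assert np.array_equal(pred.y, np.zeros(7))

    def test_single_sensor_coefficient(self, rng):
        forces = np.zeros((1, 12))
        forces[0, 0] = 7.0
        ref = CopTrajectory(np.zeros(1), np.zeros(1), np.zeros(1))
        model = fit_cop_model(np.ones((2, 12)), CopTrajectory(np.arange(2.0), np.zeros(2), np.zeros(2)))
        model.cx = np.r_[1.0, np.zeros(12)]
        pred = predict_cop(model, forces)
        assert pred.x[0] == pytest.approx(7.0)

    def test_initial_coefficients_seeded_from_layout(self, layout):
        cx0, cy0 = initial_coefficients(layout)
        assert cx0.shape == cy0.shape == (13,)
        assert np.array_equal(cx0[:12], layout.x)
        assert np.array_equal(cy0[:12], layout.y)
        assert cx0[12] == 0.0 and cy0[12] == 0.0

    def test_fit_records_initial_coefficients(self, layout, rng):
        forces = rng.uniform(0, 10, (20, 12))
        ref = CopTrajectory(np.arange(20.0), np.ones(20), np.ones(20))
        model = fit_cop_model(forces, ref, layout=layout)
        assert np.array_equal(model.initial_cx[:12], layout.x)
        assert model.layout_ref is not None
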