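"""Reservoir construction, invariant training sets, closed-form ridge
readout, prediction and hyperparameter tuning."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

from curvetrace import elm
from curvetrace.curves import affine_transform, make_named_curve
from curvetrace.kinematics import Trace, reparameterize_trace
from .conftest import random_rigid_motion


@pytest.fixture(scope="module")
def reservoir():
    return elm.make_reservoir(seed=0)


@pytest.fixture(scope="module")
def training(styled_demo, figure_eight, styled_projections):
    return elm.build_training_set(styled_demo, figure_eight, styled_projections)


class TestReservoir:
    def test_seeded_reproducibility(self):
        a = elm.make_reservoir(seed=3)
        b = elm.make_reservoir(seed=3)
        assert np.array_equal(a.C, b.C)
        assert (a.zeta == 0).all()

    def test_sampling_laws(self):
        uni = elm.make_reservoir(seed=1, n_x=5000)
        assert np.abs(uni.C).max() <= 1.0
        disc = elm.make_reservoir(seed=1, law="sign")
        assert set(np.unique(disc.C)) == {-1.0, 1.0}

    def test_unknown_law(self):
        with pytest.raises(ValueError):
            elm.make_reservoir(law="gaussian")


class TestTrainingSet:
    def test_standardized_rows(self, training):
        assert np.abs(training.Z.mean(axis=1)).max() < 1e-10
        assert np.abs(training.Z.std(axis=1) - 1).max() < 1e-10
        assert np.abs(training.Y.mean(axis=1)).max() < 1e-10

    def test_raw_inputs_bounded(self, training):
        # e small, |mu|/50 < 1 (figure-eight max curvature ~48/m),
        # wrapped p/10 < 0.63
        assert np.abs(training.Z_raw[0]).max() < 0.05
        assert np.abs(training.Z_raw[1]).max() <= 1.0
        assert training.Z_raw[2].min() >= 0.0
        assert training.Z_raw[2].max() <= 2 * np.pi / 10.0 + 1e-12

    def test_curvature_modes_differ_on_reparameterized_curve(self):
        fast = make_named_curve("speed_scaled_eight", n=2)
        from curvetrace.demonstrations import DemonstratorProfile, simulate_demonstration

        profile = DemonstratorProfile(
            lateral_noise_sd=0.0, speed_noise_sd=0.0, style_amplitude=0.0,
            n_loops=2, seed=4,
        )
        demo = simulate_demonstration(fast, profile)
        projs = reparameterize_trace(demo, fast, 0.0)
        arc = elm.build_training_set(demo, fast, projs, "arc_length")
        par = elm.build_training_set(demo, fast, projs, "parameter")
        # <c_pp, n> = mu * |c_p|^2: n=2 scales it by 4 at matched points
        ratio = par.Z_raw[1] / arc.Z_raw[1]
        cp = fast.first_derivative(np.array([p.p_star for p in projs]))
        expected = (cp**2).sum(axis=1)
        assert np.abs(ratio - expected).max() < 1e-6

    def test_requires_velocities(self, figure_eight):
        trace = Trace(dt=0.01, positions=np.zeros((10, 2)))
        with pytest.raises(ValueError):
            elm.build_training_set(trace, figure_eight, [None] * 10)


class TestComputeStates:
    def test_zero_input_zero_state(self, reservoir):
        X = elm.compute_states(reservoir, 1.0, np.zeros((3, 4)))
        assert (X == 0).all()

    def test_small_scaling_vanishes_and_bounded(self, reservoir):
        Z = np.random.default_rng(0).normal(size=(3, 50))
        X = elm.compute_states(reservoir, 1e-12, Z)
        assert np.abs(X).max() < 1e-10
        # tanh is bounded; float rounding saturates to exactly 1 at huge c
        assert np.abs(elm.compute_states(reservoir, 2.0, Z)).max() < 1.0
        assert np.abs(elm.compute_states(reservoir, 100.0, Z)).max() <= 1.0

    def test_dimension_mismatch(self, reservoir):
        with pytest.raises(ValueError):
            elm.compute_states(reservoir, 1.0, np.zeros((4, 5)))


class TestTrainReadout:
    def test_recovers_exact_linear_map(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 300))
        W0 = rng.normal(size=(2, 8))
        b0 = rng.normal(size=2)
        ro = elm.train_readout(X, W0 @ X + b0[:, None], 1e-12)
        assert np.abs(ro.W - W0).max() < 1e-6
        assert np.abs(ro.b - b0).max() < 1e-6

    def test_infinite_ridge_limit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 100))
        Y = rng.normal(size=(2, 100))
        ro = elm.train_readout(X, Y, 1e12)
        assert np.abs(ro.W).max() < 1e-8
        assert np.allclose(ro.b, Y.mean(axis=1))

    @pytest.mark.parametrize("lam", [1e-6, 1e-3, 1.0])
    def test_matches_sklearn_ridge_oracle(self, lam):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 20))
        Y = rng.normal(size=(2, 20))
        ro = elm.train_readout(X, Y, lam)
        oracle = Ridge(alpha=lam, fit_intercept=True).fit(X.T, Y.T)
        assert np.abs(ro.W - oracle.coef_).max() < 1e-10
        assert np.abs(ro.b - oracle.intercept_).max() < 1e-10

    def test_training_error_weakly_decreasing_in_lambda(self, reservoir, training):
        X = elm.compute_states(reservoir, 2.0, training.Z)
        errs = [
            elm.train_readout(X, training.Y, lam).training_mse
            for lam in (1e-1, 1e-3, 1e-5, 1e-7)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


class TestPredict:
    def test_zero_readout_returns_target_mean(self, reservoir, training):
        from dataclasses import replace

        model = elm.train_model(reservoir, training, 1.0, 1e-4)
        zeroed = replace(
            model,
            readout=replace(model.readout, W=np.zeros_like(model.readout.W)),
        )
        out = elm.predict(zeroed, np.array([0.0, 0.3, 0.3]))
        expected = (
            model.readout.b * model.normalizer.y_std + model.normalizer.y_mean
        )
        assert np.allclose(out, expected)

    def test_training_reproduction_matches_reported_mse(
        self, reservoir, training
    ):
        model = elm.train_model(reservoir, training, 2.0, 1e-4)
        pred = elm.predict(model, training.Z_raw)
        resid = (pred - model.normalizer.destandardize_y(training.Y)) / (
            model.normalizer.y_std[:, None]
        )
        mse = float(np.mean(np.sum(resid**2, axis=0)))
        assert mse == pytest.approx(model.readout.training_mse, rel=1e-9)

    def test_same_seed_models_identical(self, training):
        a = elm.train_model(elm.make_reservoir(5), training, 2.0, 1e-4)
        b = elm.train_model(elm.make_reservoir(5), training, 2.0, 1e-4)
        z = np.array([0.001, -0.2, 0.4])
        assert np.array_equal(elm.predict(a, z), elm.predict(b, z))


class TestEndToEndInvariance:
    def test_rigid_motion_leaves_readout_unchanged(
        self, styled_demo, figure_eight, styled_projections, reservoir
    ):
        training = elm.build_training_set(
            styled_demo, figure_eight, styled_projections
        )
        model = elm.train_model(reservoir, training, 2.0, 1e-4)
        rng = np.random.default_rng(11)
        R, d = random_rigid_motion(rng)
        moved_curve = affine_transform(figure_eight, R, d)
        moved = Trace(
            dt=styled_demo.dt,
            positions=styled_demo.positions @ R.T + d,
            velocities=styled_demo.velocities @ R.T,
        )
        projs2 = reparameterize_trace(moved, moved_curve, 0.0)
        training2 = elm.build_training_set(moved, moved_curve, projs2)
        model2 = elm.train_model(reservoir, training2, 2.0, 1e-4)
        assert np.abs(model2.readout.W - model.readout.W).max() < 1e-6
        assert np.abs(model2.readout.b - model.readout.b).max() < 1e-6


class TestTuning:
    def test_single_candidate_grid(
        self, styled_demo, figure_eight, styled_projections, reservoir
    ):
        c, lam, surf = elm.tune_hyperparameters(
            reservoir, styled_demo, figure_eight, styled_projections,
            c_grid=[2.0], lambda_grid=[1e-4],
        )
        assert (c, lam) == (2.0, 1e-4)
        assert surf.shape == (1, 1) and np.isfinite(surf).all()

    def test_selection_is_argmin_and_reproducible(
        self, styled_demo, figure_eight, styled_projections, reservoir
    ):
        grids = dict(c_grid=[1.0, 3.0], lambda_grid=[1e-4, 1e-2])
        c1, l1, s1 = elm.tune_hyperparameters(
            reservoir, styled_demo, figure_eight, styled_projections, **grids
        )
        c2, l2, s2 = elm.tune_hyperparameters(
            reservoir, styled_demo, figure_eight, styled_projections, **grids
        )
        assert np.array_equal(s1, s2) and (c1, l1) == (c2, l2)
        ic, il = np.unravel_index(np.argmin(s1), s1.shape)
        assert (grids["c_grid"][ic], grids["lambda_grid"][il]) == (c1, l1)

    def test_short_sample_rejected(self, figure_eight, reservoir, clean_demo):
        short = Trace(
            dt=clean_demo.dt,
            positions=clean_demo.positions[:150],
            velocities=clean_demo.velocities[:150],
        )
        projs = reparameterize_trace(short, figure_eight, 0.0)
        with pytest.raises(ValueError):
            elm.tune_hyperparameters(
                reservoir, short, figure_eight, projs,
                c_grid=[1.0], lambda_grid=[1e-4],
            )


class TestSerialization:
    def test_round_trip_bit_exact(self, reservoir, training, tmp_path):
        model = elm.train_model(reservoir, training, 2.0, 1e-4)
        path = tmp_path / "model.npz"
        elm.save_model(model, path)
        back = elm.load_model(path)
        assert np.array_equal(back.reservoir.C, model.reservoir.C)
        assert np.array_equal(back.readout.W, model.readout.W)
        assert np.array_equal(back.readout.b, model.readout.b)
        assert back.readout.scaling_c == model.readout.scaling_c
        assert back.curvature_mode == model.curvature_mode
        z = np.array([0.001, -0.5, 0.2])
        assert np.array_equal(elm.predict(back, z), elm.predict(model, z))
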