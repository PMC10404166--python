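"""Backprop network: gradients, scaling, LRC control, diagnostics, training."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from lipoml import ann
from lipoml.classify import ClassifierSpec, dispersity_table
from lipoml.datamodel import SynthesisParams
from lipoml.synthetic import mean_diameter


def _fitted_scaling(rng, n_inputs=3):
    X = rng.uniform(0, 10, size=(12, n_inputs))
    y = rng.uniform(40, 150, size=12)
    return ann.ScalingSpec().fit(X, y)


def _random_model(seed, sizes=(3, 4, 2, 1)):
    rng = np.random.default_rng(seed)
    sc = _fitted_scaling(rng, sizes[0])
    return ann.NetworkModel.initialize(ann.NetworkTopology(sizes), sc, seed=seed)


@pytest.fixture(scope="module")
def trained_curc_model(default_library):
    """A short-but-converged training run on the +Curc monodisperse subset."""
    lib, _ = default_library
    X, y = ann.monodisperse_diameter_dataset(lib, curcumin=True)
    cfg = ann.TrainingConfig(seed=2, max_iterations=20_000, patience=4_000)
    model, history = ann.train(X, y, config=cfg)
    return model, history, (X, y)


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------


@given(st.floats(min_value=-1e3, max_value=1e3, allow_nan=False))
def test_scaling_round_trip_identity(value):
    sc = ann.ScalingSpec().fit(np.array([[0.0], [10.0]]), np.array([-1e3, 1e3]))
    assert sc.unscale_output(sc.scale_output(value)) == pytest.approx(value, abs=1e-9, rel=1e-12)


def test_scaling_targets_sigmoid_interval(rng):
    sc = _fitted_scaling(rng)
    X = rng.uniform(0, 10, size=(50, 3))
    Xs = sc.scale_inputs(np.clip(X, sc.input_min, sc.input_max))
    assert Xs.min() >= 0.1 - 1e-12 and Xs.max() <= 0.9 + 1e-12


def test_unfitted_scaling_errors():
    with pytest.raises(RuntimeError):
        ann.ScalingSpec().scale_inputs(np.zeros((1, 3)))


def test_scaling_serialization_round_trip(rng):
    sc = _fitted_scaling(rng)
    back = ann.ScalingSpec.from_dict(sc.to_dict())
    assert np.allclose(back.scale_output(np.array([77.0])), sc.scale_output(np.array([77.0])))


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------


def test_zero_weights_output_midpoint(rng):
    sc = _fitted_scaling(rng)
    topo = ann.NetworkTopology((3, 4, 2, 1))
    model = ann.NetworkModel(topo, [np.zeros((4, 4)), np.zeros((5, 2)), np.zeros((3, 1))], sc)
    out = ann.forward(model, SynthesisParams(4, 20, 3, False))
    midpoint = 0.5 * (sc.output_min + sc.output_max)  # sigmoid(0)=0.5, mid of [0.1,0.9]
    assert out == pytest.approx(midpoint, rel=1e-12)


def test_forward_lipschitz_continuity(rng):
    """Output change is bounded by the product of layer weight norms times the
    input perturbation (sigmoid slope <= 1/4 per unit)."""
    model = _random_model(3)
    bound = np.prod([np.linalg.norm(w[:-1], 2) / 4.0 for w in model.weights])
    x = np.array([5.0, 5.0, 5.0])
    base = model.predict_scaled(model.scaling.scale_inputs(x[None, :]))[0]
    for eps in (1e-3, 1e-2):
        xs = model.scaling.scale_inputs(x[None, :]).copy()
        xs[0, 0] += eps
        out = model.predict_scaled(xs)[0]
        assert abs(out - base) <= bound * eps + 1e-12


def test_model_serialization_round_trip():
    model = _random_model(9)
    back = ann.NetworkModel.from_dict(model.to_dict())
    X = np.random.default_rng(0).uniform(0, 10, size=(5, 3))
    assert np.allclose(back.predict(X), model.predict(X), rtol=0, atol=0)


def test_topology_validation():
    with pytest.raises(ValueError):
        ann.NetworkTopology((3,))
    with pytest.raises(ValueError):
        ann.NetworkTopology((3, 0, 1))
    with pytest.raises(ValueError):
        ann.NetworkModel(ann.NetworkTopology((3, 2, 1)), [np.zeros((2, 2)), np.zeros((3, 1))],
                         ann.ScalingSpec())


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------


def test_gradient_matches_central_differences():
    """Norm-wise relative error of backprop vs central differences < 1e-6."""
    rng = np.random.default_rng(123)
    h = 1e-6
    for trial in range(10):
        sizes = (3, int(rng.integers(2, 5)), int(rng.integers(1, 4)), 1)
        model = _random_model(trial, sizes)
        x = rng.uniform(0.1, 0.9, sizes[0])
        t = rng.uniform(0.1, 0.9)
        grads, _ = ann.gradients(model, x, t)
        max_abs_err, max_grad = 0.0, 0.0
        for l in range(len(model.weights)):
            for idx in np.ndindex(model.weights[l].shape):
                w0 = model.weights[l][idx]
                model.weights[l][idx] = w0 + h
                ep = 0.5 * (model.predict_scaled(x[None, :])[0] - t) ** 2
                model.weights[l][idx] = w0 - h
                em = 0.5 * (model.predict_scaled(x[None, :])[0] - t) ** 2
                model.weights[l][idx] = w0
                max_abs_err = max(max_abs_err, abs(grads[l][idx] - (ep - em) / (2 * h)))
                max_grad = max(max_grad, abs(grads[l][idx]))
        assert max_abs_err / max_grad < 1e-6


def test_zero_error_pattern_leaves_model_unchanged():
    model = _random_model(5)
    x = np.array([0.3, 0.6, 0.4])
    t = model.predict_scaled(x[None, :])[0]  # exact target: zero error
    before = [w.copy() for w in model.weights]
    velocity = [np.zeros_like(w) for w in model.weights]
    err = ann.backprop_step(model, x, t, lrc=0.5, mf=0.0, velocity=velocity)
    assert err == 0.0
    for w0, w1 in zip(before, model.weights):
        assert np.array_equal(w0, w1)


def test_repeated_pattern_update_descends():
    """With mf=0 and small lrc, a second presentation of the same pattern has
    strictly smaller squared error."""
    model = _random_model(8)
    x = np.array([0.2, 0.8, 0.5])
    t = 0.7
    velocity = [np.zeros_like(w) for w in model.weights]
    e1 = ann.backprop_step(model, x, t, lrc=0.05, mf=0.0, velocity=velocity)
    e2 = model.predict_scaled(x[None, :])[0] - t
    assert abs(e2) < abs(e1)


# ---------------------------------------------------------------------------
# LRC control
# ---------------------------------------------------------------------------


def test_lrc_raised_on_monotone_improvement():
    new, unstable = ann.lrc_control(np.linspace(0.3, 0.1, 20), lrc=0.5)
    assert new == pytest.approx(0.5 * 1.05) and not unstable


def test_lrc_lowered_on_oscillation():
    window = 0.2 + 0.05 * np.tile([1.0, -1.0], 10)
    new, unstable = ann.lrc_control(window, lrc=0.5)
    assert new == pytest.approx(0.5 * 0.7) and unstable


def test_lrc_clipped_at_bounds():
    new, _ = ann.lrc_control(np.linspace(0.3, 0.1, 20), lrc=2.0, bounds=(1e-4, 2.0))
    assert new == 2.0
    new, _ = ann.lrc_control(0.2 + 0.05 * np.tile([1.0, -1.0], 10), lrc=1.2e-4, bounds=(1e-4, 2.0))
    assert new == 1e-4


def test_lrc_flat_window_unchanged():
    new, unstable = ann.lrc_control(np.full(20, 0.2), lrc=0.5)
    assert new == 0.5 and not unstable


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def test_rmse_and_correlation_cases(rng):
    model = _random_model(2)
    X = rng.uniform(0.1, 0.9, size=(40, 3))
    pred = model.predict_scaled(X)
    rmse, corr = ann._rmse_corr(pred, pred)
    assert rmse == 0.0 and corr == pytest.approx(1.0)
    _, corr_neg = ann._rmse_corr(pred, -pred + 1.0)
    assert corr_neg == pytest.approx(-1.0)
    with pytest.warns(UserWarning):
        _, corr_const = ann._rmse_corr(pred, np.full(40, 0.5))
    assert np.isnan(corr_const)


def test_random_predictions_uncorrelated(rng):
    a, b = rng.normal(size=1000), rng.normal(size=1000)
    _, corr = ann._rmse_corr(a, b)
    assert abs(corr) < 0.1


# ---------------------------------------------------------------------------
# Importance and interrogation
# ---------------------------------------------------------------------------


def test_importance_symmetric_network_uniform(rng):
    sc = _fitted_scaling(rng)
    topo = ann.NetworkTopology((3, 4, 2, 1))
    w0 = np.vstack([np.full((3, 4), 0.3), np.zeros((1, 4))])  # identical input rows
    w1 = np.random.default_rng(1).uniform(-1, 1, (5, 2))
    w2 = np.random.default_rng(2).uniform(-1, 1, (3, 1))
    model = ann.NetworkModel(topo, [w0, w1, w2], sc)
    imp = ann.input_importance(model)
    assert np.allclose(imp, [100 / 3] * 3)
    assert imp.sum() == pytest.approx(100.0, abs=1e-9)


def test_importance_matches_exhaustive_path_enumeration():
    for seed in (0, 1, 2):
        model = _random_model(seed)
        sizes = model.topology.layer_sizes
        totals = np.zeros(sizes[0])
        for i in range(sizes[0]):
            for h1, h2, o in itertools.product(range(sizes[1]), range(sizes[2]), range(sizes[3])):
                totals[i] += (
                    abs(model.weights[0][i, h1])
                    * abs(model.weights[1][h1, h2])
                    * abs(model.weights[2][h2, o])
                )
        expected = 100.0 * totals / totals.sum()
        assert np.allclose(ann.input_importance(model), expected, atol=1e-10)


def test_interrogation_zero_node_zero_degradation(rng):
    model = _random_model(4)
    model.weights[1][0, :] = 0.0  # silence hidden node (layer 1, node 0) already
    X = rng.uniform(0.1, 0.9, size=(20, 3))
    t = rng.uniform(0.1, 0.9, size=20)
    table = ann.hidden_node_interrogation(model, X, t)
    row = table[(table.layer == 1) & (table.node == 0)].iloc[0]
    assert row.degradation == 0.0
    # nonlinearity: per-node degradations need not sum to the joint removal
    joint = table[(table.layer == 1) & (table.node == "all")].iloc[0].degradation
    assert np.isfinite(joint)


def test_interrogation_on_converged_model(trained_curc_model):
    model, _, (X, y) = trained_curc_model
    Xs = model.scaling.scale_inputs(X)
    ts = model.scaling.scale_output(y)
    table = ann.hidden_node_interrogation(model, Xs, ts)
    per_node = table[table.node != "all"]
    assert (per_node["degradation"] >= -1e-9).all()  # removal never helps


def test_connection_strengths_sum_to_100(trained_curc_model):
    model, _, _ = trained_curc_model
    table = ann.connection_strengths(model)
    for _, grp in table.groupby("layer"):
        assert grp["relative_strength_pct"].sum() == pytest.approx(100.0)
    assert table["outside_design_range"].dtype == bool


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _surface_data():
    X = np.array(
        [[q, c, r] for q in (1, 2, 4, 8) for c in (10, 20, 40) for r in (3, 6, 9)], float
    )
    y = np.array([mean_diameter(SynthesisParams(q, c, r, False)) for q, c, r in X])
    return X, y


def test_training_is_deterministic_under_seed():
    X, y = _surface_data()
    cfg = ann.TrainingConfig(seed=7, max_iterations=800, patience=800)
    m1, h1 = ann.train(X, y, config=cfg)
    m2, h2 = ann.train(X, y, config=cfg)
    assert np.array_equal(h1.train_rmse, h2.train_rmse)
    assert all(np.array_equal(a, b) for a, b in zip(m1.weights, m2.weights))


def test_training_history_invariants(trained_curc_model):
    model, history, _ = trained_curc_model
    n = len(history.train_rmse)
    assert len(history.val_rmse) == len(history.lrc) == n
    assert (history.train_rmse >= 0).all() and (history.val_rmse >= 0).all()
    finite_corr = history.train_corr[np.isfinite(history.train_corr)]
    assert ((finite_corr >= -1) & (finite_corr <= 1)).all()
    # LRC trace within configured bounds
    assert history.lrc.min() >= 1e-4 and history.lrc.max() <= 2.0
    # returned model is the validation minimum: no overtraining at return
    assert history.val_rmse[history.best_iteration - 1] <= history.val_rmse[-1] + 1e-12
    assert history.val_rmse[history.best_iteration - 1] == history.val_rmse.min()
    assert all(np.all(np.isfinite(w)) for w in model.weights)


def test_rmse_profile_plateau_then_steep_descent(trained_curc_model):
    """The training RMSE history starts with a plateau (little net change over
    the first stretch) before the steep learning phase."""
    _, history, _ = trained_curc_model
    rmse = history.train_rmse
    total_drop = rmse[0] - rmse.min()
    early_drop = rmse[0] - rmse[:200].min()
    assert total_drop > 0
    assert early_drop < 0.5 * total_drop
    # steepest 200-iteration descent happens after the initial stretch
    window_drops = rmse[:-200] - rmse[200:]
    assert np.argmax(window_drops) > 100


def test_correlation_and_rmse_histories_move_oppositely(trained_curc_model):
    _, history, _ = trained_curc_model
    ok = np.isfinite(history.train_corr)
    rho = stats.spearmanr(history.train_rmse[ok], history.train_corr[ok]).statistic
    assert rho < 0


def test_train_errors_on_tiny_data():
    with pytest.raises(ValueError):
        ann.train(np.zeros((0, 3)), np.zeros(0))
    with pytest.raises(ValueError):
        ann.train(np.zeros((2, 3)), np.array([1.0, 2.0]))


def test_monodisperse_dataset_filters(default_library):
    lib, truth = default_library
    X, y = ann.monodisperse_diameter_dataset(lib, curcumin=True)
    assert X.shape[1] == 3 and len(X) == len(y)
    assert (y > 0).all()
    X_meas, y_meas = ann.monodisperse_diameter_dataset(lib, curcumin=True, per_formulation=False)
    assert len(X_meas) > len(X)  # replicate-level is larger than formulation-level


# ---------------------------------------------------------------------------
# Recall mode
# ---------------------------------------------------------------------------


def test_size_heatmap_mask_consistency(trained_curc_model, default_library):
    model, _, _ = trained_curc_model
    lib, _ = default_library
    X, y, _ = dispersity_table(lib, "binary")
    disp = ClassifierSpec("SVM", seed=0).build().fit(X, y)
    tfr_grid, lipid_grid = np.linspace(1, 16, 10), np.linspace(10, 40, 5)
    grid = ann.size_heatmap(model, tfr_grid, lipid_grid, 3.0, True, disp)
    X4 = grid[["tfr_ml_min", "lipid_mg_ml", "va_vo"]].copy()
    X4["curcumin"] = 1.0
    expected_mask = disp.predict(X4.to_numpy(float)) != "monodisperse"
    assert np.array_equal(grid["masked"].to_numpy(), expected_mask)
    # the unstable (masked) field grows with TFR
    frac_low = grid[grid.tfr_ml_min <= 6]["masked"].mean()
    frac_high = grid[grid.tfr_ml_min > 10]["masked"].mean()
    assert frac_high > frac_low
    # run twice: identical
    grid2 = ann.size_heatmap(model, tfr_grid, lipid_grid, 3.0, True, disp)
    pd.testing.assert_frame_equal(grid, grid2)


def test_size_heatmap_dimension_mismatch(trained_curc_model):
    model, _, _ = trained_curc_model
    with pytest.raises(Exception):
        ann.size_heatmap(model, np.zeros((2, 2)), np.zeros(3), 3.0, True)
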