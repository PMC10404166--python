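"""Feed-forward neural network for quantitative liposome-size prediction.

A small, fully connected sigmoid network (default topology 3-4-2-1: the
three continuous synthesis parameters in, predicted hydrodynamic diameter
out) trained from scratch with online backpropagation.  Nothing here wraps
an external ML framework: the forward pass, the gradient, the momentum
update, the adaptive learning-rate-coefficient (LRC) controller, and the
diagnostics are all explicit, because interrogating them *is* the point —
the training history, input-importance attribution and hidden-node
interrogation are first-class outputs, not afterthoughts.

Notes on the pieces:

* **Scaling** — sigmoid units saturate outside a few logits, so inputs and
  the diameter target are min-max scaled to [0.1, 0.9] (fitted on the
  training split only; the inverse map restores nm).
* **LRC/MF control** — the learning rate is raised multiplicatively while
  the training RMSE falls monotonically over a trailing window, and cut
  when the window oscillates (sign changes in the first differences); the
  momentum factor is halved when instability fires twice in a row.
* **Early stopping** — the returned model is the snapshot at the validation
  RMSE minimum; training halts after a patience period without improvement
  (a rising validation RMSE would indicate overtraining).
* **Input importance** — Garson-style attribution generalized to two hidden
  layers: each input's share of the total absolute connection-weight
  product summed over all input-to-output paths.
* **Hidden-node interrogation** — each hidden node's outgoing weights are
  zeroed in turn and the validation RMSE degradation recorded, identifying
  the minimum necessary number of units per layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import BINARY_PDI_THRESHOLD, MeasurementLibrary, SynthesisParams

__all__ = [
    "NetworkTopology",
    "ScalingSpec",
    "NetworkModel",
    "TrainingConfig",
    "TrainingHistory",
    "forward",
    "backprop_step",
    "train",
    "lrc_control",
    "rmse_and_correlation",
    "input_importance",
    "hidden_node_interrogation",
    "connection_strengths",
    "size_heatmap",
    "monodisperse_diameter_dataset",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


@dataclass(frozen=True)
class NetworkTopology:
    """Layer sizes, input first; sigmoid transfer on every non-input layer."""

    layer_sizes: tuple[int, ...] = (3, 4, 2, 1)

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least an input and an output layer")
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("all layer sizes must be >= 1")

    @property
    def n_inputs(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_outputs(self) -> int:
        return self.layer_sizes[-1]


@dataclass
class ScalingSpec:
    """Min-max scaling of inputs and target into the sigmoid working range."""

    input_min: np.ndarray | None = None
    input_max: np.ndarray | None = None
    output_min: float | None = None
    output_max: float | None = None
    target_interval: tuple[float, float] = (0.1, 0.9)

    @property
    def fitted(self) -> bool:
        return self.input_min is not None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ScalingSpec":
        X = np.asarray(X, float)
        self.input_min = X.min(axis=0)
        self.input_max = X.max(axis=0)
        self.output_min = float(np.min(y))
        self.output_max = float(np.max(y))
        return self

    def _affine(self, v, lo, hi):
        a, b = self.target_interval
        span = np.where(np.asarray(hi) > np.asarray(lo), np.asarray(hi) - np.asarray(lo), 1.0)
        return a + (b - a) * (v - lo) / span

    def _inverse(self, v, lo, hi):
        a, b = self.target_interval
        span = np.where(np.asarray(hi) > np.asarray(lo), np.asarray(hi) - np.asarray(lo), 1.0)
        return lo + (v - a) * span / (b - a)

    def scale_inputs(self, X: np.ndarray) -> np.ndarray:
        self._require_fitted()
        return self._affine(np.asarray(X, float), self.input_min, self.input_max)

    def scale_output(self, y: np.ndarray) -> np.ndarray:
        self._require_fitted()
        return self._affine(np.asarray(y, float), self.output_min, self.output_max)

    def unscale_output(self, y_scaled: np.ndarray) -> np.ndarray:
        self._require_fitted()
        return self._inverse(np.asarray(y_scaled, float), self.output_min, self.output_max)

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("scaling has not been fitted")

    def to_dict(self) -> dict:
        self._require_fitted()
        return {
            "input_min": list(map(float, self.input_min)),
            "input_max": list(map(float, self.input_max)),
            "output_min": self.output_min,
            "output_max": self.output_max,
            "target_interval": list(self.target_interval),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingSpec":
        s = cls(target_interval=tuple(d["target_interval"]))
        s.input_min = np.asarray(d["input_min"], float)
        s.input_max = np.asarray(d["input_max"], float)
        s.output_min = float(d["output_min"])
        s.output_max = float(d["output_max"])
        return s


@dataclass
class NetworkModel:
    """Topology + weights + scaling.  Weight matrix l has shape
    ``(n_l + 1, n_{l+1})``; the last row holds the bias terms."""

    topology: NetworkTopology
    weights: list[np.ndarray]
    scaling: ScalingSpec

    def __post_init__(self) -> None:
        sizes = self.topology.layer_sizes
        if len(self.weights) != len(sizes) - 1:
            raise ValueError("one weight matrix per connection layer required")
        for l, w in enumerate(self.weights):
            expected = (sizes[l] + 1, sizes[l + 1])
            if w.shape != expected:
                raise ValueError(f"weight matrix {l} has shape {w.shape}, expected {expected}")

    @classmethod
    def initialize(cls, topology: NetworkTopology, scaling: ScalingSpec, seed: int = 0) -> "NetworkModel":
        """Random initial weights, U(-0.5, 0.5), seed-controlled."""
        rng = np.random.default_rng(seed)
        sizes = topology.layer_sizes
        weights = [rng.uniform(-0.5, 0.5, size=(sizes[l] + 1, sizes[l + 1])) for l in range(len(sizes) - 1)]
        return cls(topology, weights, scaling)

    def copy(self) -> "NetworkModel":
        return NetworkModel(self.topology, [w.copy() for w in self.weights], self.scaling)

    # -- propagation ------------------------------------------------------------
    def activations(self, X_scaled: np.ndarray) -> list[np.ndarray]:
        """Layer activations (scaled units) for a batch of scaled inputs."""
        a = np.atleast_2d(np.asarray(X_scaled, float))
        acts = [a]
        for w in self.weights:
            a = _sigmoid(np.hstack([a, np.ones((a.shape[0], 1))]) @ w)
            acts.append(a)
        return acts

    def predict_scaled(self, X_scaled: np.ndarray) -> np.ndarray:
        return self.activations(X_scaled)[-1][:, 0]

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Predicted diameter (nm) for raw-unit inputs."""
        Xs = self.scaling.scale_inputs(np.atleast_2d(np.asarray(X_raw, float)))
        return self.scaling.unscale_output(self.predict_scaled(Xs))

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(self.topology.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "scaling": self.scaling.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkModel":
        return cls(
            NetworkTopology(tuple(d["layer_sizes"])),
            [np.asarray(w, float) for w in d["weights"]],
            ScalingSpec.from_dict(d["scaling"]),
        )


def forward(model: NetworkModel, params: SynthesisParams | Sequence[float]) -> float:
    """Predicted diameter (nm) for one formulation.

    The three continuous synthesis parameters (TFR, lipid concentration,
    V_a/V_o) feed the network; curcumin state selects which model to use and
    is not an input.
    """
    if isinstance(params, SynthesisParams):
        x = [params.tfr, params.lipid_conc, params.va_vo]
    else:
        x = list(params)
    return float(model.predict(np.asarray(x, float))[0])


# ---------------------------------------------------------------------------
# Gradient and update
# ---------------------------------------------------------------------------


def gradients(model: NetworkModel, x_scaled: np.ndarray, t_scaled: float) -> tuple[list[np.ndarray], float]:
    """Backpropagated gradient of the squared error ``E = 0.5 (y - t)^2``
    for one pattern.  Returns ``(per-layer gradients, output error y - t)``."""
    acts = model.activations(np.atleast_2d(x_scaled))
    y = acts[-1][0, 0]
    err = y - float(t_scaled)
    delta = np.atleast_2d(err * acts[-1] * (1.0 - acts[-1]))[0]  # dE/dz at output
    grads: list[np.ndarray] = [None] * len(model.weights)
    for l in range(len(model.weights) - 1, -1, -1):
        a_prev = np.append(acts[l][0], 1.0)
        grads[l] = np.outer(a_prev, delta)
        if l > 0:
            h = acts[l][0]
            delta = (model.weights[l][:-1, :] @ delta) * h * (1.0 - h)
    return grads, err


def backprop_step(
    model: NetworkModel,
    x_scaled: np.ndarray,
    t_scaled: float,
    lrc: float,
    mf: float,
    velocity: list[np.ndarray],
) -> float:
    """One online update: ``dw = -lrc * grad + mf * previous dw`` (in place).

    Returns the pattern's output error ``y - t`` before the update.
    """
    grads, err = gradients(model, x_scaled, t_scaled)
    for l, g in enumerate(grads):
        velocity[l] = -lrc * g + mf * velocity[l]
        model.weights[l] += velocity[l]
    return err


# ---------------------------------------------------------------------------
# Adaptive learning-rate control
# ---------------------------------------------------------------------------


def lrc_control(
    rmse_window: Sequence[float],
    lrc: float,
    bounds: tuple[float, float] = (1e-4, 2.0),
    lrc_down: float = 0.7,
    lrc_up: float = 1.05,
    oscillation_fraction: float = 0.5,
) -> tuple[float, bool]:
    """Adapt the learning-rate coefficient from a trailing RMSE window.

    Oscillation (sign changes among first differences exceeding
    ``oscillation_fraction`` of the possible count) lowers the LRC to damp
    instability; monotone improvement raises it to accelerate learning.
    Returns ``(new lrc, instability fired)``, with the LRC clipped to bounds.
    """
    w = np.asarray(rmse_window, float)
    if w.size < 2:
        raise ValueError("need a window of >= 2 RMSE values")
    diffs = np.diff(w)
    signs = np.sign(diffs[diffs != 0.0])
    n_changes = int(np.sum(signs[1:] != signs[:-1])) if signs.size > 1 else 0
    max_changes = max(len(diffs) - 1, 1)
    unstable = n_changes / max_changes > oscillation_fraction
    if unstable:
        lrc = lrc * lrc_down
    elif np.all(diffs <= 0.0) and np.any(diffs < 0.0):
        lrc = lrc * lrc_up
    return float(np.clip(lrc, *bounds)), unstable


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def rmse_and_correlation(model: NetworkModel, X_scaled: np.ndarray, t_scaled: np.ndarray) -> tuple[float, float]:
    """RMSE (scaled units) and Pearson correlation on a data set."""
    if len(t_scaled) == 0:
        raise ValueError("empty data set")
    pred = model.predict_scaled(X_scaled)
    return _rmse_corr(pred, np.asarray(t_scaled, float))


def _rmse_corr(pred: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    rmse = float(np.sqrt(np.mean((pred - target) ** 2)))
    if np.std(target) == 0.0 or np.std(pred) == 0.0:
        warnings.warn("constant predictions or targets: correlation undefined")
        return rmse, float("nan")
    corr = float(np.corrcoef(pred, target)[0, 1])
    return rmse, corr


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainingConfig:
    """Backpropagation training parameters.

    One *iteration* is one training-pattern presentation (online updating
    with per-epoch shuffling); ``batch`` mode instead accumulates the
    gradient over all patterns per iteration.  Controller defaults were
    chosen for stable convergence on the synthetic fixtures; the account
    they implement (raise the LRC while learning progresses, cut it on
    oscillation, halve the momentum on repeated instability) is the
    behavioral contract.
    """

    lrc: float = 0.5
    lrc_bounds: tuple[float, float] = (1e-4, 2.0)
    lrc_down: float = 0.7
    lrc_up: float = 1.05
    mf: float = 0.9
    max_iterations: int = 100_000
    patience: int = 10_000
    instability_window: int = 50
    val_fraction: float = 0.15
    batch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lrc > 0:
            raise ValueError("lrc must be positive")
        if not (0.0 <= self.mf < 1.0):
            raise ValueError("mf must be in [0, 1)")
        if self.lrc_bounds[0] > self.lrc_bounds[1]:
            raise ValueError("lrc bounds must be ordered")


@dataclass
class TrainingHistory:
    """Per-iteration training diagnostics."""

    train_rmse: np.ndarray
    val_rmse: np.ndarray
    train_corr: np.ndarray
    val_corr: np.ndarray
    lrc: np.ndarray
    best_iteration: int
    final_pattern_errors_train: np.ndarray  # scaled output errors at returned state
    final_pattern_errors_val: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.train_rmse)
        if not (len(self.val_rmse) == len(self.train_corr) == len(self.val_corr) == len(self.lrc) == n):
            raise ValueError("history series must have equal length")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.train_rmse) + 1),
                "train_rmse": self.train_rmse,
                "val_rmse": self.val_rmse,
                "train_corr": self.train_corr,
                "val_corr": self.val_corr,
                "lrc": self.lrc,
            }
        )


def train(
    X: np.ndarray,
    y: np.ndarray,
    topology: NetworkTopology = NetworkTopology(),
    config: TrainingConfig = TrainingConfig(),
) -> tuple[NetworkModel, TrainingHistory]:
    """Train a network on raw-unit inputs ``X`` (n, 3) and diameters ``y`` (nm).

    The data are split 85/15 into training and validation patterns; scaling
    is fitted on the training split only.  The returned model is the
    snapshot at the validation-RMSE minimum.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(X) < 3:
        raise ValueError("need at least 3 patterns to split off a validation set")
    rng = np.random.default_rng(config.seed)

    n_val = max(1, int(round(config.val_fraction * len(X))))
    perm = rng.permutation(len(X))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    scaling = ScalingSpec().fit(X[train_idx], y[train_idx])
    Xtr, ttr = scaling.scale_inputs(X[train_idx]), scaling.scale_output(y[train_idx])
    Xval, tval = scaling.scale_inputs(X[val_idx]), scaling.scale_output(y[val_idx])

    model = NetworkModel.initialize(topology, scaling, seed=int(rng.integers(0, 2**31 - 1)))
    velocity = [np.zeros_like(w) for w in model.weights]
    lrc, mf = config.lrc, config.mf
    consecutive_instability = 0

    hist = {k: [] for k in ("train_rmse", "val_rmse", "train_corr", "val_corr", "lrc")}
    best_val = np.inf
    best_model = model.copy()
    best_iter = 0

    order = rng.permutation(len(train_idx))
    pos = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny validation sets can have constant targets
        for it in range(1, config.max_iterations + 1):
            if config.batch:
                grads_sum = [np.zeros_like(w) for w in model.weights]
                for i in range(len(Xtr)):
                    g, _ = gradients(model, Xtr[i], ttr[i])
                    for l in range(len(g)):
                        grads_sum[l] += g[l]
                for l in range(len(grads_sum)):
                    velocity[l] = -lrc * grads_sum[l] / len(Xtr) + mf * velocity[l]
                    model.weights[l] += velocity[l]
            else:
                if pos >= len(order):
                    order = rng.permutation(len(train_idx))
                    pos = 0
                backprop_step(model, Xtr[order[pos]], ttr[order[pos]], lrc, mf, velocity)
                pos += 1

            tr_rmse, tr_corr = _rmse_corr(model.predict_scaled(Xtr), ttr)
            va_rmse, va_corr = _rmse_corr(model.predict_scaled(Xval), tval)
            hist["train_rmse"].append(tr_rmse)
            hist["val_rmse"].append(va_rmse)
            hist["train_corr"].append(tr_corr)
            hist["val_corr"].append(va_corr)
            hist["lrc"].append(lrc)

            if not all(np.all(np.isfinite(w)) for w in model.weights):
                raise FloatingPointError("training diverged to non-finite weights")

            if va_rmse < best_val:
                best_val = va_rmse
                best_model = model.copy()
                best_iter = it

            if it % config.instability_window == 0:
                window = hist["train_rmse"][-config.instability_window:]
                lrc, unstable = lrc_control(
                    window, lrc, config.lrc_bounds, config.lrc_down, config.lrc_up
                )
                if unstable:
                    consecutive_instability += 1
                    if consecutive_instability >= 2:
                        mf = mf / 2.0
                        consecutive_instability = 0
                else:
                    consecutive_instability = 0

            if it - best_iter >= config.patience:
                break

    err_tr = best_model.predict_scaled(Xtr) - ttr
    err_val = best_model.predict_scaled(Xval) - tval
    history = TrainingHistory(
        *(np.asarray(hist[k]) for k in ("train_rmse", "val_rmse", "train_corr", "val_corr", "lrc")),
        best_iteration=best_iter,
        final_pattern_errors_train=err_tr,
        final_pattern_errors_val=err_val,
    )
    return best_model, history


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def input_importance(model: NetworkModel) -> np.ndarray:
    """Relative input importance (percent, sums to 100).

    Garson-style connection-weight attribution generalized to any depth:
    each input's total absolute-weight path product to the output, i.e. the
    matrix product of the element-wise absolute weight matrices (bias rows
    excluded), normalized across inputs.
    """
    m = np.abs(model.weights[0][:-1, :])
    for w in model.weights[1:]:
        m = m @ np.abs(w[:-1, :])
    totals = m.sum(axis=1)
    return 100.0 * totals / totals.sum()


def hidden_node_interrogation(
    model: NetworkModel, X_scaled: np.ndarray, t_scaled: np.ndarray
) -> pd.DataFrame:
    """RMSE degradation from silencing each hidden node in turn.

    A node is silenced by zeroing its outgoing weights.  The table carries
    one row per hidden node plus one ``all`` row per layer (all that layer's
    nodes silenced together); because the network is nonlinear the per-node
    degradations need not sum to the joint one, so both are reported.
    """
    base_rmse, _ = rmse_and_correlation(model, X_scaled, t_scaled)
    rows = []
    for layer in range(1, len(model.topology.layer_sizes) - 1):
        for node in range(model.topology.layer_sizes[layer]):
            probe = model.copy()
            probe.weights[layer][node, :] = 0.0
            rmse, _ = rmse_and_correlation(probe, X_scaled, t_scaled)
            rows.append(
                {"layer": layer, "node": node, "rmse": rmse, "degradation": rmse - base_rmse}
            )
        probe = model.copy()
        probe.weights[layer][:-1, :] = 0.0
        rmse, _ = rmse_and_correlation(probe, X_scaled, t_scaled)
        rows.append({"layer": layer, "node": "all", "rmse": rmse, "degradation": rmse - base_rmse})
    return pd.DataFrame(rows)


def connection_strengths(model: NetworkModel, bounds: tuple[float, float] = (15.0, 52.0)) -> pd.DataFrame:
    """Per-layer relative output-connection strengths (percent), with a flag
    for nodes outside the design range.  Reported, never enforced."""
    rows = []
    for layer, w in enumerate(model.weights):
        strengths = np.abs(w[:-1, :]).sum(axis=1)
        rel = 100.0 * strengths / strengths.sum()
        for node, r in enumerate(rel):
            rows.append(
                {
                    "layer": layer,
                    "node": node,
                    "relative_strength_pct": float(r),
                    "outside_design_range": bool(r < bounds[0] or r > bounds[1]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Data plumbing and recall mode
# ---------------------------------------------------------------------------


def monodisperse_diameter_dataset(
    lib: MeasurementLibrary,
    curcumin: bool,
    per_formulation: bool = True,
    threshold: float = BINARY_PDI_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Training data for size prediction: day-0 monodisperse records of one
    curcumin subset.  With ``per_formulation`` the replicate measurements are
    averaged into one (features, mean diameter) pattern per formulation."""
    frame = lib.day0().frame
    frame = frame[frame["curcumin"] == int(curcumin)]
    if per_formulation:
        g = frame.groupby(["tfr_ml_min", "lipid_mg_ml", "va_vo"], as_index=False).agg(
            pdi=("pdi", "mean"), diameter_nm=("diameter_nm", "mean")
        )
    else:
        g = frame
    g = g[g["pdi"] <= threshold]
    if len(g) == 0:
        raise ValueError("no monodisperse records after filtering")
    X = g[["tfr_ml_min", "lipid_mg_ml", "va_vo"]].to_numpy(float)
    y = g["diameter_nm"].to_numpy(float)
    return X, y


def size_heatmap(
    model: NetworkModel,
    tfr_grid: np.ndarray,
    lipid_grid: np.ndarray,
    va_vo: float,
    curcumin: bool,
    dispersity_model=None,
) -> pd.DataFrame:
    """Recall-mode diameter grid with polydisperse masking.

    The ANN predicts the diameter over a dense (TFR, lipid) grid at fixed
    V_a/V_o; cells a trained dispersity classifier predicts polydisperse are
    flagged ``masked`` (the grey zones of the published heatmaps).
    """
    tfr_grid = np.asarray(tfr_grid, float)
    lipid_grid = np.asarray(lipid_grid, float)
    if tfr_grid.ndim != 1 or lipid_grid.ndim != 1:
        raise ValueError("tfr_grid and lipid_grid must be one-dimensional axes")
    tt, cc = np.meshgrid(tfr_grid, lipid_grid, indexing="ij")
    X3 = np.column_stack([tt.ravel(), cc.ravel(), np.full(tt.size, float(va_vo))])
    diam = model.predict(X3)
    if dispersity_model is not None:
        X4 = np.column_stack([X3, np.full(tt.size, float(curcumin))])
        masked = dispersity_model.predict(X4) != "monodisperse"
    else:
        masked = np.zeros(tt.size, dtype=bool)
    return pd.DataFrame(
        {
            "tfr_ml_min": X3[:, 0],
            "lipid_mg_ml": X3[:, 1],
            "va_vo": X3[:, 2],
            "curcumin": int(curcumin),
            "diameter_nm": diam,
            "masked": masked,
        }
    )
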