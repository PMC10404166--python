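"""Supervised classification of liposome dispersity and stability.

Qualitative predictions from the four synthesis parameters (TFR, lipid
concentration, V_a/V_o, curcumin flag):

* **dispersity** — per-measurement labels on day-0 observations, binary
  (monodisperse/polydisperse at PdI 0.220) or multiclass (0.200/0.300);
* **stability** — per-formulation labels from the one-sided t-test on PdI
  over the 72 h observation window.

Six classifier families are compared with frozen out-of-the-box
hyperparameters (no tuning, mirroring a deliberately hands-off approach):
logistic regression (LOR), linear discriminant analysis (LDA), k-nearest
neighbours (KNN), a decision tree (CART), Gaussian naive Bayes (GNB) and a
support-vector machine (SVM).  Accuracy is estimated two ways: repeated
stratified 85/15 holdout resampling, and stratified 10-fold cross-validation.

The module also provides the three sensitivity sweeps (dataset size, unique
formulations, replicate cap) and dense recall-mode prediction grids
("heatmaps") over hypothetical synthesis conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datamodel import (
    BINARY_PDI_THRESHOLD,
    MeasurementLibrary,
    cap_replicates,
    label_all_stability,
    label_dispersity,
)

__all__ = [
    "ALGORITHMS",
    "FEATURE_COLUMNS",
    "ClassifierSpec",
    "AccuracyReport",
    "SweepResult",
    "StratificationError",
    "dispersity_table",
    "stability_table",
    "holdout_split",
    "train_and_score",
    "repeated_holdout_accuracy",
    "stratified_kfold_accuracy",
    "compare_algorithms",
    "dataset_size_sweep",
    "replicate_cap_sweep",
    "plateau_size",
    "predict_heatmap",
]

FEATURE_COLUMNS = ("tfr_ml_min", "lipid_mg_ml", "va_vo", "curcumin")

ALGORITHMS = ("LOR", "LDA", "KNN", "CART", "GNB", "SVM")

#: Frozen out-of-the-box hyperparameters per algorithm family.
DEFAULT_HYPERPARAMETERS: Mapping[str, Mapping] = {
    "LOR": {"max_iter": 1000},
    "LDA": {},
    "KNN": {"n_neighbors": 5},
    "CART": {},
    "GNB": {},
    "SVM": {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
}


class StratificationError(ValueError):
    """A class is too small (or absent) for the requested stratified scheme."""


@dataclass(frozen=True)
class ClassifierSpec:
    """One classification algorithm with frozen hyperparameters."""

    algorithm: str = "SVM"
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0
    standardize: bool = False  # optional feature standardization (off by default)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")

    def build(self):
        params = {**DEFAULT_HYPERPARAMETERS[self.algorithm], **dict(self.hyperparameters)}
        if self.algorithm == "LOR":
            est = LogisticRegression(**params)
        elif self.algorithm == "LDA":
            est = LinearDiscriminantAnalysis(**params)
        elif self.algorithm == "KNN":
            est = KNeighborsClassifier(**params)
        elif self.algorithm == "CART":
            est = DecisionTreeClassifier(random_state=self.seed, **params)
        elif self.algorithm == "GNB":
            est = GaussianNB(**params)
        else:
            est = SVC(random_state=self.seed, **params)
        if self.standardize:
            return make_pipeline(StandardScaler(), est)
        return est


@dataclass(frozen=True)
class AccuracyReport:
    """Holdout and k-fold accuracy of one classifier (percent)."""

    algorithm: str
    scheme: str
    holdout_accuracy: float
    kfold_mean: float
    kfold_sd: float
    k: int = 10

    def __post_init__(self) -> None:
        for v in (self.holdout_accuracy, self.kfold_mean):
            if not (0.0 <= v <= 100.0):
                raise ValueError("accuracies must be in [0, 100]")
        if self.kfold_sd < 0:
            raise ValueError("kfold_sd must be >= 0")


@dataclass(frozen=True)
class SweepResult:
    """Mean +/- SD accuracy against one swept quantity."""

    swept: str
    table: pd.DataFrame  # columns: x, mean_accuracy, sd_accuracy, n_randomizations
    n_randomizations: int


# ---------------------------------------------------------------------------
# Feature/label extraction
# ---------------------------------------------------------------------------


def dispersity_table(
    lib: MeasurementLibrary, scheme: Literal["binary", "multiclass"] = "binary"
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Day-0 feature matrix and dispersity labels, one row per measurement."""
    frame = lib.day0().frame
    X = frame.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = np.array([label_dispersity(p, scheme).label for p in frame["pdi"]])
    return X, y, frame


def stability_table(
    lib: MeasurementLibrary,
    threshold: float = BINARY_PDI_THRESHOLD,
    alpha: float = 0.05,
    days: Sequence[int] = (0, 1, 2, 3),
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Per-formulation feature matrix and stable/unstable labels."""
    table = label_all_stability(lib, threshold=threshold, alpha=alpha, days=days)
    X = table.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = np.where(table["stable"].to_numpy(), "stable", "unstable")
    return X, y, table


# ---------------------------------------------------------------------------
# Splitting and scoring
# ---------------------------------------------------------------------------


def holdout_split(
    X: np.ndarray,
    y: np.ndarray,
    train_fraction: float = 0.85,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Class-stratified 85/15 train/validation split, reproducible under seed."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise StratificationError(f"need >= 2 classes, got {list(classes)}")
    if counts.min() < 2:
        raise StratificationError(
            f"class {classes[counts.argmin()]!r} has fewer than 2 observations"
        )
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, train_size=train_fraction, stratify=y, random_state=seed
    )
    return X_tr, X_val, y_tr, y_val


def train_and_score(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
):
    """Fit one classifier and score it on the validation set.

    Returns ``(fitted model, validation accuracy in percent)``.
    """
    if len(np.unique(y_train)) < 2:
        raise StratificationError("degenerate single-class training set")
    model = spec.build()
    model.fit(X_train, y_train)
    return model, 100.0 * float(model.score(X_val, y_val))


def repeated_holdout_accuracy(
    spec: ClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 50,
    train_fraction: float = 0.85,
) -> float:
    """Holdout with random resampling: mean validation accuracy (percent)."""
    rng = np.random.default_rng(spec.seed)
    accs = []
    for _ in range(n_repeats):
        split_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, X_val, y_tr, y_val = holdout_split(X, y, train_fraction, split_seed)
        _, acc = train_and_score(spec, X_tr, y_tr, X_val, y_val)
        accs.append(acc)
    return float(np.mean(accs))


def stratified_kfold_accuracy(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, k: int = 10
) -> tuple[float, float]:
    """Stratified k-fold cross-validated accuracy: ``(mean %, sd %)``."""
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} members, fewer than k={k}"
        )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    accs = []
    for train_idx, val_idx in cv.split(X, y):
        _, acc = train_and_score(spec, X[train_idx], y[train_idx], X[val_idx], y[val_idx])
        accs.append(acc)
    return float(np.mean(accs)), float(np.std(accs))


def compare_algorithms(
    X: np.ndarray,
    y: np.ndarray,
    scheme: str,
    seed: int = 0,
    k: int = 10,
    n_holdout_repeats: int = 50,
) -> pd.DataFrame:
    """Accuracy report for all six algorithm families (Table-1-style)."""
    rows = []
    for algo in ALGORITHMS:
        spec = ClassifierSpec(algorithm=algo, seed=seed)
        holdout = repeated_holdout_accuracy(spec, X, y, n_repeats=n_holdout_repeats)
        kfold_mean, kfold_sd = stratified_kfold_accuracy(spec, X, y, k=k)
        report = AccuracyReport(algo, scheme, holdout, kfold_mean, kfold_sd, k)
        rows.append(report.__dict__)
    return pd.DataFrame(rows).sort_values("kfold_mean", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Sensitivity sweeps
# ---------------------------------------------------------------------------


def _one_subsample_run(
    X: np.ndarray,
    y: np.ndarray,
    formulation_key: np.ndarray,
    size: int,
    spec: ClassifierSpec,
    rng: np.random.Generator,
) -> tuple[float, int] | None:
    idx = rng.choice(len(y), size=size, replace=False)
    Xs, ys = X[idx], y[idx]
    n_formulations = len(np.unique(formulation_key[idx]))
    try:
        split_seed = int(rng.integers(0, 2**31 - 1))
        X_tr, X_val, y_tr, y_val = holdout_split(Xs, ys, seed=split_seed)
        _, acc = train_and_score(spec, X_tr, y_tr, X_val, y_val)
    except StratificationError:
        return None
    return acc, n_formulations


def dataset_size_sweep(
    lib: MeasurementLibrary,
    sizes: Sequence[int] | None = None,
    n_rand: int = 200,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    scheme: Literal["binary", "multiclass"] = "binary",
) -> SweepResult:
    """Effect of library size on holdout accuracy.

    For each target size, measurements are randomly deleted from the day-0
    set, the full pipeline (stratified split, training, validation scoring)
    re-runs, and outcomes are averaged over ``n_rand`` randomizations.  The
    number of unique formulations surviving each subsample is recorded, so
    the same sweep also yields accuracy vs unique-formulation count.
    """
    spec = spec or ClassifierSpec(seed=seed)
    X, y, frame = dispersity_table(lib, scheme)
    key = frame.groupby(list(FEATURE_COLUMNS), sort=False).ngroup().to_numpy()
    n_total = len(y)
    if sizes is None:
        sizes = np.unique(np.linspace(40, n_total, 8).astype(int))
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > n_total:
            raise ValueError(f"size {size} exceeds day-0 measurement count {n_total}")
        accs, nforms = [], []
        for _ in range(n_rand):
            out = _one_subsample_run(X, y, key, int(size), spec, rng)
            if out is not None:
                accs.append(out[0])
                nforms.append(out[1])
        if not accs:
            continue  # size below minimum trainable set: skipped
        rows.append(
            {
                "x": int(size),
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs)),
                "mean_formulations": float(np.mean(nforms)),
                "n_randomizations": len(accs),
            }
        )
    return SweepResult("measurement count", pd.DataFrame(rows), n_rand)


def plateau_size(
    sweep: SweepResult, reference_accuracy: float = 92.0, alpha: float = 0.05
) -> int | None:
    """Smallest swept size whose mean accuracy is not significantly below a
    fixed reference accuracy (one-sided t-test against ``reference_accuracy``)."""
    for row in sweep.table.itertuples():
        n = row.n_randomizations
        if row.sd_accuracy == 0:
            if row.mean_accuracy >= reference_accuracy:
                return int(row.x)
            continue
        se = row.sd_accuracy / np.sqrt(n)
        t = (row.mean_accuracy - reference_accuracy) / se
        p_below = stats.t.cdf(t, df=n - 1)  # H1: mean < reference
        if p_below >= alpha:
            return int(row.x)
    return None


def replicate_cap_sweep(
    lib: MeasurementLibrary,
    caps: Sequence[int] = tuple(range(3, 16)),
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    n_holdout_repeats: int = 10,
    k: int = 10,
    scheme: Literal["binary", "multiclass"] = "binary",
) -> SweepResult:
    """Effect of the per-formulation replicate cap on accuracy.

    For each cap the library is re-capped, and both the repeated-holdout
    accuracy and the stratified k-fold predicted accuracy are reported.
    """
    spec = spec or ClassifierSpec(seed=seed)
    rows = []
    for i, cap in enumerate(caps):
        capped = cap_replicates(lib, int(cap), seed=seed + i)
        X, y, _ = dispersity_table(capped, scheme)
        holdout = repeated_holdout_accuracy(
            ClassifierSpec(spec.algorithm, spec.hyperparameters, seed + i, spec.standardize),
            X,
            y,
            n_repeats=n_holdout_repeats,
        )
        kfold_mean, kfold_sd = stratified_kfold_accuracy(spec, X, y, k=k)
        rows.append(
            {
                "x": int(cap),
                "mean_accuracy": holdout,
                "kfold_mean": kfold_mean,
                "sd_accuracy": kfold_sd,
                "n_measurements": len(y),
                "n_randomizations": n_holdout_repeats,
            }
        )
    return SweepResult("replicate cap", pd.DataFrame(rows), n_holdout_repeats)


# ---------------------------------------------------------------------------
# Recall-mode heatmaps
# ---------------------------------------------------------------------------


def predict_heatmap(
    model,
    tfr_grid: np.ndarray,
    lipid_grid: np.ndarray,
    va_vo: float,
    curcumin: bool,
    training_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Dense recall-mode prediction grid for one (V_a/V_o, curcumin) panel.

    Returns a long-format frame with one row per (TFR, lipid) cell, the
    predicted label, and an ``extrapolation`` flag for cells outside the
    training hull (predictions there are allowed but flagged).
    """
    tt, cc = np.meshgrid(np.asarray(tfr_grid, float), np.asarray(lipid_grid, float), indexing="ij")
    X = np.column_stack(
        [tt.ravel(), cc.ravel(), np.full(tt.size, float(va_vo)), np.full(tt.size, float(curcumin))]
    )
    labels = model.predict(X)
    extrapolation = np.zeros(tt.size, dtype=bool)
    if training_bounds is not None:
        for j, col in enumerate(FEATURE_COLUMNS):
            if col in training_bounds:
                lo, hi = training_bounds[col]
                extrapolation |= (X[:, j] < lo) | (X[:, j] > hi)
    return pd.DataFrame(
        {
            "tfr_ml_min": X[:, 0],
            "lipid_mg_ml": X[:, 1],
            "va_vo": X[:, 2],
            "curcumin": int(curcumin),
            "label": labels,
            "extrapolation": extrapolation,
        }
    )


def plot_heatmap(grid: pd.DataFrame, ax=None, experimental: pd.DataFrame | None = None):
    """Render one prediction panel; experimental points overlaid as diamonds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = sorted(grid["label"].unique())
    code = grid["label"].map({lab: i for i, lab in enumerate(labels)})
    tfr = np.sort(grid["tfr_ml_min"].unique())
    lipid = np.sort(grid["lipid_mg_ml"].unique())
    img = code.to_numpy().reshape(len(tfr), len(lipid))
    ax.pcolormesh(lipid, tfr, img, shading="nearest", cmap="viridis", vmin=0, vmax=max(1, len(labels) - 1))
    if experimental is not None and len(experimental):
        ax.scatter(
            experimental["lipid_mg_ml"], experimental["tfr_ml_min"],
            marker="D", c="white", edgecolors="black", s=30,
        )
    ax.set_xlabel("total lipid concentration (mg/ml)")
    ax.set_ylabel("TFR (ml/min)")
    return ax
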