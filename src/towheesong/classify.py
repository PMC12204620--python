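"""Species-classification evaluation harness.

Balanced and region-stratified train/test splits, pluggable classifier
backends behind one contract, permutation-null significance, per-sample
vote-confidence maps, and multi-seed confidence intervals.  The learners
themselves are off-the-shelf; this module owns splits, metrics, nulls, and
configuration echo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .geo import OverlapZone

BACKENDS = ("rf", "gbm", "mlp", "cnn", "lda")


class BackendUnavailableError(RuntimeError):
    """Raised when a backend's runtime dependency is missing."""


@dataclass
class SplitPlan:
    train_ids: np.ndarray
    test_ids: np.ndarray
    per_class_train_counts: dict[str, int]
    seed: int
    mode: str  # "random_balanced" | "region_stratified"
    test_in_zone_ids: np.ndarray | None = None
    test_out_zone_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


@dataclass
class ClassifierConfig:
    """Backend choice plus the per-backend hyperparameter echo.

    mlp layer sizes are (16, 64, 64, 2): 16 inputs, two 64-unit rectified
    hidden layers, 2 outputs (log-softmax / cross-entropy training with the
    adaptive-moment optimizer).  cnn expects 224 x 224 x 3 image tensors.
    """

    backend: str = "rf"
    seed: int = 0
    rf_n_trees: int = 500
    rf_tune: bool = False
    rf_cv_folds: int = 10
    rf_grid_shape: tuple[int, int] = (10, 16)
    gbm_max_rounds: int = 100
    gbm_early_stopping_rounds: int = 10
    mlp_hidden: tuple[int, int] = (64, 64)
    mlp_learning_rate: float = 0.001
    mlp_batch_size: int = 32
    mlp_epochs: int = 100
    cnn_input_shape: tuple[int, int, int] = (224, 224, 3)
    cnn_filters: tuple[int, ...] = (32, 128, 128, 128)
    cnn_kernel: int = 3
    cnn_dense: int = 1024
    cnn_batch_size: int = 32
    cnn_epochs: int = 10

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}")
        for name in ("rf_n_trees", "gbm_max_rounds", "mlp_epochs", "cnn_epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def layer_sizes(self) -> tuple[int, ...]:
        return (16, *self.mlp_hidden, 2)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EvalResult:
    accuracy: float
    balanced_accuracy: float
    kappa: float
    confusion: np.ndarray  # classes x classes counts, rows = truth
    perm_p: float | None
    predictions: np.ndarray
    classes: list
    config: dict = field(default_factory=dict)


@dataclass
class ConfidenceMap:
    """Per test sample: fraction of trees voting the true class + location."""

    fraction_correct: np.ndarray
    longitude: np.ndarray
    latitude: np.ndarray
    misclassified: np.ndarray


def make_balanced_split(
    labels: pd.Series,
    train_frac: float = 0.75,
    seed: int = 0,
) -> SplitPlan:
    """75/25-style split with the train set downsampled to balance classes.

    Train size is ``floor(train_frac * N)`` sampled without replacement; the
    remainder is the test set (untouched).  Within the train set the
    majority class is randomly downsampled to the minority class count.
    """
    ids = np.asarray(labels.index)
    y = labels.to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    rng = np.random.default_rng(seed)
    n = len(ids)
    n_train = math.floor(train_frac * n)
    order = rng.permutation(n)
    train_idx, test_idx = order[:n_train], order[n_train:]
    train_y = y[train_idx]
    counts = {c: int((train_y == c).sum()) for c in classes}
    if min(counts.values()) == 0:
        raise ValueError("a class is absent from the training split")
    n_min = min(counts.values())
    keep = []
    for c in classes:
        c_idx = train_idx[train_y == c]
        if len(c_idx) > n_min:
            c_idx = rng.choice(c_idx, size=n_min, replace=False)
        keep.append(c_idx)
    train_sel = np.sort(np.concatenate(keep))
    return SplitPlan(
        train_ids=ids[train_sel],
        test_ids=ids[np.sort(test_idx)],
        per_class_train_counts={str(c): n_min for c in classes},
        seed=seed,
        mode="random_balanced",
    )


def make_region_split(
    records: pd.DataFrame,
    zone: OverlapZone,
    seed: int = 0,
) -> SplitPlan:
    """Train outside the overlap zone; test in-zone and on a matched holdout.

    Training records are drawn only from outside the zone (then balanced by
    downsampling); test sets are (i) all in-zone records and (ii) an
    equal-size out-of-zone holdout disjoint from training.
    """
    ids = records["id"].to_numpy()
    lon = records["longitude"].to_numpy(dtype=float)
    y = records["species"].to_numpy()
    in_zone = np.asarray(zone.contains(lon))
    if not in_zone.any() or in_zone.all():
        raise ValueError("both regions must be non-empty")
    rng = np.random.default_rng(seed)
    in_ids = ids[in_zone]
    out_idx = np.flatnonzero(~in_zone)
    n_holdout = len(in_ids)
    if n_holdout >= len(out_idx):
        raise ValueError("in-zone count exceeds available out-of-zone holdout")
    holdout_idx = rng.choice(out_idx, size=n_holdout, replace=False)
    train_pool = np.setdiff1d(out_idx, holdout_idx)
    pool_y = y[train_pool]
    classes = np.unique(pool_y)
    if len(classes) < 2:
        raise ValueError("a class is absent from the out-of-zone training pool")
    n_min = min(int((pool_y == c).sum()) for c in classes)
    keep = []
    for c in classes:
        c_idx = train_pool[pool_y == c]
        if len(c_idx) > n_min:
            c_idx = rng.choice(c_idx, size=n_min, replace=False)
        keep.append(c_idx)
    train_sel = np.sort(np.concatenate(keep))
    test_out = ids[np.sort(holdout_idx)]
    return SplitPlan(
        train_ids=ids[train_sel],
        test_ids=np.concatenate([in_ids, test_out]),
        per_class_train_counts={str(c): n_min for c in classes},
        seed=seed,
        mode="region_stratified",
        test_in_zone_ids=in_ids,
        test_out_zone_ids=test_out,
    )


def balanced_accuracy(confusion: np.ndarray) -> float:
    """Mean of per-class recalls from a confusion table (rows = truth)."""
    c = np.asarray(confusion, dtype=float)
    row_totals = c.sum(axis=1)
    if (row_totals == 0).any():
        raise ValueError("empty class row in confusion table")
    return float(np.mean(np.diag(c) / row_totals))


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a confusion table."""
    c = np.asarray(confusion, dtype=float)
    n = c.sum()
    if n == 0:
        raise ValueError("empty confusion table")
    p_o = np.trace(c) / n
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum() / n**2)
    if p_e == 1.0:
        raise ValueError("degenerate marginals: kappa undefined")
    return float((p_o - p_e) / (1 - p_e))


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, classes) -> np.ndarray:
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        out[idx[t], idx[p]] += 1
    return out


def _build_estimator(config: ClassifierConfig):
    if config.backend == "rf":
        est = RandomForestClassifier(
            n_estimators=config.rf_n_trees, random_state=config.seed
        )
        if config.rf_tune:
            n_feat_axis, n_split_axis = config.rf_grid_shape
            grid = {
                "max_features": [max(1, round(f)) for f in np.linspace(1, 16, n_feat_axis)],
                "min_samples_split": [int(s) for s in np.linspace(2, 32, n_split_axis)],
            }
            est = GridSearchCV(est, grid, cv=config.rf_cv_folds, n_jobs=1)
        return est
    if config.backend == "gbm":
        est = GradientBoostingClassifier(
            n_estimators=config.gbm_max_rounds,
            n_iter_no_change=config.gbm_early_stopping_rounds,
            validation_fraction=0.1,
            random_state=config.seed,
        )
        return Pipeline([("scale", StandardScaler()), ("gbm", est)])
    if config.backend == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=config.mlp_hidden,
            activation="relu",
            solver="adam",
            learning_rate_init=config.mlp_learning_rate,
            batch_size=config.mlp_batch_size,
            max_iter=config.mlp_epochs,
            random_state=config.seed,
        )
        return Pipeline([("scale", StandardScaler()), ("mlp", est)])
    if config.backend == "lda":
        return LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    raise ValueError(f"unknown backend {config.backend!r}")


def train_classifier(config: ClassifierConfig, X: np.ndarray, y: np.ndarray):
    """Fit the configured backend; returns a model exposing ``predict``.

    rf/gbm/mlp/lda train on the 16-feature table (features centered and
    scaled internally for gbm and mlp); cnn trains on 224 x 224 x 3 image
    tensors and requires the optional torch runtime.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if config.backend == "cnn":
        return _train_cnn(config, X, y)
    if X.ndim != 2:
        raise ValueError(f"backend {config.backend!r} expects a 2-D feature table")
    est = _build_estimator(config)
    est.fit(X, y)
    return est


def _train_cnn(config: ClassifierConfig, X: np.ndarray, y: np.ndarray):
    expected = config.cnn_input_shape
    if X.ndim != 4 or X.shape[1:] != expected:
        raise ValueError(f"cnn accepts only n x {expected} inputs, got {X.shape}")
    try:
        import torch  # noqa: F401
    except ImportError as exc:
        raise BackendUnavailableError(
            "cnn backend requires torch, which is not installed"
        ) from exc
    from ._cnn_torch import fit_cnn  # pragma: no cover - optional runtime

    return fit_cnn(config, X, y)  # pragma: no cover


def evaluate(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    config: ClassifierConfig | None = None,
    perm_p: float | None = None,
) -> EvalResult:
    """Predict on the test set and assemble the full metric bundle."""
    y_test = np.asarray(y_test)
    pred = model.predict(np.asarray(X_test))
    classes = sorted(np.unique(np.concatenate([y_test, pred])).tolist())
    conf = confusion_matrix(y_test, pred, classes)
    return EvalResult(
        accuracy=float(np.trace(conf) / conf.sum()),
        balanced_accuracy=balanced_accuracy(conf),
        kappa=cohen_kappa(conf),
        confusion=conf,
        perm_p=perm_p,
        predictions=pred,
        classes=classes,
        config=config.to_dict() if config else {},
    )


def permutation_null(
    config: ClassifierConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    observed_accuracy: float | None = None,
) -> float:
    """Label-shuffling null: p = (1 + #{perm acc >= observed}) / (n_perm + 1).

    Training labels are shuffled each replicate, the model refit with fixed
    hyperparameters, and test accuracy recorded.  A failing replicate is
    retried once, then aborts with its index.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)
    if observed_accuracy is None:
        model = train_classifier(config, X_train, y_train)
        observed_accuracy = float(np.mean(model.predict(X_test) == y_test))
    rng = np.random.default_rng(seed)
    count = 0
    for rep in range(n_perm):
        shuffled = rng.permutation(y_train)
        for attempt in (0, 1):
            try:
                model = train_classifier(config, X_train, shuffled)
                acc = float(np.mean(model.predict(X_test) == y_test))
                break
            except Exception:
                if attempt == 1:
                    raise RuntimeError(f"permutation replicate {rep} failed twice")
        if acc >= observed_accuracy - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def rf_vote_confidence(
    model,
    X_test: np.ndarray,
    y_true: np.ndarray,
    longitude: np.ndarray,
    latitude: np.ndarray,
) -> ConfidenceMap:
    """Fraction of forest trees voting each sample's true class."""
    forest = model
    if isinstance(model, Pipeline):
        forest = model[-1]
    if isinstance(forest, GridSearchCV):
        forest = forest.best_estimator_
    if not hasattr(forest, "estimators_"):
        raise BackendUnavailableError("backend does not expose per-tree votes")
    X_test = np.asarray(X_test)
    y_true = np.asarray(y_true)
    votes = np.stack([tree.predict(X_test) for tree in forest.estimators_])
    class_of = {i: c for i, c in enumerate(forest.classes_)}
    decoded = np.vectorize(lambda v: class_of.get(v, v))(votes)
    frac = (decoded == y_true[None, :]).mean(axis=0)
    pred = forest.predict(X_test)
    return ConfidenceMap(
        fraction_correct=frac,
        longitude=np.asarray(longitude, dtype=float),
        latitude=np.asarray(latitude, dtype=float),
        misclassified=pred != y_true,
    )


def repeat_over_seeds(
    run_once: Callable[[int], float],
    n_seeds: int = 100,
    base_seed: int = 0,
) -> dict:
    """Repeat a full split+train+test pipeline across seeds.

    ``run_once(seed)`` must return an accuracy.  Returns mean accuracy with
    a normal-approximation 95% CI and every per-seed accuracy.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    seeds = [base_seed + k for k in range(n_seeds)]
    accs = []
    for s in seeds:
        try:
            accs.append(float(run_once(s)))
        except Exception as exc:
            raise RuntimeError(f"seed {s} failed: {exc}") from exc
    accs = np.asarray(accs)
    mean = float(accs.mean())
    se = float(accs.std(ddof=1) / np.sqrt(n_seeds)) if n_seeds > 1 else 0.0
    return {
        "mean_accuracy": mean,
        "ci_low": mean - 1.96 * se,
        "ci_high": mean + 1.96 * se,
        "seeds": seeds,
        "accuracies": accs.tolist(),
    }
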