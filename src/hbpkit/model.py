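"""Boosted shallow-tree ensemble ("boosted random forest").

The classifier is an adaptive-boosting loop over randomized depth-limited
decision trees.  Each round draws a bootstrap sample from the current
sample-weight distribution, fits a depth-2 tree on it (with a random sqrt-
sized feature subset considered at each split), sets the learner weight from
its weighted training error, and up-weights the misclassified samples for
the next round.  Prediction is a weighted vote of the learners; the positive
class probability is the alpha-weighted fraction of trees voting positive.

Defaults are the grid-searched operating point: 125 trees, depth 2, entropy
splits, minimum 2 samples per leaf and per split.  Turning per-tree
randomization off and setting ``n_estimators=1`` reduces the model to a
single depth-2 decision tree, which is a useful limit case for testing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

_MODEL_FORMAT = "hbpkit-model-v1"
_ERR_EPS = 1e-10


class ModelError(ValueError):
    """Raised for invalid training input, version mismatch, or corrupt model files."""


@dataclass(frozen=True)
class BoostedForestConfig:
    n_estimators: int = 125
    max_depth: int = 2
    min_samples_leaf: int = 2
    min_samples_split: int = 2
    split_criterion: str = "entropy"  # or "gini"
    per_tree_randomization: bool = True  # bootstrap + sqrt feature subsample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ModelError("n_estimators and max_depth must be >= 1")
        if min(self.min_samples_leaf, self.min_samples_split) < 1:
            raise ModelError("min_samples_* must be >= 1")
        if self.split_criterion not in ("entropy", "gini"):
            raise ModelError(f"unknown split criterion {self.split_criterion!r}")


@dataclass
class TrainedModel:
    config: BoostedForestConfig
    feature_version: str
    feature_names: list[str]
    class_order: tuple[int, int]  # (negative, positive)
    trees: list[DecisionTreeClassifier] = field(default_factory=list)
    alphas: list[float] = field(default_factory=list)
    staged_train_error: list[float] = field(default_factory=list)


def _split_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    cols = [c for c in table.columns if c != "label"]
    X = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy() if "label" in table.columns else None
    return X, y, cols


def train(table: pd.DataFrame, cfg: BoostedForestConfig = BoostedForestConfig()) -> TrainedModel:
    """Fit the boosted ensemble on a labelled feature table.

    Deterministic given ``cfg.seed``.  Requires at least two samples per
    class and finite features.
    """
    X, y, cols = _split_xy(table)
    if y is None:
        raise ModelError("feature table has no 'label' column")
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ModelError("training labels contain a single class")
    if counts.min() < 2:
        raise ModelError("need at least 2 samples per class")
    if not np.all(np.isfinite(X)):
        raise ModelError("non-finite feature values")

    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    w = np.full(n, 1.0 / n)
    y_sign = np.where(y == 1, 1, -1)

    model = TrainedModel(
        config=cfg,
        feature_version=table.attrs.get("feature_version", "untagged"),
        feature_names=cols,
        class_order=(0, 1),
    )
    vote = np.zeros(n)  # running alpha-weighted margin, for staged error
    for _ in range(cfg.n_estimators):
        tree = DecisionTreeClassifier(
            max_depth=cfg.max_depth,
            criterion=cfg.split_criterion,
            min_samples_leaf=cfg.min_samples_leaf,
            min_samples_split=cfg.min_samples_split,
            max_features="sqrt" if cfg.per_tree_randomization else None,
            random_state=int(rng.integers(2**31 - 1)),
        )
        if cfg.per_tree_randomization:
            # bootstrap: resample the training set from the weight distribution
            idx = rng.choice(n, size=n, replace=True, p=w)
            if len(np.unique(y[idx])) < 2:  # degenerate draw; weight-fit instead
                tree.fit(X, y, sample_weight=w)
            else:
                tree.fit(X[idx], y[idx])
        else:
            tree.fit(X, y, sample_weight=w)
        pred = tree.predict(X)
        mis = pred != y
        err = float(w[mis].sum())
        if err >= 0.5:
            # learner no better than chance on the weighted sample: discard it
            # and restart from uniform weights (classic boosting safeguard)
            w = np.full(n, 1.0 / n)
            continue
        err = max(err, _ERR_EPS)
        alpha = 0.5 * np.log((1.0 - err) / err)
        model.trees.append(tree)
        model.alphas.append(float(alpha))
        vote += alpha * np.where(pred == 1, 1, -1)
        model.staged_train_error.append(float(np.mean((vote >= 0) != (y_sign > 0))))
        w = w * np.exp(alpha * np.where(mis, 1.0, -1.0))
        w /= w.sum()

    if not model.trees:  # every round was chance-level; keep one plain tree
        tree = DecisionTreeClassifier(
            max_depth=cfg.max_depth,
            criterion=cfg.split_criterion,
            min_samples_leaf=cfg.min_samples_leaf,
            min_samples_split=cfg.min_samples_split,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X, y)
        model.trees.append(tree)
        model.alphas.append(1.0)
        model.staged_train_error.append(float(np.mean(tree.predict(X) != y)))
    return model


def _check_table(m: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    tag = table.attrs.get("feature_version")
    if tag is not None and m.feature_version != "untagged" and tag != m.feature_version:
        raise ModelError(
            f"feature version mismatch: model {m.feature_version!r}, table {tag!r}"
        )
    cols = [c for c in table.columns if c != "label"]
    if cols != m.feature_names:
        missing = set(m.feature_names) - set(cols)
        extra = set(cols) - set(m.feature_names)
        raise ModelError(
            f"feature columns mismatch (missing {sorted(missing)[:3]}, "
            f"extra {sorted(extra)[:3]})"
        )
    return table[cols].to_numpy(dtype=float)


def predict_proba(m: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Positive-class probability per row: alpha-weighted vote fraction."""
    X = _check_table(m, table)
    if X.shape[0] == 0:
        return np.empty(0)
    alphas = np.array(m.alphas)
    votes = np.zeros(X.shape[0])
    for tree, alpha in zip(m.trees, alphas):
        votes += alpha * (tree.predict(X) == 1)
    return votes / alphas.sum()


def predict_label(m: TrainedModel, table: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
    """Binary labels: 1 iff probability >= threshold (ties go positive)."""
    if not 0.0 <= threshold <= 1.0:
        raise ModelError(f"threshold must be in [0, 1], got {threshold}")
    return (predict_proba(m, table) >= threshold).astype(int)


def save_model(m: TrainedModel, path) -> None:
    """Serialize the model bundle (config, version tag, learner states)."""
    joblib.dump(
        {
            "format": _MODEL_FORMAT,
            "config": asdict(m.config),
            "feature_version": m.feature_version,
            "feature_names": m.feature_names,
            "class_order": m.class_order,
            "trees": m.trees,
            "alphas": m.alphas,
            "staged_train_error": m.staged_train_error,
        },
        path,
    )


def load_model(path) -> TrainedModel:
    """Load a model bundle; identical predictions to the saved model."""
    try:
        bundle = joblib.load(path)
    except Exception as exc:
        raise ModelError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(bundle, dict) or bundle.get("format") != _MODEL_FORMAT:
        raise ModelError(f"not a {_MODEL_FORMAT} bundle: {path}")
    return TrainedModel(
        config=BoostedForestConfig(**bundle["config"]),
        feature_version=bundle["feature_version"],
        feature_names=list(bundle["feature_names"]),
        class_order=tuple(bundle["class_order"]),
        trees=list(bundle["trees"]),
        alphas=list(bundle["alphas"]),
        staged_train_error=list(bundle.get("staged_train_error", [])),
    )
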