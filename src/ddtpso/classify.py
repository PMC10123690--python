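"""Dataset containers, splitting, KNN evaluation and classifier tuning.

The classifier-tuning stage mirrors the study design in which the swarm
optimizer searches a hyperparameter space to minimize validation error of a
downstream classifier; here the classifier is a pluggable scikit-learn
estimator built by a user-supplied factory (default: a small multilayer
perceptron), so the identical mechanism runs at desk scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier

from .optimizers import (
    ConfigurationError,
    OptimizerConfig,
    OptimizationResult,
    optimize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureDataset",
    "ParamSpec",
    "HyperparamSpace",
    "TunedModelResult",
    "split_train_valid_test",
    "standardize",
    "knn_classify_error",
    "kfold_evaluate",
    "decode_hyperparameters",
    "tune_classifier",
    "default_hyperparam_space",
    "default_classifier_factory",
]


@dataclass
class FeatureDataset:
    """Samples x features matrix with categorical labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels length must match the number of rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite entries")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match the number of columns")
        if not self.class_names:
            self.class_names = [str(c) for c in np.unique(self.labels)]

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def subset(self, indices: np.ndarray) -> "FeatureDataset":
        return FeatureDataset(
            self.features[indices],
            self.labels[indices],
            list(self.feature_names),
            list(self.class_names),
        )

    def select_columns(self, mask_bits: np.ndarray) -> "FeatureDataset":
        cols = np.flatnonzero(np.asarray(mask_bits).astype(bool))
        return FeatureDataset(
            self.features[:, cols],
            self.labels,
            [self.feature_names[c] for c in cols],
            list(self.class_names),
        )


def split_train_valid_test(
    dataset: FeatureDataset, seed: int
) -> tuple[FeatureDataset, FeatureDataset, FeatureDataset]:
    """Stratified split into equal thirds (sizes per class differ by <= 1).

    Within each class the shuffled indices go to train, then validation,
    then test, with any remainder assigned in that order.
    """
    rng = np.random.default_rng(seed)
    classes = np.unique(dataset.labels)
    parts: list[list[int]] = [[], [], []]
    for c in classes:
        idx = np.flatnonzero(dataset.labels == c)
        if idx.size < 3:
            raise ValueError(
                f"class {c!r} has only {idx.size} samples; need at least 3 to stratify"
            )
        rng.shuffle(idx)
        base, rem = divmod(idx.size, 3)
        sizes = [base + (1 if rem >= 1 else 0), base + (1 if rem >= 2 else 0), base]
        start = 0
        for p, size in enumerate(sizes):
            parts[p].extend(idx[start : start + size].tolist())
            start += size
    out = []
    for p in parts:
        arr = np.sort(np.asarray(p, dtype=int))
        out.append(dataset.subset(arr))
    return out[0], out[1], out[2]


def standardize(
    train_x: np.ndarray, *others: np.ndarray
) -> tuple[np.ndarray, ...]:
    """Z-score using the training mean/sd only (constant columns left centered)."""
    mean = train_x.mean(axis=0)
    sd = train_x.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return tuple((x - mean) / sd for x in (train_x, *others))


def knn_classify_error(
    train: FeatureDataset,
    evaluation: FeatureDataset,
    mask: np.ndarray | None = None,
    k: int = 5,
) -> float:
    """Misclassification rate of k-nearest-neighbor majority vote.

    Distances are Euclidean on features z-scored with training statistics;
    only the masked feature columns participate.
    """
    if k > train.n_samples:
        raise ValueError(f"k={k} exceeds training set size {train.n_samples}")
    if mask is not None:
        bits = np.asarray(mask).astype(bool)
        if bits.sum() < 1:
            raise ValueError("mask must select at least one feature")
        train_x = train.features[:, bits]
        eval_x = evaluation.features[:, bits]
    else:
        train_x = train.features
        eval_x = evaluation.features
    train_x, eval_x = standardize(train_x, eval_x)
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(train_x, train.labels)
    pred = clf.predict(eval_x)
    return float(np.mean(pred != evaluation.labels))


def _micro_confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: Sequence) -> dict:
    """One-vs-rest confusion counts summed over classes (micro-averaging)."""
    tp = tn = fp = fn = 0
    for c in classes:
        t = y_true == c
        p = y_pred == c
        tp += int(np.sum(t & p))
        tn += int(np.sum(~t & ~p))
        fp += int(np.sum(~t & p))
        fn += int(np.sum(t & ~p))
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


def kfold_evaluate(
    dataset: FeatureDataset,
    mask: np.ndarray | None,
    classifier_factory: Callable[[], object],
    k: int = 10,
    seed: int = 0,
    positive_label=None,
):
    """Stratified k-fold evaluation with confusion counts summed over folds.

    With ``positive_label`` the counts are the one-vs-rest dichotomy for that
    class (so TP+TN+FP+FN = n_samples); otherwise one-vs-rest counts are
    micro-summed over all classes. Returns ``(aggregate_report,
    aggregate_counts, fold_counts)`` where the report is computed from the
    summed counts. Metric formulas live in :mod:`ddtpso.metrics`.
    """
    from .metrics import ConfusionCounts, classification_metrics

    classes, counts = np.unique(dataset.labels, return_counts=True)
    if np.any(counts < k):
        small = classes[counts < k]
        raise ValueError(f"classes {small.tolist()} have fewer than {k} samples")
    if mask is not None:
        dataset = dataset.select_columns(mask)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_counts = []
    agg = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
    for train_idx, test_idx in skf.split(dataset.features, dataset.labels):
        train = dataset.subset(train_idx)
        test = dataset.subset(test_idx)
        train_x, test_x = standardize(train.features, test.features)
        clf = classifier_factory()
        clf.fit(train_x, train.labels)
        pred = np.asarray(clf.predict(test_x))
        if positive_label is not None:
            c = _micro_confusion(test.labels, pred, [positive_label])
        else:
            c = _micro_confusion(test.labels, pred, classes)
        fold_counts.append(ConfusionCounts(**c))
        for key in agg:
            agg[key] += c[key]
    agg_counts = ConfusionCounts(**agg)
    return classification_metrics(agg_counts), agg_counts, fold_counts


@dataclass
class ParamSpec:
    """Decode rule for one hyperparameter from a unit-interval coordinate."""

    name: str
    kind: str  # "continuous" | "grid" | "categorical"
    low: float | None = None
    high: float | None = None
    log: bool = False
    choices: list | None = None

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.low is None or self.high is None:
                raise ConfigurationError(f"{self.name}: continuous params need low/high")
            if self.log and (self.low <= 0 or self.high <= 0):
                raise ConfigurationError(f"{self.name}: log scale requires positive bounds")
        elif self.kind in ("grid", "categorical"):
            if not self.choices:
                raise ConfigurationError(f"{self.name}: grid/categorical params need choices")
        else:
            raise ConfigurationError(f"{self.name}: unknown kind {self.kind!r}")

    def decode(self, x: float) -> object:
        x = min(max(float(x), 0.0), 1.0)
        if self.kind == "continuous":
            if self.log:
                return math.exp(
                    math.log(self.low) + x * (math.log(self.high) - math.log(self.low))
                )
            return self.low + x * (self.high - self.low)
        idx = min(int(x * len(self.choices)), len(self.choices) - 1)
        return self.choices[idx]


HyperparamSpace = list[ParamSpec]


def decode_hyperparameters(vector: np.ndarray, space: HyperparamSpace) -> dict:
    """Map a point of the unit box to a named hyperparameter set."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape[0] != len(space):
        raise ValueError("vector length must equal the space dimension")
    return {spec.name: spec.decode(v) for spec, v in zip(space, vector)}


def default_hyperparam_space() -> HyperparamSpace:
    """Learning rate, hidden width, L2 strength and batch size for the MLP stand-in."""
    return [
        ParamSpec("learning_rate", "continuous", 1e-4, 1e-1, log=True),
        ParamSpec("hidden_width", "grid", choices=[8, 16, 32, 64]),
        ParamSpec("alpha", "continuous", 1e-6, 1e-1, log=True),
        ParamSpec("batch_size", "grid", choices=[16, 32, 64]),
    ]


def default_classifier_factory(params: dict):
    return MLPClassifier(
        hidden_layer_sizes=(int(params["hidden_width"]),),
        learning_rate_init=float(params["learning_rate"]),
        alpha=float(params["alpha"]),
        batch_size=int(params["batch_size"]),
        max_iter=300,
        random_state=0,
    )


@dataclass
class TunedModelResult:
    best_params: dict
    best_vector: np.ndarray
    validation_error: float
    history: list[float]
    test_report: object | None = None
    test_counts: object | None = None
    optimizer_result: OptimizationResult | None = None

    def to_dict(self) -> dict:
        from dataclasses import asdict

        out = {
            "best_params": {k: (float(v) if isinstance(v, float) else v) for k, v in self.best_params.items()},
            "best_vector": [float(v) for v in self.best_vector],
            "validation_error": float(self.validation_error),
            "history": [float(v) for v in self.history],
        }
        if self.test_report is not None:
            out["test_report"] = asdict(self.test_report)
        if self.test_counts is not None:
            out["test_counts"] = asdict(self.test_counts)
        return out


def tune_classifier(
    dataset: FeatureDataset,
    mask: np.ndarray | None,
    space: HyperparamSpace,
    optimizer_config: OptimizerConfig,
    classifier_factory: Callable[[dict], object] = default_classifier_factory,
    seed: int | None = None,
) -> TunedModelResult:
    """Minimize validation error over the hyperparameter unit box with DDTPSO.

    The dataset is split into stratified thirds; candidates are trained on
    the training third and scored on the validation third. Training failures
    score as worst fitness. The winning configuration is refit on
    train+validation and reported on the held-out test third.
    """
    from dataclasses import replace as dc_replace

    from .metrics import classification_metrics

    seed = optimizer_config.seed if seed is None else seed
    if mask is not None:
        dataset = dataset.select_columns(mask)
    train, valid, test = split_train_valid_test(dataset, seed)
    train_x, valid_x = standardize(train.features, valid.features)

    cache: dict[tuple, float] = {}

    def objective(x: np.ndarray) -> float:
        params = decode_hyperparameters(x, space)
        key = tuple(sorted(params.items()))
        if key in cache:
            return cache[key]
        try:
            clf = classifier_factory(params)
            clf.fit(train_x, train.labels)
            err = float(np.mean(np.asarray(clf.predict(valid_x)) != valid.labels))
        except Exception:  # noqa: BLE001 - training failure counts as worst fitness
            logger.warning("classifier training failed for %s", params, exc_info=True)
            err = math.inf
        cache[key] = err
        return err

    config = dc_replace(optimizer_config, bounds=(0.0, 1.0), seed=seed)
    result = optimize(objective, len(space), config)
    best_params = decode_hyperparameters(result.best_position, space)

    # final fit on train+valid, report on the untouched test third
    fit_x = np.vstack([train.features, valid.features])
    fit_y = np.concatenate([train.labels, valid.labels])
    fit_x, test_x = standardize(fit_x, test.features)
    clf = classifier_factory(best_params)
    clf.fit(fit_x, fit_y)
    pred = np.asarray(clf.predict(test_x))
    classes = np.unique(dataset.labels)
    counts_dict = _micro_confusion(test.labels, pred, classes)
    from .metrics import ConfusionCounts

    counts = ConfusionCounts(**counts_dict)
    report = classification_metrics(counts)
    return TunedModelResult(
        best_params=best_params,
        best_vector=np.asarray(result.best_position),
        validation_error=result.best_fitness,
        history=result.best_history,
        test_report=report,
        test_counts=counts,
        optimizer_result=result,
    )
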