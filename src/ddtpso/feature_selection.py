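"""Binary wrapper feature selection (bDDTPSO).

The continuous hybrid optimizer searches the unit box [0, 1]^d; each
candidate position is squashed componentwise by a steep logistic transfer
function and thresholded to a binary feature-inclusion mask, which is scored
by a k-nearest-neighbor wrapper fitness

    fitness = alpha * validation_error + (1 - alpha) * selected_fraction

so selection trades predictive error against subset size. The continuous
population is never overwritten with bits; binarization happens at
evaluation time only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .classify import FeatureDataset, knn_classify_error, split_train_valid_test
from .optimizers import ConfigurationError, OptimizerConfig, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMask",
    "FSConfig",
    "FSRunResult",
    "sigmoid_transfer",
    "binarize",
    "fs_fitness",
    "select_features",
    "exhaustive_best_mask",
    "random_mask_select",
    "run_fs_experiment",
]


@dataclass
class FeatureMask:
    """Binary inclusion vector over features (1 = feature selected)."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits).astype(np.int8)
        if self.bits.ndim != 1:
            raise ValueError("mask bits must be a 1-D vector")
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("mask bits must be 0/1")

    @property
    def selected_count(self) -> int:
        return int(self.bits.sum())

    @property
    def selected_fraction(self) -> float:
        return self.selected_count / self.bits.size

    def key(self) -> bytes:
        return self.bits.tobytes()

    def to_dict(self, feature_names: Sequence[str] | None = None) -> dict:
        out = {
            "bits": self.bits.tolist(),
            "selected_count": self.selected_count,
            "selected_fraction": self.selected_fraction,
        }
        if feature_names is not None:
            out["selected_features"] = [
                feature_names[i] for i in np.flatnonzero(self.bits)
            ]
        return out


@dataclass
class FSConfig:
    """Feature-selection configuration.

    ``sigmoid_slope``/``sigmoid_center`` parameterize the logistic transfer
    F(s) = 1 / (1 + exp(-slope * (s - center))); a component is selected when
    F(s) >= threshold (inclusive). ``alpha`` weights validation error against
    the selected-feature fraction in the wrapper fitness; ``knn_k`` is the
    neighbor count of the wrapper classifier.
    """

    sigmoid_slope: float = 10.0
    sigmoid_center: float = 0.5
    threshold: float = 0.50
    alpha: float = 0.99
    knn_k: int = 5
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    n_runs: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ConfigurationError("threshold must lie strictly in (0, 1)")
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError("alpha must lie in (0, 1]")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ConfigurationError("knn_k must be a positive odd integer")


@dataclass
class FSRunResult:
    best_mask: FeatureMask
    best_fitness: float
    error_rate: float
    fitness_history: list[float]
    seed: int

    def to_dict(self, feature_names: Sequence[str] | None = None) -> dict:
        return {
            "best_mask": self.best_mask.to_dict(feature_names),
            "best_fitness": float(self.best_fitness),
            "error_rate": float(self.error_rate),
            "fitness_history": [float(v) for v in self.fitness_history],
            "seed": int(self.seed),
        }


def sigmoid_transfer(component, config: FSConfig | None = None):
    """Logistic transfer of a continuous solution component into (0, 1)."""
    config = config or FSConfig()
    return expit(config.sigmoid_slope * (np.asarray(component, dtype=float) - config.sigmoid_center))


def binarize(solution: np.ndarray, config: FSConfig | None = None) -> FeatureMask:
    """Threshold the transferred components into a mask (>= is inclusive)."""
    config = config or FSConfig()
    values = sigmoid_transfer(solution, config)
    return FeatureMask((values >= config.threshold).astype(np.int8))


def fs_fitness(
    mask: FeatureMask,
    train: FeatureDataset,
    valid: FeatureDataset,
    config: FSConfig,
) -> tuple[float, float]:
    """Wrapper fitness of a mask: weighted KNN error plus size penalty.

    Returns ``(fitness, error)``. An all-zero mask gets the +inf sentinel so
    it can never become the incumbent best.
    """
    if mask.selected_count == 0:
        logger.debug("all-zero mask scored with +inf sentinel")
        return math.inf, math.inf
    err = knn_classify_error(train, valid, mask.bits, k=config.knn_k)
    fitness = config.alpha * err + (1.0 - config.alpha) * mask.selected_fraction
    return fitness, err


def _validate_dataset(dataset: FeatureDataset) -> None:
    if dataset.n_features < 2:
        raise ConfigurationError("feature selection needs at least 2 features")
    if np.unique(dataset.labels).size < 2:
        raise ConfigurationError("feature selection needs at least 2 classes")


def select_features(
    dataset: FeatureDataset,
    config: FSConfig,
    seed: int | None = None,
) -> FSRunResult:
    """One seeded bDDTPSO run over the full loop.

    Splits the dataset into stratified thirds, runs the continuous hybrid
    optimizer on [0, 1]^d against the binarized wrapper fitness, and returns
    the best mask found together with its validation error and the best-so-far
    fitness history. Fitness values are cached per distinct mask.
    """
    _validate_dataset(dataset)
    seed = config.optimizer.seed if seed is None else seed
    train, valid, _test = split_train_valid_test(dataset, seed)
    d = dataset.n_features

    cache: dict[bytes, tuple[float, float]] = {}

    def objective(x: np.ndarray) -> float:
        mask = binarize(x, config)
        key = mask.key()
        if key not in cache:
            cache[key] = fs_fitness(mask, train, valid, config)
        return cache[key][0]

    opt_config = replace(config.optimizer, bounds=(0.0, 1.0), seed=seed)
    result = optimize(objective, d, opt_config)
    best_mask = binarize(result.best_position, config)
    _, err = cache[best_mask.key()]
    return FSRunResult(
        best_mask=best_mask,
        best_fitness=float(result.best_fitness),
        error_rate=float(err),
        fitness_history=result.best_history,
        seed=seed,
    )


def exhaustive_best_mask(
    dataset: FeatureDataset, config: FSConfig, seed: int
) -> tuple[FeatureMask, float]:
    """Brute-force optimum over all 2^d - 1 non-empty masks (oracle, d <= ~12).

    Uses the same stratified split and wrapper fitness as
    :func:`select_features` so the two are directly comparable.
    """
    _validate_dataset(dataset)
    d = dataset.n_features
    if d > 16:
        raise ValueError("exhaustive search is intended for small d")
    train, valid, _ = split_train_valid_test(dataset, seed)
    best_mask = None
    best_fit = math.inf
    for code in range(1, 2**d):
        bits = np.array([(code >> i) & 1 for i in range(d)], dtype=np.int8)
        mask = FeatureMask(bits)
        fit, _err = fs_fitness(mask, train, valid, config)
        if fit < best_fit:
            best_fit = fit
            best_mask = mask
    return best_mask, best_fit


def random_mask_select(
    dataset: FeatureDataset,
    config: FSConfig,
    seed: int | None = None,
    n_candidates: int = 50,
) -> FSRunResult:
    """Baseline "method": best of uniformly random masks (Bernoulli 1/2 bits).

    Uses the same split and fitness as :func:`select_features` so the
    comparison isolates the search strategy.
    """
    _validate_dataset(dataset)
    seed = config.optimizer.seed if seed is None else seed
    train, valid, _ = split_train_valid_test(dataset, seed)
    rng = np.random.default_rng(seed)
    d = dataset.n_features
    best = None
    history: list[float] = []
    for _ in range(n_candidates):
        bits = rng.integers(0, 2, size=d).astype(np.int8)
        mask = FeatureMask(bits)
        fit, err = fs_fitness(mask, train, valid, config)
        if best is None or fit < best[1]:
            best = (mask, fit, err)
        history.append(best[1])
    mask, fit, err = best
    return FSRunResult(
        best_mask=mask,
        best_fitness=float(fit),
        error_rate=float(err),
        fitness_history=history,
        seed=seed,
    )


FSMethod = Callable[[FeatureDataset, FSConfig, int], FSRunResult]


def run_fs_experiment(
    dataset: FeatureDataset,
    methods: dict[str, FSMethod],
    n_runs: int,
    seed_base: int,
    config: FSConfig | None = None,
) -> dict[str, list[FSRunResult]]:
    """Run each method ``n_runs`` times with seeds seed_base .. seed_base+n_runs-1.

    Every method sees the identical seed sequence, so differences reflect the
    search strategy rather than the draw of splits.
    """
    config = config or FSConfig()
    results: dict[str, list[FSRunResult]] = {}
    for name, method in methods.items():
        results[name] = [
            method(dataset, config, seed_base + j) for j in range(n_runs)
        ]
    return results
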