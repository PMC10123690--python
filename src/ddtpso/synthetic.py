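"""Synthetic stand-ins for the study's data.

Three generators:

* :func:`gen_feature_dataset` emulates deep global-average-pooling feature
  tables: class-informative Gaussian columns, redundant linear combinations
  of them, and pure-noise columns, with a recorded column permutation and the
  ground-truth informative index set.
* :func:`gen_synthetic_images` produces class-textured grayscale images
  (class-specific blob counts and an orientation ramp) that are deliberately
  asymmetric under flips, so augmentation yields distinct variants.
* :func:`benchmark_objective` returns standard test objectives (sphere,
  rastrigin, rosenbrock) with their known optima for optimizer validation.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import FeatureDataset

__all__ = [
    "SyntheticSpec",
    "gen_feature_dataset",
    "standard_dataset_spec",
    "gen_synthetic_images",
    "benchmark_objective",
]


@dataclass
class SyntheticSpec:
    """Specification of a synthetic feature table.

    ``class_separation`` is the between-class mean shift in units of the
    within-class standard deviation (1.0); ``redundancy_noise_sd`` is the
    Gaussian noise added to each redundant linear combination.
    """

    n_samples: int = 200
    n_informative: int = 5
    n_redundant: int = 3
    n_noise: int = 12
    n_classes: int = 2
    class_separation: float = 3.0
    redundancy_noise_sd: float = 0.1
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("need at least one informative feature")
        if self.n_informative + self.n_redundant + self.n_noise < 2:
            raise ValueError("need at least two features in total")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def standard_dataset_spec(**overrides) -> SyntheticSpec:
    """The default fixture used across examples and experiments."""
    return SyntheticSpec(**overrides)


def gen_feature_dataset(spec: SyntheticSpec) -> tuple[FeatureDataset, np.ndarray]:
    """Generate a feature table; returns (dataset, informative column indices).

    Labels are balanced (class counts differ by at most 1). Informative
    columns are class-conditional Gaussians with unit within-class sd and
    class means 0, s, 2s, ... (s = class_separation); redundant columns are
    random linear combinations of the informative block plus noise; noise
    columns are standard normal. Columns are then shuffled by a recorded
    permutation, and the returned index set refers to post-shuffle positions.
    """
    rng = np.random.default_rng(spec.seed)
    n, c = spec.n_samples, spec.n_classes
    labels = np.array([i % c for i in range(n)])
    rng.shuffle(labels)

    informative = rng.normal(size=(n, spec.n_informative))
    informative += spec.class_separation * labels[:, None]

    blocks = [informative]
    if spec.n_redundant:
        weights = rng.normal(size=(spec.n_informative, spec.n_redundant))
        weights /= np.linalg.norm(weights, axis=0, keepdims=True)
        redundant = informative @ weights
        redundant += rng.normal(scale=spec.redundancy_noise_sd, size=redundant.shape)
        blocks.append(redundant)
    if spec.n_noise:
        blocks.append(rng.normal(size=(n, spec.n_noise)))
    features = np.hstack(blocks)

    d = spec.n_features
    permutation = rng.permutation(d)
    features = features[:, permutation]
    # post-shuffle positions of the original informative columns
    informative_idx = np.sort(np.array([int(np.where(permutation == j)[0][0]) for j in range(spec.n_informative)]))

    names = [""] * d
    for new_pos, orig in enumerate(permutation):
        if orig < spec.n_informative:
            kind = "inf"
        elif orig < spec.n_informative + spec.n_redundant:
            kind = "red"
        else:
            kind = "noise"
        names[new_pos] = f"{kind}_{orig}"
    class_names = [f"class_{i}" for i in range(c)]
    dataset = FeatureDataset(
        features,
        np.array([class_names[v] for v in labels]),
        names,
        class_names,
    )
    return dataset, informative_idx


def gen_synthetic_images(
    class_counts: dict[str, int],
    height: int = 64,
    width: int = 64,
    seed: int = 0,
) -> dict[str, list[np.ndarray]]:
    """Generate grayscale images grouped by class.

    Each class gets a characteristic number of Gaussian blobs plus a
    class-oriented intensity ramp; a horizontal gradient component makes
    every image asymmetric under horizontal flip so augmented variants are
    pixel-distinct. Pixel values are floats in [0, 1].
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    out: dict[str, list[np.ndarray]] = {}
    for class_idx, (label, count) in enumerate(class_counts.items()):
        if count < 1:
            raise ValueError(f"class {label!r} needs a positive count")
        n_blobs = class_idx + 2
        images = []
        for _ in range(count):
            img = np.zeros((height, width))
            for _b in range(n_blobs):
                cy = rng.uniform(0.15, 0.85) * height
                cx = rng.uniform(0.15, 0.85) * width
                s = rng.uniform(0.05, 0.15) * min(height, width)
                img += np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2)))
            # oriented ramp: breaks flip symmetry and encodes the class angle
            angle = class_idx * np.pi / (2 * max(1, len(class_counts) - 1))
            ramp = np.cos(angle) * xx / width + np.sin(angle) * yy / height
            img += 0.5 * ramp + 0.3 * (xx / width)
            img += rng.normal(scale=0.02, size=img.shape)
            lo, hi = img.min(), img.max()
            images.append((img - lo) / (hi - lo))
        out[label] = images
    return out


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(np.square(x)))


def _rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def _rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def benchmark_objective(name: str, dim: int):
    """Return ``(objective, optimum_position, optimum_value)`` by name."""
    if dim < 1:
        raise ValueError("dim must be at least 1")
    table = {
        "sphere": (_sphere, np.zeros(dim)),
        "rastrigin": (_rastrigin, np.zeros(dim)),
        "rosenbrock": (_rosenbrock, np.ones(dim)),
    }
    if name not in table:
        raise ValueError(f"unknown objective {name!r}; choose from {sorted(table)}")
    fn, optimum = table[name]
    return fn, optimum, 0.0
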