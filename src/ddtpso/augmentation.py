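"""Class-balancing image augmentation by flips and 90-degree rotation.

Each class is grown to a fixed per-class quota using only horizontal flip,
vertical flip and counter-clockwise 90-degree rotation. The three operations
generate the dihedral symmetry group of the square (8 elements), so each
source image yields at most 7 distinct non-identity variants; transforms are
enumerated in a fixed order and cycled round-robin over source images, and
only when the pool of distinct symmetries is exhausted are exact duplicates
emitted (with a logged warning). Every augmented record carries the ordered
op chain that produced it, so provenance can be replayed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ImageRecord",
    "AugmentationSpec",
    "hflip",
    "vflip",
    "rot90",
    "apply_ops",
    "distinct_symmetry_chains",
    "augment_to_quota",
]

OPS = ("hflip", "vflip", "rot90")


def hflip(image: np.ndarray) -> np.ndarray:
    """Reverse column order (mirror about the vertical axis)."""
    return np.asarray(image)[:, ::-1].copy()


def vflip(image: np.ndarray) -> np.ndarray:
    """Reverse row order (mirror about the horizontal axis)."""
    return np.asarray(image)[::-1, :].copy()


def rot90(image: np.ndarray) -> np.ndarray:
    """Rotate counter-clockwise by 90 degrees."""
    return np.rot90(np.asarray(image)).copy()


_OP_FUNCS = {"hflip": hflip, "vflip": vflip, "rot90": rot90}


def apply_ops(image: np.ndarray, ops: Sequence[str]) -> np.ndarray:
    """Apply an op chain left to right."""
    out = np.asarray(image)
    for op in ops:
        out = _OP_FUNCS[op](out)
    return out


def distinct_symmetry_chains(max_len: int = 3) -> list[tuple[str, ...]]:
    """Op chains realizing the 7 distinct non-identity square symmetries.

    Chains are enumerated by increasing length, then lexicographically by op
    name order (hflip, vflip, rot90); a chain is kept only if its action on a
    canonical asymmetric marker image is new. The result is deterministic.
    """
    marker = np.arange(16).reshape(4, 4)
    seen = {marker.tobytes()}
    chains: list[tuple[str, ...]] = []
    for length in range(1, max_len + 1):
        for chain in itertools.product(OPS, repeat=length):
            key = apply_ops(marker, chain).tobytes()
            if key not in seen:
                seen.add(key)
                chains.append(chain)
        if len(chains) == 7:
            break
    return chains


@dataclass
class ImageRecord:
    """One grayscale image with its class and augmentation provenance."""

    pixels: np.ndarray
    class_label: str
    provenance: str = "original"  # "original" | "augmented"
    ops: tuple[str, ...] = ()
    source_index: int | None = None


@dataclass
class AugmentationSpec:
    ops: tuple[str, ...] = OPS
    per_class_quota: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.ops) - set(OPS)
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
        if self.per_class_quota < 1:
            raise ValueError("per_class_quota must be positive")


def augment_to_quota(
    images_by_class: dict[str, list[np.ndarray]],
    spec: AugmentationSpec,
) -> dict[str, list[ImageRecord]]:
    """Grow every class to exactly ``spec.per_class_quota`` images.

    Originals are always retained (pixel-identical). New records cycle over
    (transform, source) pairs: for each distinct symmetry chain in fixed
    order, every source image is transformed in turn; once the 7 distinct
    symmetries per source are exhausted the cycle restarts, producing exact
    duplicates, and a warning is logged.
    """
    chains = distinct_symmetry_chains()
    out: dict[str, list[ImageRecord]] = {}
    for label, images in images_by_class.items():
        if not images:
            raise ValueError(f"class {label!r} has no images")
        n = len(images)
        if spec.per_class_quota < n:
            raise ValueError(
                f"class {label!r}: quota {spec.per_class_quota} below current count {n}"
            )
        records = [
            ImageRecord(np.asarray(img), label, "original", (), i)
            for i, img in enumerate(images)
        ]
        needed = spec.per_class_quota - n
        pool_size = len(chains) * n
        if needed > pool_size:
            logger.warning(
                "class %r: quota requires %d augmented images but only %d distinct "
                "symmetry variants exist; exact duplicates will be emitted",
                label,
                needed,
                pool_size,
            )
        for j in range(needed):
            k = j % pool_size
            chain = chains[k // n]
            src = k % n
            pixels = apply_ops(images[src], chain)
            records.append(ImageRecord(pixels, label, "augmented", chain, src))
        out[label] = records
    return out
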