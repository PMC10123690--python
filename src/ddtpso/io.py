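"""Readers and writers: feature CSVs, mask JSON, image trees, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import FeatureDataset
from .feature_selection import FeatureMask

__all__ = [
    "load_feature_csv",
    "save_feature_csv",
    "save_mask_json",
    "load_mask_json",
    "write_image_tree",
    "read_image_tree",
    "load_yaml_config",
]


def load_feature_csv(path: str | Path, label_col: str) -> FeatureDataset:
    """Load a samples x features table with one designated label column.

    Fails loudly: a missing label column, duplicate feature names, or any
    non-numeric feature cell raise distinct errors (no silent NaN coercion).
    Row order is preserved.
    """
    path = Path(path)
    # inspect the raw header: pandas silently renames duplicate columns
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    dupes = [c for c in set(header) if header.count(c) > 1]
    if dupes:
        raise ValueError(f"duplicate feature names in {path.name}: {sorted(dupes)}")
    df = pd.read_csv(path, float_precision="round_trip")
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found in {path.name}")
    feature_cols = [c for c in df.columns if c != label_col]
    features = np.empty((len(df), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(values.isna())[0])
            raise ValueError(
                f"non-numeric or missing value in feature column {col!r} at row {row}"
            )
        features[:, j] = values.to_numpy()
    labels = df[label_col].astype(str).to_numpy()
    return FeatureDataset(features, labels, feature_cols)


def save_feature_csv(dataset: FeatureDataset, path: str | Path, label_col: str = "label") -> Path:
    path = Path(path)
    df = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    df[label_col] = dataset.labels
    df.to_csv(path, index=False)
    return path


def save_mask_json(mask: FeatureMask, path: str | Path, feature_names=None, extra: dict | None = None) -> Path:
    path = Path(path)
    payload = {"schema_version": 1, **mask.to_dict(feature_names)}
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_mask_json(path: str | Path) -> FeatureMask:
    payload = json.loads(Path(path).read_text())
    return FeatureMask(np.asarray(payload["bits"], dtype=np.int8))


def write_image_tree(records_by_class: dict, out_dir: str | Path) -> Path:
    """Write `class/NNNN.png` trees (pixels scaled to uint8) plus a manifest."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    manifest = {"schema_version": 1, "classes": {}}
    for label, records in records_by_class.items():
        class_dir = out_dir / str(label)
        class_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for i, rec in enumerate(records):
            pixels = np.asarray(rec.pixels, dtype=float)
            lo, hi = pixels.min(), pixels.max()
            scale = (hi - lo) if hi > lo else 1.0
            img8 = np.round(255 * (pixels - lo) / scale).astype(np.uint8)
            name = f"{i:05d}.png"
            iio.imwrite(class_dir / name, img8)
            entries.append(
                {
                    "file": name,
                    "provenance": rec.provenance,
                    "ops": list(rec.ops),
                    "source_index": rec.source_index,
                }
            )
        manifest["classes"][str(label)] = entries
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir


def read_image_tree(in_dir: str | Path) -> dict[str, list[np.ndarray]]:
    """Read a `class/*.png` tree into float arrays grouped by class."""
    import imageio.v3 as iio

    in_dir = Path(in_dir)
    out: dict[str, list[np.ndarray]] = {}
    for class_dir in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        images = [
            np.asarray(iio.imread(f), dtype=float)
            for f in sorted(class_dir.glob("*.png"))
        ]
        if images:
            out[class_dir.name] = images
    if not out:
        raise ValueError(f"no class subdirectories with PNG images under {in_dir}")
    return out


def load_yaml_config(path: str | Path, allowed_keys: set[str] | None = None) -> dict:
    """Load a YAML mapping, rejecting unknown top-level keys when given."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    if allowed_keys is not None:
        unknown = set(data) - allowed_keys
        if unknown:
            raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return data
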