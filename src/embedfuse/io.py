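"""Readers for external dataset formats.

* NPZ image bundles in the MedMNIST layout: keys ``train_images``,
  ``train_labels``, ``val_images``, ``val_labels``, ``test_images``,
  ``test_labels``.  Labels are integer class indices (single-label; a
  trailing singleton axis is squeezed) or multi-hot 0/1 matrices
  (multi-label).
* CSV label tables: header ``sample_id,label`` for single-label tasks, or
  ``sample_id,l0,l1,...`` with 0/1 entries for multi-label tasks.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import EmbeddingSet
from .registry import ModelSpec

# bundle key -> canonical split name
_NPZ_SPLITS = {"train": "train", "val": "valid", "test": "test"}


def load_npz_bundle(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Load an NPZ image bundle: split name -> (images, labels)."""
    with np.load(path) as npz:
        out = {}
        for raw, split in _NPZ_SPLITS.items():
            images = np.asarray(npz[f"{raw}_images"])
            labels = np.asarray(npz[f"{raw}_labels"])
            if labels.ndim == 2 and labels.shape[1] == 1:
                labels = labels[:, 0]
            out[split] = (images, labels.astype(np.int64))
    return out


def flatten_pixels_provider(path: str | Path, model_name: str = "flatten"):
    """A trivial provider: each image's flattened pixel vector is its embedding.

    Useful as a no-download baseline and for exercising the full pipeline on
    real image bundles.  Returns ``(spec, provider)`` ready for registration.
    """
    bundle = load_npz_bundle(path)
    images, _ = bundle["train"]
    dim = int(np.prod(images.shape[1:]))
    spec = ModelSpec(name=model_name, dim=dim, modality="pixels")

    def provider(split: str) -> EmbeddingSet:
        images, labels = bundle[split]
        n = images.shape[0]
        return EmbeddingSet(
            model_name=model_name,
            split=split,
            X=images.reshape(n, -1).astype(np.float64),
            sample_ids=np.array([f"{split}-{i:06d}" for i in range(n)]),
            labels=labels,
        )

    return spec, provider


def load_label_table(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a CSV label table: returns (sample_ids, labels).

    A two-column ``sample_id,label`` table yields integer class indices; a
    wider ``sample_id,l0,l1,...`` table yields a multi-hot 0/1 matrix.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    ids = df["sample_id"].to_numpy().astype(str)
    value_cols = [c for c in df.columns if c != "sample_id"]
    if not value_cols:
        raise ValueError(f"{path}: no label columns")
    if len(value_cols) == 1:
        return ids, df[value_cols[0]].to_numpy().astype(np.int64)
    labels = df[value_cols].to_numpy().astype(np.int64)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError(f"{path}: multi-label entries must be 0/1")
    return ids, labels


def save_label_table(path: str | Path, sample_ids: np.ndarray,
                     labels: np.ndarray) -> None:
    """Write a label table in the format :func:`load_label_table` reads."""
    labels = np.asarray(labels)
    if labels.ndim == 1:
        df = pd.DataFrame({"sample_id": sample_ids, "label": labels})
    else:
        df = pd.DataFrame(labels,
                          columns=[f"l{j}" for j in range(labels.shape[1])])
        df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, index=False)
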