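"""On-disk embedding cache.

The exhaustive subset search evaluates up to ``2^n - 1`` model combinations
but needs each model's embeddings only once per split; the cache makes that
economy explicit.  Blocks are persisted as NPY arrays with a JSON manifest
beside them (sample IDs, labels, dims, key fields and an array checksum), so
a cached dataset is self-describing and human-inspectable.

Layout: ``<cache_root>/<dataset_id>/<model_name>/<split>.npy`` plus
``<split>.manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .embeddings import EmbeddingSet
from .errors import CacheIntegrityError
from .registry import ModelSpec, Registry


def content_tag(provider_version: str, dataset_fingerprint: str) -> str:
    """First 12 hex digits of SHA-256 over provider version + fingerprint."""
    digest = hashlib.sha256(
        f"{provider_version}\x00{dataset_fingerprint}".encode()
    ).hexdigest()
    return digest[:12]


@dataclass(frozen=True)
class CacheKey:
    """Identifies one cached block: (model, dataset, split) plus a content tag.

    The tag distinguishes different provider versions or dataset revisions
    that would otherwise collide on the same path.
    """

    model_name: str
    dataset_id: str
    split: str
    content_tag: str = ""

    def relpath(self) -> Path:
        stem = self.split if not self.content_tag else f"{self.split}.{self.content_tag}"
        return Path(self.dataset_id) / self.model_name / f"{stem}.npy"


class EmbeddingCache:
    """Filesystem cache of embedding blocks keyed by :class:`CacheKey`.

    ``enabled=False`` turns the cache into a pass-through: every
    :meth:`get_or_extract` call invokes the provider.
    """

    def __init__(self, root: str | Path, enabled: bool = True) -> None:
        self.root = Path(root)
        self.enabled = enabled
        # in-process memo: provider invoked at most once per key per process
        self._memo: dict[CacheKey, EmbeddingSet] = {}

    def _paths(self, key: CacheKey) -> tuple[Path, Path]:
        arr = self.root / key.relpath()
        return arr, arr.with_suffix("").with_suffix(".manifest.json")

    def store(self, key: CacheKey, emb: EmbeddingSet) -> Path:
        """Persist a block; returns the array path. Idempotent per key."""
        if emb.n_samples == 0:
            raise ValueError("refusing to cache an empty embedding block")
        arr_path, man_path = self._paths(key)
        arr_path.parent.mkdir(parents=True, exist_ok=True)
        np.save(arr_path, emb.X)
        manifest = {
            "model_name": key.model_name,
            "dataset_id": key.dataset_id,
            "split": key.split,
            "content_tag": key.content_tag,
            "n_samples": int(emb.n_samples),
            "dim": int(emb.dim),
            "dtype": str(emb.X.dtype),
            "array_sha256": hashlib.sha256(
                np.ascontiguousarray(emb.X).tobytes()
            ).hexdigest(),
            "sample_ids": [str(s) for s in emb.sample_ids],
            "labels": None if emb.labels is None else emb.labels.tolist(),
        }
        man_path.write_text(json.dumps(manifest))
        return arr_path

    def load(self, key: CacheKey) -> EmbeddingSet | None:
        """Load a block, validating it against the manifest.

        Returns ``None`` when the key is absent; raises
        :class:`CacheIntegrityError` when array and manifest disagree —
        corruption is never silently treated as a miss.
        """
        arr_path, man_path = self._paths(key)
        if not arr_path.exists() or not man_path.exists():
            return None
        manifest = json.loads(man_path.read_text())
        try:
            X = np.load(arr_path)
        except Exception as exc:
            raise CacheIntegrityError(f"unreadable array at {arr_path}: {exc}") from exc
        if X.shape != (manifest["n_samples"], manifest["dim"]):
            raise CacheIntegrityError(
                f"{arr_path}: array shape {X.shape} does not match manifest "
                f"({manifest['n_samples']}, {manifest['dim']})"
            )
        digest = hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()
        if digest != manifest["array_sha256"]:
            raise CacheIntegrityError(f"{arr_path}: checksum mismatch")
        labels = manifest["labels"]
        return EmbeddingSet(
            model_name=manifest["model_name"],
            split=manifest["split"],
            X=X,
            sample_ids=np.array(manifest["sample_ids"]),
            labels=None if labels is None else np.array(labels),
        )

    def get_or_extract(
        self, registry: Registry, key: CacheKey, split: str | None = None
    ) -> EmbeddingSet:
        """Return the cached block, extracting (and storing) on a miss.

        Within one process the provider is invoked at most once per key; the
        disk copy extends that guarantee across processes.
        """
        split = split if split is not None else key.split
        if not self.enabled:
            return registry.extract_embeddings(key.model_name, split)
        if key in self._memo:
            return self._memo[key]
        cached = self.load(key)
        if cached is None:
            cached = registry.extract_embeddings(key.model_name, split)
            self.store(key, cached)
        self._memo[key] = cached
        return cached

    def store_dataset(self, dataset, dataset_id: str) -> None:
        """Persist every (model, split) block of a synthetic dataset."""
        for (model_name, split), emb in dataset.embeddings.items():
            self.store(CacheKey(model_name=model_name, dataset_id=dataset_id,
                                split=split), emb)


def registry_from_cache(cache: EmbeddingCache, dataset_id: str) -> Registry:
    """Build a registry whose providers read straight from a populated cache.

    Model order is the lexicographic order of the model directories under
    ``<cache_root>/<dataset_id>/`` — write datasets with zero-padded model
    names when the generation order matters.
    """
    base = cache.root / dataset_id
    if not base.is_dir():
        raise FileNotFoundError(f"no cached dataset at {base}")
    registry = Registry()
    for model_dir in sorted(p for p in base.iterdir() if p.is_dir()):
        manifests = sorted(model_dir.glob("*.manifest.json"))
        if not manifests:
            continue
        first = json.loads(manifests[0].read_text())
        name = model_dir.name

        def provider(split: str, _name=name) -> EmbeddingSet:
            emb = cache.load(CacheKey(model_name=_name, dataset_id=dataset_id,
                                      split=split))
            if emb is None:
                raise FileNotFoundError(
                    f"no cached block for ({_name}, {dataset_id}, {split})"
                )
            return emb

        registry.register(
            ModelSpec(name=name, dim=int(first["dim"]), modality="cached"),
            provider,
        )
    return registry
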