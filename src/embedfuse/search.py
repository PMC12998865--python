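"""Exhaustive model-subset search.

Every non-empty subset of the registered pool (``2^n - 1`` candidates for
``n`` models) is fused and scored with the fixed probing classifier on
validation accuracy; the best subset wins.  Within a subset, blocks are
always concatenated in registry order — the order is fixed once at
registration and never permuted, since jointly optimising subsets *and*
orders (``n!`` per subset) is intractable and order effects are negligible
for a tree-based probe.

Selection uses validation accuracy only; AUC is reported downstream but never
drives the choice.  Ties break toward fewer models (a cheaper embedding
generator at equal score), then earlier enumeration order.  The
``singles_only`` mode restricts candidates to the ``n`` singletons; its
winner is the best single backbone ("oracle-single").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .cache import CacheKey, EmbeddingCache
from .embeddings import EmbeddingSet
from .errors import EmbedFuseError, UnknownModelError
from .fusion import (
    AttentionFusionConfig,
    AttentionFusionModel,
    FusedEmbeddings,
    attention_fuse_apply,
    attention_fuse_fit,
    concat_fuse,
)
from .probe import ProbeConfig, fit_probe, probe_accuracy
from .registry import Registry


def enumerate_subsets(n: int, mode: str = "exhaustive") -> list[tuple[int, ...]]:
    """All candidate subsets as index tuples, in the canonical order.

    Exhaustive: every non-empty subset exactly once, by increasing size then
    lexicographic position, each subset's internal order ascending (registry
    order).  ``singles_only``: the ``n`` singletons.
    """
    if n < 1:
        raise ValueError("need at least one registered model")
    if mode == "singles_only":
        return [(i,) for i in range(n)]
    if mode != "exhaustive":
        raise ValueError(f"unknown search mode '{mode}'")
    out: list[tuple[int, ...]] = []
    for size in range(1, n + 1):
        out.extend(combinations(range(n), size))
    return out


@dataclass
class Evaluation:
    """One scored subset."""

    subset: tuple[str, ...]
    valid_accuracy: float
    fused_dim: int
    status: str = "ok"  # "ok" or "failed: <reason>"


@dataclass
class SearchResult:
    """Full leaderboard of a subset search plus the selected winner."""

    evaluations: list[Evaluation]
    selected: tuple[str, ...]
    n_evaluated: int
    mode: str
    seed: int
    dataset_id: str = "dataset"
    fusion: str = "concat"
    attention_model: AttentionFusionModel | None = field(default=None, repr=False)

    @property
    def selected_accuracy(self) -> float:
        for ev in self.evaluations:
            if ev.subset == self.selected:
                return ev.valid_accuracy
        raise KeyError("selected subset missing from evaluations")

    def best_singleton_accuracy(self) -> float:
        singles = [ev.valid_accuracy for ev in self.evaluations
                   if len(ev.subset) == 1 and ev.status == "ok"]
        return max(singles) if singles else float("nan")

    def to_dataframe(self) -> pd.DataFrame:
        """Leaderboard, best first: ``rank,subset,fused_dim,valid_accuracy,status``."""
        ok = [ev for ev in self.evaluations if ev.status == "ok"]
        failed = [ev for ev in self.evaluations if ev.status != "ok"]
        ok.sort(key=lambda ev: -ev.valid_accuracy)
        rows = []
        for rank, ev in enumerate(ok + failed, start=1):
            rows.append({
                "rank": rank,
                "subset": "+".join(ev.subset),
                "fused_dim": ev.fused_dim,
                "valid_accuracy": ev.valid_accuracy,
                "status": ev.status,
            })
        return pd.DataFrame(rows)


class _BlockFetcher:
    """Fetches blocks through the cache, or a process-local memo without one."""

    def __init__(self, registry: Registry, dataset_id: str,
                 cache: EmbeddingCache | None):
        self.registry = registry
        self.dataset_id = dataset_id
        self.cache = cache
        self._memo: dict[tuple[str, str], EmbeddingSet] = {}

    def get(self, model_name: str, split: str) -> EmbeddingSet:
        if self.cache is not None:
            key = CacheKey(model_name=model_name, dataset_id=self.dataset_id,
                           split=split)
            return self.cache.get_or_extract(self.registry, key)
        memo_key = (model_name, split)
        if memo_key not in self._memo:
            self._memo[memo_key] = self.registry.extract_embeddings(model_name, split)
        return self._memo[memo_key]


def run_search(
    registry: Registry,
    dataset_id: str = "dataset",
    probe_config: ProbeConfig | None = None,
    mode: str = "exhaustive",
    seed: int = 0,
    cache: EmbeddingCache | None = None,
    fusion: str = "concat",
    attention_config: AttentionFusionConfig | None = None,
) -> SearchResult:
    """Score every candidate subset and select the validation-accuracy winner.

    Each subset is fused (concatenation by default; ``fusion="self_attention"``
    re-fits the attention block per subset), the fixed probe is fit on the
    train split, and validation accuracy is recorded.  A failing subset is
    recorded as failed and skipped; the search aborts only if every subset
    fails.  One probe seed is used during search; run-averaging is reserved
    for final test evaluation.
    """
    if len(registry) < 1:
        raise ValueError("registry is empty")
    probe_config = replace(probe_config or ProbeConfig(), seed=seed)
    names = registry.names
    fetcher = _BlockFetcher(registry, dataset_id, cache)

    evaluations: list[Evaluation] = []
    best: tuple[float, int, int] | None = None  # (-acc, size, position)
    best_idx = -1
    best_att: AttentionFusionModel | None = None
    for pos, idx in enumerate(enumerate_subsets(len(names), mode)):
        subset = tuple(names[i] for i in idx)
        try:
            train_blocks = [fetcher.get(m, "train") for m in subset]
            valid_blocks = [fetcher.get(m, "valid") for m in subset]
            train_labels = train_blocks[0].labels
            valid_labels = valid_blocks[0].labels
            att_model = None
            if fusion == "self_attention":
                att_cfg = attention_config or AttentionFusionConfig(seed=seed)
                att_model = attention_fuse_fit(
                    train_blocks, train_labels, att_cfg, valid_blocks, valid_labels
                )
                train_fused = attention_fuse_apply(att_model, train_blocks)
                valid_fused = attention_fuse_apply(att_model, valid_blocks)
            else:
                train_fused = concat_fuse(train_blocks)
                valid_fused = concat_fuse(valid_blocks)
            probe = fit_probe(train_fused, train_labels, probe_config)
            acc = probe_accuracy(probe, valid_fused, valid_labels)
            ev = Evaluation(subset=subset, valid_accuracy=acc,
                            fused_dim=train_fused.dim)
        except EmbedFuseError as exc:
            evaluations.append(Evaluation(
                subset=subset, valid_accuracy=float("nan"),
                fused_dim=sum(registry.spec(m).dim for m in subset),
                status=f"failed: {exc}"))
            continue
        evaluations.append(ev)
        key = (-acc, len(subset), pos)
        if best is None or key < best:
            best, best_idx, best_att = key, len(evaluations) - 1, att_model

    if best is None:
        raise EmbedFuseError("all subset evaluations failed")
    return SearchResult(
        evaluations=evaluations,
        selected=evaluations[best_idx].subset,
        n_evaluated=len(evaluations),
        mode=mode,
        seed=seed,
        dataset_id=dataset_id,
        fusion=fusion,
        attention_model=best_att,
    )


@dataclass
class FusionModel:
    """The configured embedding generator for a selected model subset.

    Given any split, it extracts the selected models' blocks (through the
    cache when one is attached) and fuses them with the fitted strategy,
    yielding embeddings laid out exactly as during the search.
    """

    registry: Registry
    selected: tuple[str, ...]
    dataset_id: str = "dataset"
    fusion: str = "concat"
    cache: EmbeddingCache | None = None
    attention_model: AttentionFusionModel | None = None

    def __post_init__(self) -> None:
        missing = [m for m in self.selected if m not in self.registry]
        if missing:
            raise UnknownModelError(f"selected models not registered: {missing}")
        if self.fusion == "self_attention" and self.attention_model is None:
            raise ValueError("self_attention fusion requires a fitted attention model")
        self._fetcher = _BlockFetcher(self.registry, self.dataset_id, self.cache)

    @property
    def fused_dim(self) -> int:
        if self.fusion == "self_attention":
            return self.attention_model.config.proj_dim
        return sum(self.registry.spec(m).dim for m in self.selected)

    def transform(self, split: str) -> FusedEmbeddings:
        blocks = [self._fetcher.get(m, split) for m in self.selected]
        if self.fusion == "self_attention":
            return attention_fuse_apply(self.attention_model, blocks)
        return concat_fuse(blocks)


def build_fusion_model(
    result: SearchResult,
    registry: Registry,
    cache: EmbeddingCache | None = None,
) -> FusionModel:
    """Turn a search winner into a reusable embedding generator."""
    if not result.selected:
        raise ValueError("search result has an empty selection")
    return FusionModel(
        registry=registry,
        selected=result.selected,
        dataset_id=result.dataset_id,
        fusion=result.fusion,
        cache=cache,
        attention_model=result.attention_model,
    )


def search_space_size(n: int, mode: str = "exhaustive") -> int:
    """Number of candidate subsets: ``2^n - 1`` exhaustive, ``n`` singles."""
    if n < 1:
        raise ValueError("need at least one model")
    return n if mode == "singles_only" else 2**n - 1
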