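"""Fusion of per-model embedding blocks into a single representation.

Two strategies:

* **Concatenation** (default): parameter-free stacking of blocks along the
  feature dimension.  For blocks ``e_i`` of width ``d_i`` the fused vector is
  ``[e_1; e_2; ...; e_n]`` of width ``sum(d_i)``.  Each model's features stay
  in an isolated, recoverable sub-block, and no cross-model normalisation is
  applied — a tree-based downstream classifier splits on feature *order*, not
  magnitude, so heterogeneous scales across blocks are harmless.  An optional
  per-block z-scoring flag exists for other downstream learners; it defaults
  off.

* **Multi-head self-attention** (learnable alternative): each block is
  linearly projected to a common width ``proj_dim = d_head * n_heads``,
  forming one token per model; scaled dot-product self-attention mixes the
  tokens; the mean over tokens is the fused vector.  The block is trained
  end-to-end with a temporary linear softmax head under cross-entropy (Adam),
  and the head is discarded after training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import attention as _att
from .embeddings import EmbeddingSet, check_aligned
from .errors import AlignmentError, ConfigError

DEFAULT_HEAD_DIM = 64
HEAD_SWEEP = (4, 8, 12)  # head counts swept when selecting proj_dim


@dataclass
class FusedEmbeddings:
    """The combined representation for a model subset.

    ``blocks`` records the sub-block layout as ``(model_name, offset, dim)``
    triples for concatenation; it is empty for attention fusion, whose output
    has no per-model columns.
    """

    matrix: np.ndarray
    blocks: list[tuple[str, int, int]]
    strategy: str  # "concat" | "self_attention"
    sample_ids: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def sub_block(self, model_name: str) -> np.ndarray:
        """Columns of one model's sub-block (concat strategy only)."""
        for name, offset, dim in self.blocks:
            if name == model_name:
                return self.matrix[:, offset : offset + dim]
        raise KeyError(f"no sub-block for model '{model_name}'")


def concat_fuse(
    blocks: Sequence[EmbeddingSet], zscore_blocks: bool = False
) -> FusedEmbeddings:
    """Concatenate blocks along the feature dimension.

    The fused width is the sum of the block widths; block ``i`` occupies
    columns ``[offset_i, offset_i + d_i)`` where offsets are cumulative sums
    in the order given (callers pass blocks in registry order).  Blocks must
    share identical sample IDs in identical order.
    """
    blocks = list(blocks)
    if not blocks:
        raise AlignmentError("cannot fuse an empty sequence of blocks")
    check_aligned(blocks)
    mats = []
    layout: list[tuple[str, int, int]] = []
    offset = 0
    for blk in blocks:
        X = blk.X
        if zscore_blocks:
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd
        mats.append(X)
        layout.append((blk.model_name, offset, blk.dim))
        offset += blk.dim
    return FusedEmbeddings(
        matrix=np.concatenate(mats, axis=1),
        blocks=layout,
        strategy="concat",
        sample_ids=blocks[0].sample_ids,
        labels=blocks[0].labels,
    )


@dataclass
class AttentionFusionConfig:
    """Training controls for the self-attention fusion block.

    ``proj_dim`` is always ``d_head * n_heads``; at the default head width of
    64 the swept head counts (4, 8, 12) give 256, 512 and 768.
    """

    n_heads: int = 8
    d_head: int = DEFAULT_HEAD_DIM
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 64
    patience: int = 10  # early-stopping patience on validation accuracy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_heads < 1:
            raise ConfigError("n_heads must be >= 1")
        if self.d_head < 1:
            raise ConfigError("d_head must be >= 1")

    @property
    def proj_dim(self) -> int:
        return self.n_heads * self.d_head


@dataclass
class AttentionFusionModel:
    """A trained self-attention fusion block, reusable on new splits."""

    config: AttentionFusionConfig
    model_names: list[str]
    dims: list[int]
    params: dict = field(repr=False, default_factory=dict)

    def _check_blocks(self, blocks: Sequence[EmbeddingSet]) -> None:
        names = [b.model_name for b in blocks]
        dims = [b.dim for b in blocks]
        if names != self.model_names or dims != self.dims:
            raise AlignmentError(
                f"blocks do not match fitted model: expected "
                f"{list(zip(self.model_names, self.dims))}, got "
                f"{list(zip(names, dims))}"
            )


def attention_fuse_fit(
    blocks: Sequence[EmbeddingSet],
    labels: np.ndarray,
    config: AttentionFusionConfig,
    valid_blocks: Sequence[EmbeddingSet] | None = None,
    valid_labels: np.ndarray | None = None,
) -> AttentionFusionModel:
    """Fit the attention fusion block on training blocks.

    Training minimises cross-entropy of a temporary linear head on the pooled
    output, with Adam; if a validation split is given, early stopping keeps
    the parameters of the best validation-accuracy epoch.  Deterministic
    given ``config.seed``.
    """
    blocks = list(blocks)
    if not blocks:
        raise AlignmentError("cannot fit attention fusion on zero blocks")
    check_aligned(blocks)
    labels = np.asarray(labels)
    valid = None
    if valid_blocks is not None:
        valid_blocks = list(valid_blocks)
        check_aligned(valid_blocks)
        valid = ([b.X for b in valid_blocks], np.asarray(valid_labels))
    params = _att.train(
        [b.X for b in blocks],
        labels,
        n_heads=config.n_heads,
        d_head=config.d_head,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        patience=config.patience,
        seed=config.seed,
        valid=valid,
    )
    return AttentionFusionModel(
        config=config,
        model_names=[b.model_name for b in blocks],
        dims=[b.dim for b in blocks],
        params=params,
    )


def attention_fuse_apply(
    model: AttentionFusionModel, blocks: Sequence[EmbeddingSet]
) -> FusedEmbeddings:
    """Apply a trained fusion block: ``n_samples x proj_dim`` pooled output."""
    blocks = list(blocks)
    check_aligned(blocks)
    model._check_blocks(blocks)
    pooled = _att.fuse(model.params, [b.X for b in blocks])
    return FusedEmbeddings(
        matrix=pooled,
        blocks=[],
        strategy="self_attention",
        sample_ids=blocks[0].sample_ids,
        labels=blocks[0].labels,
    )


def sweep_attention_heads(
    blocks: Sequence[EmbeddingSet],
    labels: np.ndarray,
    valid_blocks: Sequence[EmbeddingSet],
    valid_labels: np.ndarray,
    head_counts: Sequence[int] = HEAD_SWEEP,
    d_head: int = DEFAULT_HEAD_DIM,
    score_fn=None,
    **config_kwargs,
) -> tuple[AttentionFusionModel, list[tuple[int, float]]]:
    """Select ``proj_dim`` by sweeping head counts, keeping the best on validation.

    ``score_fn(train_fused, train_labels, valid_fused, valid_labels) -> float``
    scores each candidate; the default trains the fixed probing classifier
    and returns validation accuracy.  Returns the winning model and the
    ``(n_heads, score)`` log.
    """
    if score_fn is None:
        from .probe import ProbeConfig, fit_probe, probe_accuracy

        def score_fn(tr, tr_y, va, va_y):  # noqa: ANN001
            probe = fit_probe(tr, tr_y, ProbeConfig())
            return probe_accuracy(probe, va, va_y)

    best_model, best_score = None, -np.inf
    log: list[tuple[int, float]] = []
    for h in head_counts:
        cfg = AttentionFusionConfig(n_heads=h, d_head=d_head, **config_kwargs)
        model = attention_fuse_fit(blocks, labels, cfg, valid_blocks, valid_labels)
        tr = attention_fuse_apply(model, blocks)
        va = attention_fuse_apply(model, valid_blocks)
        score = score_fn(tr, np.asarray(labels), va, np.asarray(valid_labels))
        log.append((h, float(score)))
        if score > best_score:
            best_model, best_score = model, score
    assert best_model is not None
    return best_model, log
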