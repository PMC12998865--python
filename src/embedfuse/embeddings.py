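"""The in-memory container for one model's embeddings of one dataset split.

An :class:`EmbeddingSet` couples an ``n_samples x dim`` real matrix with the
sample IDs and labels of the split it was extracted from.  Sample order is
significant: fusion concatenates blocks row-by-row, so all blocks entering a
fusion must carry identical IDs in identical order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError


@dataclass
class EmbeddingSet:
    """One provider's embedding matrix for one dataset split.

    Parameters
    ----------
    model_name
        Name of the provider that produced the block.
    split
        Split identifier, conventionally ``train``, ``valid`` or ``test``.
    X
        ``(n_samples, dim)`` float matrix.
    sample_ids
        Length-``n_samples`` array of unique sample identifiers, in row order.
    labels
        Length-``n_samples`` integer class indices, or an
        ``(n_samples, n_labels)`` 0/1 matrix for multi-label tasks.
    """

    model_name: str
    split: str
    X: np.ndarray
    sample_ids: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        self.sample_ids = np.asarray(self.sample_ids)
        if self.sample_ids.shape[0] != self.X.shape[0]:
            raise AlignmentError(
                f"{self.sample_ids.shape[0]} sample IDs for {self.X.shape[0]} rows"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.X.shape[0]:
                raise AlignmentError(
                    f"{self.labels.shape[0]} labels for {self.X.shape[0]} rows"
                )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]


def check_aligned(blocks: list[EmbeddingSet]) -> None:
    """Verify that all blocks share identical sample IDs in identical order.

    Raises :class:`AlignmentError` naming the first mismatching ID.
    """
    if not blocks:
        raise AlignmentError("no blocks given")
    ref = blocks[0]
    for blk in blocks[1:]:
        if blk.n_samples != ref.n_samples:
            raise AlignmentError(
                f"block '{blk.model_name}' has {blk.n_samples} rows, "
                f"'{ref.model_name}' has {ref.n_samples}"
            )
        mismatch = np.nonzero(blk.sample_ids != ref.sample_ids)[0]
        if mismatch.size:
            i = int(mismatch[0])
            raise AlignmentError(
                f"sample IDs differ at row {i}: "
                f"'{ref.sample_ids[i]}' ({ref.model_name}) vs "
                f"'{blk.sample_ids[i]}' ({blk.model_name})"
            )
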