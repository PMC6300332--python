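"""Temporal aggregation of count networks and count-to-binary conversion.

Aggregation at level ``W`` sums non-overlapping blocks of ``W`` consecutive
unit-width adjacency matrices, so the ``m``-th aggregated matrix covers the
original-time interval ``((m-1)W, mW]``.  Binarization converts a count cell
to an indicator ``1{count >= threshold}``; when both are requested the
package always binarizes *after* aggregating (B^(W) = binarize(C^(W))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError
from .model import NetworkSequence

__all__ = ["AggregationSpec", "aggregate", "binarize", "density"]


@dataclass(frozen=True)
class AggregationSpec:
    """How a unit-width count sequence is prepared for monitoring."""

    level: int = 1
    output_type: str = "count"
    binarize_threshold: int = 1

    def __post_init__(self):
        if self.level < 1:
            raise InvalidParameterError("aggregation level must be >= 1")
        if self.binarize_threshold < 1:
            raise InvalidParameterError("binarize threshold must be >= 1")
        if self.output_type not in ("count", "binary"):
            raise InvalidParameterError("output_type must be 'count' or 'binary'")

    def apply(self, seq: NetworkSequence) -> NetworkSequence:
        out = aggregate(seq, self.level)
        if self.output_type == "binary":
            out = binarize(out, self.binarize_threshold)
        return out


def aggregate(seq: NetworkSequence, level: int) -> NetworkSequence:
    """Sum non-overlapping blocks of ``level`` consecutive matrices.

    The sequence length must be divisible by ``level``: silent truncation
    would corrupt the bookkeeping of which original periods each aggregated
    matrix covers, so a remainder is a hard error.  Total counts are
    conserved exactly.
    """
    if level < 1:
        raise InvalidParameterError("aggregation level must be >= 1")
    T = len(seq)
    if T % level:
        raise InvalidInputError(
            f"sequence length {T} is not divisible by aggregation level {level}"
        )
    if level == 1:
        return NetworkSequence(data=seq.data.copy(), step_width=seq.step_width,
                               start_time=seq.start_time, data_type=seq.data_type)
    n = seq.order
    summed = seq.data.reshape(T // level, level, n, n).sum(axis=1)
    return NetworkSequence(data=summed, step_width=seq.step_width * level,
                           start_time=seq.start_time, data_type="count")


def binarize(seq: NetworkSequence, threshold: int = 1) -> NetworkSequence:
    """Indicator conversion: cell becomes 1 iff its count is >= ``threshold``.

    At the default threshold 1 this records whether any communication
    occurred at all; it is idempotent there, since an indicator is itself a
    count that is >= 1 exactly when it is 1.
    """
    if threshold < 1:
        raise InvalidParameterError("binarize threshold must be >= 1")
    if (seq.data < 0).any():
        raise InvalidInputError("counts must be non-negative")
    return NetworkSequence(data=(seq.data >= threshold).astype(np.int64),
                           step_width=seq.step_width, start_time=seq.start_time,
                           data_type="binary")


def density(matrix: np.ndarray) -> float:
    """Proportion of potential node pairs that are connected in a binary
    adjacency matrix: ``|E| / (|V| (|V|-1) / 2)``."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError("expected a square adjacency matrix")
    if not (m == m.T).all():
        raise InvalidInputError("adjacency matrix must be symmetric")
    if np.diag(m).any():
        raise InvalidInputError("diagonal must be zero")
    if not np.isin(m, (0, 1)).all():
        raise InvalidInputError("density is defined for binary matrices")
    n = m.shape[0]
    if n < 2:
        raise InvalidInputError("density needs at least two nodes")
    return float(np.triu(m, k=1).sum() / (n * (n - 1) / 2))
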