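"""Priebe's moving-window scan method for dynamic-network surveillance.

For each network snapshot three locality statistics are computed per node
``i``: the degree ``O^0`` (total communications to or from ``i``) and the
sizes ``O^1``, ``O^2`` of its first and second neighborhoods — the summed
edge weight among all nodes within graph distance 1 (resp. 2) of ``i`` in
the support graph (an edge is present iff its count is >= 1).  The node
itself belongs to every one of its neighborhoods, so ``O^0 <= O^1 <= O^2``.

Each per-node series is standardized against the mean and standard
deviation of the previous ``width`` observations (divisor ``width - 1``,
denominator floored at 1), the per-time maximum over nodes is taken, and the
three maximum series are standardized the same way a second time.  A signal
is raised at time ``t`` when ``max(M*_t^0, M*_t^1, M*_t^2)`` reaches the
signaling threshold.  Two stacked windows mean the first signalable index is
``2 * width + 1``; with the default width 20 the method needs a minimum of
40 snapshots of history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import InsufficientHistoryError, InvalidInputError, InvalidParameterError
from .model import NetworkSequence

__all__ = [
    "ScanConfig",
    "ScanResult",
    "neighborhood_stats",
    "windowed_standardize",
    "scan_sequence",
]

ORDERS = (0, 1, 2)


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: window width 20 and signaling threshold 4 are the
    values used throughout the surveillance literature this package follows."""

    window_width: int = 20
    signal_threshold: float = 4.0

    def __post_init__(self):
        if self.window_width < 2:
            raise InvalidParameterError("window_width must be >= 2")

    @property
    def min_length(self) -> int:
        """Shortest sequence with at least one signalable index."""
        return 2 * self.window_width + 1


@dataclass
class ScanResult:
    """Everything the scan computed for one sequence.

    Arrays are indexed by sequence position (0-based); entries before the
    warm-up of each stage are NaN (statistics) or False (flags), never
    zero-filled.  ``signal_times`` are in original time units
    (``start_time + (index + 1) * step_width``).
    """

    raw_node_stats: np.ndarray          # (T, n, 3)  O^k
    standardized_node_stats: np.ndarray  # (T, n, 3)  O*^k, NaN for t < width
    max_stats: np.ndarray                # (T, 3)     M^k,  NaN for t < width
    standardized_max_stats: np.ndarray   # (T, 3)     M*^k, NaN for t < 2*width
    signal_flags: np.ndarray             # (T,) bool
    step_width: int
    start_time: int
    config: ScanConfig

    @property
    def monitored_indices(self) -> np.ndarray:
        """0-based indices where a signal decision is available."""
        return np.arange(2 * self.config.window_width, len(self.signal_flags))

    @property
    def signal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.signal_flags)

    @property
    def signal_times(self) -> np.ndarray:
        """Original-time stamps (interval end points) of the flagged indices."""
        return self.start_time + (self.signal_indices + 1) * self.step_width


def _support_neighborhoods(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean membership matrices of the closed 1- and 2-neighborhoods.

    ``C`` is a stack (T, n, n).  Row ``i`` of each output marks the nodes at
    support-graph distance <= 1 (resp. <= 2) from ``i``, including ``i``.
    """
    n = C.shape[-1]
    A1 = (C >= 1) | np.eye(n, dtype=bool)
    # reach in <= 2 steps: one step from anything one step away (incl. self)
    A2 = np.matmul(A1.astype(np.uint8), A1.astype(np.uint8)) > 0
    return A1, A2


def _stats_stack(C: np.ndarray) -> np.ndarray:
    """O^k for k = 0, 1, 2 on a stack of matrices; returns (T, n, 3)."""
    C = C.astype(np.float64, copy=False)
    A1, A2 = _support_neighborhoods(C)
    out = np.empty(C.shape[:2] + (3,))
    out[..., 0] = C.sum(axis=-1)
    for k, M in ((1, A1), (2, A2)):
        Mf = M.astype(np.float64)
        # sum over ordered pairs (a, b) in N_k(i); diagonal is zero and C is
        # symmetric, so halving gives the unordered-pair edge-weight total
        out[..., k] = 0.5 * np.einsum("tia,tab,tib->ti", Mf, C, Mf, optimize=True)
    return out


def neighborhood_stats(matrix: np.ndarray, order: int | None = None) -> np.ndarray:
    """Per-node locality statistics of a single adjacency matrix.

    Returns the length-``n`` vector ``O^order`` if ``order`` is given, else
    an ``(n, 3)`` array with columns ``O^0, O^1, O^2``.  For binary data
    ``O^0`` is the neighbor count and ``O^1``/``O^2`` induced edge counts;
    for count data all three are weighted sums, so the binary case is the
    special case of unit weights.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError("expected a square adjacency matrix")
    if (m < 0).any():
        raise InvalidInputError("entries must be non-negative")
    if not (m == m.T).all():
        raise InvalidInputError("adjacency matrix must be symmetric")
    if np.diag(m).any():
        raise InvalidInputError("diagonal must be zero")
    stats = _stats_stack(m[None])[0]
    if order is None:
        return stats
    if order not in ORDERS:
        raise InvalidParameterError(f"neighborhood order must be one of {ORDERS}")
    return stats[:, order]


def windowed_standardize(series: np.ndarray, width: int) -> np.ndarray:
    """Standardize each point against the previous ``width`` points.

    Output at index ``t`` is ``(x_t - mean(x[t-width:t])) / max(sd, 1)``
    with the sample standard deviation (divisor ``width - 1``) of the same
    window.  Indices with fewer than ``width`` predecessors are NaN.  The
    unit floor on the denominator keeps flat stretches (sd 0, or tiny) from
    exploding the statistic.  Works along axis 0 of any-dimensional input.
    """
    if width < 2:
        raise InvalidParameterError("window width must be >= 2")
    x = np.asarray(series, dtype=np.float64)
    T = x.shape[0]
    out = np.full_like(x, np.nan)
    if T <= width:
        return out
    # windows[j] views x[j : j+width]; index t uses windows[t - width]
    win = np.moveaxis(sliding_window_view(x, width, axis=0), -1, 1)[: T - width]
    mean = win.mean(axis=1)
    sd = win.std(axis=1, ddof=1)
    out[width:] = (x[width:] - mean) / np.maximum(sd, 1.0)
    return out


def scan_sequence(seq: NetworkSequence, config: ScanConfig | None = None) -> ScanResult:
    """Run the full two-stage scan over a network sequence.

    Raises :class:`InsufficientHistoryError` if the sequence is shorter than
    ``2 * width + 1`` points (41 at the default width), the minimum needed
    to stack the two standardization windows and monitor one point.
    """
    config = config or ScanConfig()
    w = config.window_width
    T = len(seq)
    if T < config.min_length:
        raise InsufficientHistoryError(
            f"scan needs at least {config.min_length} matrices "
            f"(2 x window {w} of history plus one monitored point); got {T}"
        )
    seq.validate()
    O = _stats_stack(seq.data)                      # (T, n, 3)
    Ostar = windowed_standardize(O, w)              # NaN for t < w
    M = np.full((T, 3), np.nan)
    M[w:] = Ostar[w:].max(axis=1)
    Mstar = np.full((T, 3), np.nan)
    Mstar[2 * w:] = windowed_standardize(M[w:], w)[w:]
    flags = np.zeros(T, dtype=bool)
    flags[2 * w:] = np.nanmax(Mstar[2 * w:], axis=1) >= config.signal_threshold
    return ScanResult(
        raw_node_stats=O,
        standardized_node_stats=Ostar,
        max_stats=M,
        standardized_max_stats=Mstar,
        signal_flags=flags,
        step_width=seq.step_width,
        start_time=seq.start_time,
        config=config,
    )
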