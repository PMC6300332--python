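"""Degree-corrected stochastic block model (DCSBM) network-sequence simulator.

The model: nodes are partitioned into ``R`` communities; node ``i`` carries a
degree propensity ``theta_i > 0`` and communities ``r, r'`` a block propensity
``P[r, r']``.  Conditional on membership, the number of communications
between nodes ``i != j`` in one unit time period is Poisson with mean

    lambda_ij = theta_i * theta_j * P[r(i), r(j)].

Identifiability is imposed by scaling ``theta`` so that it sums to the
community size within each community.  An anomaly is a sustained
multiplicative shift of one community's within-block propensity starting
after a configurable shift time: the last baseline period is ``tau`` and the
first anomalous period is ``tau + 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "CommunityStructure",
    "DegreePropensity",
    "BlockPropensity",
    "RateMatrix",
    "ShiftSpec",
    "NetworkSequence",
    "draw_degree_propensities",
    "build_block_matrix",
    "apply_shift",
    "compute_rates",
    "generate_sequence",
]


@dataclass(frozen=True)
class CommunityStructure:
    """Partition of the node set into communities.

    Communities are numbered ``1..R`` and community 1 is, by convention, the
    community that receives the anomalous shift.  Nodes are assigned in
    blocks: the first ``sizes[0]`` nodes to community 1, and so on.
    """

    sizes: tuple[int, ...]

    def __post_init__(self):
        if not self.sizes or any(int(s) < 1 for s in self.sizes):
            raise InvalidParameterError("community sizes must all be >= 1")
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))

    @property
    def num_communities(self) -> int:
        return len(self.sizes)

    @property
    def order(self) -> int:
        """Number of nodes |V|."""
        return sum(self.sizes)

    @property
    def membership(self) -> np.ndarray:
        """Community label (1-based) per node, shape ``(|V|,)``."""
        return np.repeat(np.arange(1, len(self.sizes) + 1), self.sizes)

    def community_slice(self, r: int) -> slice:
        """Node-index slice for community ``r`` (1-based)."""
        if not 1 <= r <= self.num_communities:
            raise InvalidParameterError(f"community {r} not in 1..{self.num_communities}")
        start = sum(self.sizes[: r - 1])
        return slice(start, start + self.sizes[r - 1])


@dataclass(frozen=True)
class DegreePropensity:
    """Per-node communication propensities theta, normalised per community.

    ``raw_theta`` holds the i.i.d. Pareto draws theta'; ``theta`` is the
    rescaled vector satisfying sum_{i in r} theta_i = |V_r| for every
    community r.
    """

    theta: np.ndarray
    raw_theta: np.ndarray
    pareto_scale: float
    pareto_shape: float


@dataclass(frozen=True)
class BlockPropensity:
    """Symmetric R x R matrix of between-community communication propensities."""

    P: np.ndarray
    baseline_diag: float
    homophily_ratio: float

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise InvalidInputError("block propensity matrix must be square")
        if not np.allclose(P, P.T):
            raise InvalidInputError("block propensity matrix must be symmetric")
        object.__setattr__(self, "P", P)

    @property
    def num_communities(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class RateMatrix:
    """Dense |V| x |V| matrix of Poisson rates lambda_ij; zero diagonal."""

    lam: np.ndarray

    @property
    def total_rate(self) -> float:
        """Sum of lambda over unordered node pairs."""
        return float(np.triu(self.lam, k=1).sum())


@dataclass(frozen=True)
class ShiftSpec:
    """A sustained multiplicative shift in one community's within-propensity.

    ``shift_time`` (tau) is the last baseline unit-time index; period
    ``tau + 1`` is the first anomalous one and the shift never reverts.  The
    shifted propensity is ``(1 + shift_fraction) * P[target, target]``.
    """

    shift_fraction: float
    shift_time: int
    target_community: int = 1

    def __post_init__(self):
        if self.shift_fraction < 0:
            raise InvalidParameterError("shift_fraction must be >= 0")
        if self.target_community < 1:
            raise InvalidParameterError("target_community is a 1-based community index")


@dataclass
class NetworkSequence:
    """Ordered sequence of symmetric zero-diagonal adjacency matrices.

    ``data`` has shape ``(T, |V|, |V|)`` with non-negative integer entries.
    Matrix ``t`` (1-based) summarises communications over the original-time
    interval ``(start_time + (t-1)*W, start_time + t*W]`` where
    ``W = step_width``.
    """

    data: np.ndarray
    step_width: int = 1
    start_time: int = 0
    data_type: str = "count"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise InvalidInputError("expected an array of square matrices (T, n, n)")
        if self.step_width < 1:
            raise InvalidParameterError("step_width must be >= 1")
        if self.data_type not in ("count", "binary"):
            raise InvalidParameterError("data_type must be 'count' or 'binary'")

    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, t: int) -> np.ndarray:
        return self.data[t]

    @property
    def order(self) -> int:
        return self.data.shape[1]

    def end_times(self) -> np.ndarray:
        """Original-time end point of each matrix's covering interval."""
        T = len(self)
        return self.start_time + self.step_width * np.arange(1, T + 1)

    def validate(self) -> None:
        """Raise unless every matrix is symmetric, non-negative and zero-diagonal."""
        d = self.data
        if not np.issubdtype(d.dtype, np.integer):
            raise InvalidInputError("entries must be integers")
        if (d < 0).any():
            raise InvalidInputError("entries must be non-negative")
        if not (d == d.transpose(0, 2, 1)).all():
            raise InvalidInputError("matrices must be symmetric")
        if d[:, np.arange(self.order), np.arange(self.order)].any():
            raise InvalidInputError("diagonals must be zero")
        if self.data_type == "binary" and (d > 1).any():
            raise InvalidInputError("binary sequence contains entries > 1")


def draw_degree_propensities(
    structure: CommunityStructure,
    pareto_scale: float = 1.0,
    pareto_shape: float = 3.0,
    rng: np.random.Generator | None = None,
) -> DegreePropensity:
    """Draw per-node propensities from a Pareto law and normalise per community.

    Raw draws are i.i.d. Type-I Pareto with density
    ``f(x) = shape * scale**shape / x**(shape+1)`` on ``x >= scale``; the
    defaults (scale 1, shape 3) give mean 1.5 and a heavy right tail,
    emulating the skewed degree distributions of empirical social networks.
    Within each community ``r`` the draws are rescaled so that
    ``sum_{i in r} theta_i = |V_r|``.
    """
    if pareto_scale <= 0 or pareto_shape <= 0:
        raise InvalidParameterError("Pareto scale and shape must be > 0")
    if pareto_shape <= 1:
        warnings.warn(
            "Pareto shape <= 1 has infinite mean; draws remain valid but extreme",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(rng)
    # standard Type-I Pareto: scale * (1 + Lomax(shape))
    raw = pareto_scale * (1.0 + rng.pareto(pareto_shape, size=structure.order))
    theta = np.empty_like(raw)
    for r in range(1, structure.num_communities + 1):
        sl = structure.community_slice(r)
        theta[sl] = raw[sl] * structure.sizes[r - 1] / raw[sl].sum()
    return DegreePropensity(theta=theta, raw_theta=raw,
                            pareto_scale=float(pareto_scale),
                            pareto_shape=float(pareto_shape))


def build_block_matrix(
    baseline_diag: float, homophily_ratio: float, num_communities: int
) -> BlockPropensity:
    """Homophilous block matrix: diagonal ``baseline_diag``, off-diagonal
    ``baseline_diag / homophily_ratio`` (ratio 2 gives the 2:1 within/between
    propensity used throughout the simulation study)."""
    if baseline_diag <= 0 or homophily_ratio <= 0:
        raise InvalidParameterError("baseline_diag and homophily_ratio must be > 0")
    if num_communities < 1:
        raise InvalidParameterError("num_communities must be >= 1")
    off = baseline_diag / homophily_ratio
    P = np.full((num_communities, num_communities), off, dtype=float)
    np.fill_diagonal(P, baseline_diag)
    return BlockPropensity(P=P, baseline_diag=float(baseline_diag),
                           homophily_ratio=float(homophily_ratio))


def apply_shift(P: BlockPropensity, spec: ShiftSpec) -> BlockPropensity:
    """Return a copy of ``P`` with the target community's within-propensity
    multiplied by ``1 + shift_fraction``; every other entry is unchanged."""
    if not 1 <= spec.target_community <= P.num_communities:
        raise InvalidParameterError(
            f"target community {spec.target_community} not in 1..{P.num_communities}"
        )
    shifted = P.P.copy()
    k = spec.target_community - 1
    shifted[k, k] *= 1.0 + spec.shift_fraction
    return BlockPropensity(P=shifted, baseline_diag=P.baseline_diag,
                           homophily_ratio=P.homophily_ratio)


def compute_rates(
    theta: DegreePropensity | np.ndarray,
    P: BlockPropensity,
    structure: CommunityStructure,
) -> RateMatrix:
    """Poisson rate matrix ``lambda_ij = theta_i theta_j P[r(i), r(j)]``,
    zero on the diagonal (no self-loops)."""
    th = theta.theta if isinstance(theta, DegreePropensity) else np.asarray(theta, float)
    if th.shape != (structure.order,):
        raise InvalidInputError(
            f"theta has length {th.shape}, expected ({structure.order},)"
        )
    if P.num_communities != structure.num_communities:
        raise InvalidInputError(
            f"block matrix is {P.num_communities}x{P.num_communities} but the "
            f"structure has {structure.num_communities} communities"
        )
    labels = structure.membership - 1
    lam = np.outer(th, th) * P.P[np.ix_(labels, labels)]
    np.fill_diagonal(lam, 0.0)
    return RateMatrix(lam=lam)


def _upper_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def generate_sequence(
    structure: CommunityStructure,
    theta: DegreePropensity | np.ndarray,
    P_baseline: BlockPropensity,
    shift: ShiftSpec | None,
    run_length: int,
    rng: np.random.Generator | None = None,
) -> NetworkSequence:
    """Generate ``run_length`` unit-width count matrices from the DCSBM.

    Periods ``1..tau`` use baseline rates, periods ``tau+1..T`` the shifted
    rates (``tau = shift.shift_time``); with ``shift=None`` the whole run is
    baseline.  Only the upper triangle is drawn (independent Poisson cells)
    and then mirrored, so matrices are exactly symmetric with zero diagonal.
    """
    if run_length < 1:
        raise InvalidParameterError("run_length must be >= 1")
    if shift is not None and not 0 <= shift.shift_time <= run_length:
        raise InvalidParameterError(
            f"shift_time must lie in 0..{run_length}, got {shift.shift_time}"
        )
    rng = np.random.default_rng(rng)
    n = structure.order
    iu, ju = _upper_pairs(n)

    lam0 = compute_rates(theta, P_baseline, structure).lam[iu, ju]
    T = run_length
    tau = T if shift is None else shift.shift_time
    out = np.zeros((T, n, n), dtype=np.int64)

    def fill(t0: int, t1: int, rates: np.ndarray) -> None:
        if t1 <= t0:
            return
        counts = rng.poisson(rates, size=(t1 - t0, rates.size))
        out[t0:t1, iu, ju] = counts
        out[t0:t1, ju, iu] = counts

    fill(0, tau, lam0)
    if tau < T:
        lam1 = compute_rates(theta, apply_shift(P_baseline, shift), structure).lam[iu, ju]
        fill(tau, T, lam1)
    return NetworkSequence(data=out, step_width=1, start_time=0, data_type="count")
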