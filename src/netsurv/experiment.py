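"""Monte-Carlo harness: false alarm rates, detection rates, signal delays.

A *replication* simulates a full run of ``run_length`` unit-time networks
(default 860), aggregates them at level ``W``, optionally binarizes, scans,
and records whether the method signaled at any aggregated point whose
covering interval ends after the shift time ``tau`` (and at or before the
end of the run).  Detection runs place a sustained shift in community 1;
false-alarm runs apply the identical bookkeeping with no shift, so a "false
alarm" is a signal inside the designated post-``tau`` window of an
in-control run.

Shift times are allocated equally over the offsets ``{840, ..., 840+W-1}``
(just 840 for W = 1), i.e. over all positions a shift can occupy within one
aggregation period, because the method can only ever signal at the end of a
period and a late shift leaves most of its period's data at baseline.

Reproducibility contract: every replication's random stream is derived from
``(master seed, cell label, run index)``, so results are identical whatever
the execution order or degree of parallelism.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aggregate import AggregationSpec
from .errors import InvalidParameterError
from .model import (
    CommunityStructure,
    ShiftSpec,
    build_block_matrix,
    draw_degree_propensities,
    generate_sequence,
)
from .scan import ScanConfig, ScanResult, scan_sequence

__all__ = [
    "ScenarioConfig",
    "RunOutcome",
    "run_single",
    "detection_rate",
    "false_alarm_rate",
    "conditional_delay_distribution",
    "shift_offset_profile",
    "sweep",
    "default_shift_times",
    "post_shift_opportunities",
]

DEFAULT_SHIFT_BASE = 840


def default_shift_times(level: int, run_length: int = 860) -> tuple[int, ...]:
    """All shift offsets within one aggregation period: ``{840..840+W-1}``
    for ``W > 1`` (a single offset 840 at W = 1) when ``run_length`` is 860;
    scaled as ``run_length - 20`` in general."""
    base = run_length - 20
    if level == 1:
        return (base,)
    return tuple(range(base, base + level))


def post_shift_opportunities(level: int, shift_time: int, run_length: int = 860,
                             window_width: int = 20) -> np.ndarray:
    """Original end times of the aggregated points where a post-shift signal
    can occur: monitored points (index > 2 x window) whose covering interval
    ends in ``(shift_time, run_length]``.  At W = 20 and run length 860 any
    shift time in 840..859 leaves a single opportunity, t = 860."""
    ends = level * np.arange(1, run_length // level + 1)
    monitored = ends[2 * window_width:]
    return monitored[(monitored > shift_time) & (monitored <= run_length)]


@dataclass(frozen=True)
class ScenarioConfig:
    """One fully specified experimental condition."""

    order: int = 20
    community_sizes: tuple[int, ...] = (10, 10)
    baseline_diag: float = 1.0
    homophily_ratio: float = 2.0
    pareto_scale: float = 1.0
    pareto_shape: float = 3.0
    run_length: int = 860
    shift_fraction: float = 0.5
    shift_times: tuple[int, ...] | None = None  # None -> default offsets for level
    level: int = 1
    data_type: str = "count"
    binarize_threshold: int = 1
    window_width: int = 20
    signal_threshold: float = 4.0
    replications: int = 200
    seed: int = 0
    share_unit_draws: bool = True

    def __post_init__(self):
        if sum(self.community_sizes) != self.order:
            raise InvalidParameterError(
                f"community sizes {self.community_sizes} do not sum to order {self.order}"
            )
        if self.run_length % self.level:
            raise InvalidParameterError(
                f"run_length {self.run_length} not divisible by level {self.level}"
            )
        if self.replications < 1:
            raise InvalidParameterError("replications must be >= 1")

    @property
    def structure(self) -> CommunityStructure:
        return CommunityStructure(self.community_sizes)

    @property
    def aggregation(self) -> AggregationSpec:
        return AggregationSpec(level=self.level, output_type=self.data_type,
                               binarize_threshold=self.binarize_threshold)

    @property
    def scan(self) -> ScanConfig:
        return ScanConfig(window_width=self.window_width,
                          signal_threshold=self.signal_threshold)

    @property
    def offsets(self) -> tuple[int, ...]:
        if self.shift_times is not None:
            return tuple(self.shift_times)
        return default_shift_times(self.level, self.run_length)

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class RunOutcome:
    """Bookkeeping for one replication.

    ``delay`` is in original time units with origin at the first anomalous
    period: a signal at original time ``tau + 1`` has delay 0.
    """

    detected: bool
    signal_time: int | None
    delay: int | None
    shift_time: int
    pre_shift_signal: bool
    shifted: bool

    def __post_init__(self):
        if self.detected:
            assert self.signal_time is not None
            assert self.delay == self.signal_time - (self.shift_time + 1)


def _run_rng(config: ScenarioConfig, run_index: int, cell: int = 0) -> np.random.Generator:
    material = [int(config.seed), int(cell), int(run_index)]
    if not config.share_unit_draws:
        material.append(int(config.level))
    return np.random.default_rng(np.random.SeedSequence(material))


def run_single(
    config: ScenarioConfig,
    shift_time: int,
    run_index: int = 0,
    rng: np.random.Generator | None = None,
    apply_shift: bool = True,
) -> RunOutcome:
    """One replication: draw theta, simulate, aggregate, (binarize,) scan.

    Detection means a signal at an aggregated point whose original end time
    lies in ``(tau, T]``; earlier signals are recorded as
    ``pre_shift_signal`` and never count as detection.  With
    ``apply_shift=False`` the run is in-control and a "detection" is a false
    alarm in the same window.
    """
    rng = rng if rng is not None else _run_rng(config, run_index)
    structure = config.structure
    theta = draw_degree_propensities(structure, config.pareto_scale,
                                     config.pareto_shape, rng)
    P = build_block_matrix(config.baseline_diag, config.homophily_ratio,
                           structure.num_communities)
    spec = ShiftSpec(shift_fraction=config.shift_fraction, shift_time=shift_time)
    seq = generate_sequence(structure, theta, P,
                            spec if apply_shift and config.shift_fraction > 0 else None,
                            config.run_length, rng)
    result = scan_sequence(config.aggregation.apply(seq), config.scan)
    return outcome_from_scan(result, shift_time, config.run_length,
                             shifted=apply_shift and config.shift_fraction > 0)


def outcome_from_scan(result: ScanResult, shift_time: int, run_length: int,
                      shifted: bool = True) -> RunOutcome:
    """Classify a scan's signals relative to a (possibly notional) shift time."""
    times = result.signal_times
    post = times[(times > shift_time) & (times <= run_length)]
    pre = bool((times <= shift_time).any())
    if post.size:
        t = int(post[0])
        return RunOutcome(detected=True, signal_time=t, delay=t - (shift_time + 1),
                          shift_time=shift_time, pre_shift_signal=pre, shifted=shifted)
    return RunOutcome(detected=False, signal_time=None, delay=None,
                      shift_time=shift_time, pre_shift_signal=pre, shifted=shifted)


def _mc_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))


def _run_cell(config: ScenarioConfig, replications: int | None,
              apply_shift: bool, cell: int = 0) -> list[RunOutcome]:
    n = replications or config.replications
    offsets = config.offsets
    outcomes = []
    for run_index in range(n):
        tau = offsets[run_index % len(offsets)]
        rng = _run_rng(config, run_index, cell)
        outcomes.append(run_single(config, tau, rng=rng, apply_shift=apply_shift))
    return outcomes


def detection_rate(config: ScenarioConfig, replications: int | None = None,
                   cell: int = 0) -> dict:
    """Proportion of shifted replications that were detected, with its
    binomial Monte-Carlo standard error; replications are allocated to the
    shift offsets round-robin (counts differ by at most one)."""
    outcomes = _run_cell(config, replications, apply_shift=True, cell=cell)
    n = len(outcomes)
    p = sum(o.detected for o in outcomes) / n
    return {"metric": "detection_rate", "value": p, "se": _mc_se(p, n),
            "replications": n, "outcomes": outcomes}


def false_alarm_rate(config: ScenarioConfig, replications: int | None = None,
                     cell: int = 0) -> dict:
    """Identical pipeline with no shift applied: the rate of runs with at
    least one signal in the designated post-``tau`` window."""
    outcomes = _run_cell(config, replications, apply_shift=False, cell=cell)
    n = len(outcomes)
    p = sum(o.detected for o in outcomes) / n
    return {"metric": "far", "value": p, "se": _mc_se(p, n),
            "replications": n, "outcomes": outcomes}


def conditional_delay_distribution(config: ScenarioConfig,
                                   replications: int | None = None,
                                   cell: int = 0) -> dict:
    """Signal delays among detected runs only: histogram over original time
    units plus mean and median."""
    out = detection_rate(config, replications, cell)
    delays = np.array([o.delay for o in out["outcomes"] if o.detected], dtype=int)
    hist: dict[int, int] = {}
    if delays.size:
        vals, counts = np.unique(delays, return_counts=True)
        hist = dict(zip(vals.tolist(), counts.tolist()))
    return {
        "metric": "conditional_delay",
        "detection_rate": out["value"],
        "n_detected": int(delays.size),
        "replications": out["replications"],
        "delays": delays,
        "histogram": hist,
        "mean": float(delays.mean()) if delays.size else None,
        "median": float(np.median(delays)) if delays.size else None,
    }


def shift_offset_profile(config: ScenarioConfig,
                         replications_per_offset: int = 100,
                         offsets: Sequence[int] | None = None) -> pd.DataFrame:
    """Detection rate as a function of where the shift falls within the
    aggregation period (one row per shift time tau)."""
    offsets = tuple(offsets) if offsets is not None else \
        tuple(range(DEFAULT_SHIFT_BASE, config.run_length))
    rows = []
    for cell, tau in enumerate(offsets):
        res = detection_rate(config.replace(shift_times=(tau,)),
                             replications_per_offset, cell=cell)
        rows.append({"shift_time": tau, "offset_in_period": tau - offsets[0] + 1,
                     "detection_rate": res["value"], "se": res["se"],
                     "replications": res["replications"]})
    return pd.DataFrame(rows)


_PARAM_COLS = ["order", "baseline_diag", "homophily_ratio", "shift_fraction",
               "level", "data_type", "binarize_threshold", "run_length",
               "window_width", "signal_threshold", "seed"]


def sweep(configs: Iterable[ScenarioConfig], metric: str = "detection_rate",
          replications: int | None = None) -> pd.DataFrame:
    """Evaluate a metric over a grid of conditions into a tidy table.

    Each cell derives its own random streams from ``(seed, cell index,
    run index)``, so the table is identical no matter how the cells are
    executed.  A failing cell is recorded with an ``error`` column rather
    than aborting the sweep.
    """
    fn = {"detection_rate": detection_rate, "far": false_alarm_rate}[metric]
    rows = []
    for cell, cfg in enumerate(configs):
        row = {c: getattr(cfg, c) for c in _PARAM_COLS}
        row["community_sizes"] = "+".join(map(str, cfg.community_sizes))
        row["metric"] = metric
        try:
            res = fn(cfg, replications, cell=cell)
            row.update(value=res["value"], se=res["se"],
                       replications=res["replications"], error="")
        except Exception as exc:  # noqa: BLE001 - per-cell failures are data
            row.update(value=np.nan, se=np.nan, replications=0, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
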