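"""Deterministic fixture catalogue used by the tests, examples and docs.

Every fixture is generated programmatically and carries hand-computed
expected values where the object is small enough to work out by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UnknownFixtureError
from .model import (
    CommunityStructure,
    NetworkSequence,
    ShiftSpec,
    build_block_matrix,
    draw_degree_propensities,
    generate_sequence,
)

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]


@dataclass
class Fixture:
    name: str
    sequence: NetworkSequence
    expected: dict = field(default_factory=dict)


def _single(matrix: np.ndarray) -> NetworkSequence:
    return NetworkSequence(data=np.asarray(matrix, dtype=np.int64)[None],
                           data_type="count")


def _triangle() -> Fixture:
    m = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
    # every node sees the whole triangle at distance <= 1
    return Fixture("triangle", _single(m),
                   expected={"O": np.array([[2, 3, 3]] * 3, dtype=float)})


def _path3() -> Fixture:
    m = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return Fixture("path3", _single(m),
                   expected={"O": np.array([[1, 1, 2],
                                            [2, 2, 2],
                                            [1, 1, 2]], dtype=float)})


def _weighted_path3() -> Fixture:
    # counts C(1,2)=5, C(2,3)=2
    m = np.array([[0, 5, 0], [5, 0, 2], [0, 2, 0]])
    return Fixture("weighted-path3", _single(m),
                   expected={"O": np.array([[5, 5, 7],
                                            [7, 7, 7],
                                            [2, 2, 7]], dtype=float)})


def _constant_sequence() -> Fixture:
    m = np.array([[0, 2, 0, 1],
                  [2, 0, 3, 0],
                  [0, 3, 0, 1],
                  [1, 0, 1, 0]])
    seq = NetworkSequence(data=np.repeat(m[None], 60, axis=0).astype(np.int64))
    return Fixture("constant-sequence", seq,
                   expected={"max_standardized": 0.0, "num_signals": 0})


def _shifted_run() -> Fixture:
    """Seeded 20-node DCSBM run with the shift late in the final W=20 block:
    tau = 845 leaves 5 baseline and 15 anomalous unit matrices in the block
    covering original times 841-860."""
    structure = CommunityStructure((10, 10))
    rng = np.random.default_rng(20180921)
    theta = draw_degree_propensities(structure, 1.0, 3.0, rng)
    P = build_block_matrix(1.0, 2.0, 2)
    spec = ShiftSpec(shift_fraction=1.5, shift_time=845)
    seq = generate_sequence(structure, theta, P, spec, 860, rng)
    return Fixture("shifted-run", seq,
                   expected={"shift_time": 845, "level": 20,
                             "baseline_in_final_block": 5,
                             "anomalous_in_final_block": 15})


_CATALOGUE = {
    "triangle": _triangle,
    "path3": _path3,
    "weighted-path3": _weighted_path3,
    "constant-sequence": _constant_sequence,
    "shifted-run": _shifted_run,
}

FIXTURE_NAMES = tuple(_CATALOGUE)


def make_fixture(name: str) -> Fixture:
    """Build a named fixture; unknown names raise with the full catalogue."""
    try:
        builder = _CATALOGUE[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()
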