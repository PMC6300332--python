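"""File formats: temporal edge lists, matrix archives, result tables.

The interchange format is a delimited temporal edge list with header
``t<TAB>i<TAB>j<TAB>count`` (tab or comma delimited): 1-based time and node
indices, upper triangle only (``i < j``), zero cells omitted.  Comment lines
beginning ``#`` carry metadata (number of nodes, number of time steps, step
width, data type) so a round trip is lossless even for sequences that end in
empty networks.  A dense ``.npz`` archive of the matrix stack is provided
for bulk storage.
"""

from __future__ import annotations

import datetime
import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .model import NetworkSequence

__all__ = [
    "write_edge_list",
    "read_edge_list",
    "save_archive",
    "load_archive",
    "write_results",
    "read_results",
]

_META_RE = re.compile(r"(\w+)\s*=\s*(\S+)")


def write_edge_list(seq: NetworkSequence, path: str | Path) -> None:
    """Write a sequence as a canonical tab-delimited temporal edge list,
    sorted by (t, i, j); only strictly-upper-triangle nonzero cells appear."""
    seq.validate()
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# nodes={seq.order} times={len(seq)} width={seq.step_width} "
                 f"start={seq.start_time} type={seq.data_type}\n")
        fh.write("t\ti\tj\tcount\n")
        for t in range(len(seq)):
            iu, ju = np.nonzero(np.triu(seq.data[t], k=1))
            for i, j in zip(iu, ju):
                fh.write(f"{t + 1}\t{i + 1}\t{j + 1}\t{seq.data[t, i, j]}\n")


def read_edge_list(
    path: str | Path,
    num_nodes: int | None = None,
    num_times: int | None = None,
) -> NetworkSequence:
    """Read a temporal edge list into a dense sequence.

    The node universe and time range come from the ``#`` metadata line if
    present, else from ``num_nodes`` / ``num_times``, else they are inferred
    as the largest observed index.  Missing time indices inside the range
    become zero matrices.  Self-pairs, duplicate ``(t, i, j)`` keys and
    non-integer fields raise :class:`ParseError` with the line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    records: list[tuple[int, int, int, int]] = []
    header_seen = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta.update(_META_RE.findall(line.lstrip("# ")))
                continue
            parts = re.split(r"[\t,]+", line)
            if not header_seen:
                header_seen = True
                if parts[0].lower() == "t":
                    continue  # header row
            if len(parts) != 4:
                raise ParseError(f"expected 4 fields, got {len(parts)}", lineno)
            try:
                t, i, j, c = (int(p) for p in parts)
            except ValueError:
                raise ParseError(f"non-integer field in {parts!r}", lineno) from None
            if i == j:
                raise ParseError(f"self-pair ({i},{j}) not allowed", lineno)
            if t < 1 or i < 1 or j < 1:
                raise ParseError("indices are 1-based and must be positive", lineno)
            if c < 0:
                raise ParseError(f"negative count {c}", lineno)
            if i > j:
                i, j = j, i
            records.append((t, i, j, c))

    n = int(meta.get("nodes", num_nodes or 0))
    T = int(meta.get("times", num_times or 0))
    if records:
        n = max(n, max(max(i, j) for _, i, j, _ in records))
        T = max(T, max(t for t, *_ in records))
    if n < 1 or T < 1:
        raise ParseError("empty edge list and no declared node/time range")
    seen: set[tuple[int, int, int]] = set()
    data = np.zeros((T, n, n), dtype=np.int64)
    for t, i, j, c in records:
        if (t, i, j) in seen:
            raise ParseError(f"duplicate record for (t={t}, i={i}, j={j})")
        seen.add((t, i, j))
        data[t - 1, i - 1, j - 1] = c
        data[t - 1, j - 1, i - 1] = c
    return NetworkSequence(
        data=data,
        step_width=int(meta.get("width", 1)),
        start_time=int(meta.get("start", 0)),
        data_type=meta.get("type", "count"),
    )


def save_archive(seq: NetworkSequence, path: str | Path) -> None:
    """Dense archive of the matrix stack (``.npz``)."""
    np.savez_compressed(Path(path), data=seq.data,
                        meta=np.array([seq.step_width, seq.start_time]),
                        data_type=np.array(seq.data_type))


def load_archive(path: str | Path) -> NetworkSequence:
    with np.load(Path(path)) as z:
        return NetworkSequence(data=z["data"], step_width=int(z["meta"][0]),
                               start_time=int(z["meta"][1]),
                               data_type=str(z["data_type"]))


def write_results(table: pd.DataFrame, path: str | Path,
                  seed: int | None = None, comments: bool = True) -> None:
    """Write a tidy result table as CSV with a deterministic column order.

    Header comment lines record the master seed, package version and a
    timestamp; the data section below them is byte-identical across repeated
    runs with the same seed.
    """
    from . import __version__

    path = Path(path)
    cols = sorted(table.columns)
    buf = _io.StringIO()
    table[cols].to_csv(buf, index=False)
    with path.open("w") as fh:
        if comments:
            fh.write(f"# netsurv v{__version__}\n")
            if seed is not None:
                fh.write(f"# seed={seed}\n")
            fh.write(f"# written={datetime.datetime.now().isoformat()}\n")
        fh.write(buf.getvalue())


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), comment="#")
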