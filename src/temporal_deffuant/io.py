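"""Plain-text readers and writers for run artefacts.

Everything on disk is diff-able text: whitespace-separated edge lists,
CSV tables with fixed headers, and JSON metadata carrying the config hash
and master seed.  Writes are atomic (temp file + rename) and deterministic
(stable column order, floats at 12 significant digits).
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import warnings
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .networks import StaticNetwork

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "write_csv",
    "write_json",
    "write_results",
    "config_hash",
]

FLOAT_FMT = "%.12g"


def read_edge_list(path) -> StaticNetwork:
    """Read a two-column whitespace-separated edge list.

    Lines starting with '#' are comments.  Self-loops are rejected with
    their line number; duplicate edges are dropped with a warning.  Node
    ids are compacted to 0..N-1 preserving numeric order; the mapping is
    attached as ``network.id_map`` (original -> compact).
    """
    edges_raw: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two node ids")
            u, v = int(parts[0]), int(parts[1])
            if u == v:
                raise ValueError(f"{path}:{lineno}: self-loop at node {u}")
            edges_raw.append((u, v))
    nodes = sorted({n for e in edges_raw for n in e})
    id_map = {orig: i for i, orig in enumerate(nodes)}
    seen: set[tuple[int, int]] = set()
    edges: list[tuple[int, int]] = []
    dupes = 0
    for u, v in edges_raw:
        key = (id_map[u], id_map[v])
        key = key if key[0] < key[1] else (key[1], key[0])
        if key in seen:
            dupes += 1
            continue
        seen.add(key)
        edges.append(key)
    if dupes:
        warnings.warn(f"{path}: dropped {dupes} duplicate edge(s)", stacklevel=2)
    net = StaticNetwork(len(nodes), edges)
    net.id_map = id_map  # type: ignore[attr-defined]
    return net


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_edge_list(network: StaticNetwork, path) -> None:
    lines = [f"{u} {v}" for u, v in network.edges]
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def write_csv(df: pd.DataFrame, path) -> None:
    """Deterministic CSV: stable column order, 12-significant-digit floats."""
    _atomic_write(Path(path), df.to_csv(index=False, float_format=FLOAT_FMT))


def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(data: dict, path) -> None:
    _atomic_write(Path(path), json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n")


def config_hash(config: Any) -> str:
    """Stable short hash of a (dataclass or dict) configuration."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_event_log(schedule, n_events: int, path) -> int:
    """Consume ``n_events`` activations from a schedule into a `time,u,v` CSV.

    Returns the number of events written (fewer if the schedule exhausts).
    The log can be replayed bit-exactly through :func:`read_event_log`.
    """
    from .activation import ScheduleExhausted

    lines = ["time,u,v"]
    written = 0
    for _ in range(n_events):
        try:
            t, (u, v) = schedule.pop()
        except ScheduleExhausted:
            break
        lines.append(f"{FLOAT_FMT % t},{u},{v}")
        written += 1
    _atomic_write(Path(path), "\n".join(lines) + "\n")
    return written


def read_event_log(path, network: StaticNetwork):
    """Replay a `time,u,v` activation log recorded by :func:`write_event_log`."""
    from .activation import ReplaySchedule

    df = pd.read_csv(path)
    links = list(zip(df["u"].astype(int), df["v"].astype(int)))
    return ReplaySchedule(df["time"].to_numpy(), links, network)


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir,
    metadata: dict | None = None,
) -> list[Path]:
    """Write named tables as CSVs plus a metadata.json; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out / f"{name}.csv"
        write_csv(df, p)
        written.append(p)
    if metadata is not None:
        p = out / "metadata.json"
        write_json(metadata, p)
        written.append(p)
    return written
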