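"""Reading timestamped contact data and building the snapshot tensor.

The input dialect is the SocioPatterns-style edge list: one contact event per
line, ``t i j [extra columns ignored]``, whitespace- or tab-separated, with
``t`` in integer seconds.  Events are binned into consecutive half-open
intervals ``[t0 + m*delta, t0 + (m+1)*delta)`` and each interval becomes one
binary adjacency slice of an N x N x S tensor: a link is present in a slice
iff the pair had at least one contact during that interval.

Node axis order is the lexicographically sorted node-id registry, so that
identical inputs always yield byte-identical tensors regardless of file
order.  Self-loops and exact duplicate events are dropped with counts kept
on the returned network.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import CPModel
from .validation import GroundTruth, LocationFingerprints

__all__ = [
    "AggregatedNetwork",
    "EdgeListParseError",
    "SnapshotTensor",
    "TemporalNetwork",
    "aggregate_time",
    "build_tensor",
    "read_edge_list",
    "read_factors",
    "read_fingerprints",
    "read_metadata",
    "read_tensor",
    "write_activities",
    "write_factors",
    "write_memberships",
    "write_tensor",
]

DEFAULT_INTERVAL = 780.0  # seconds (~13 minutes)
_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


class EdgeListParseError(ValueError):
    """A contact line failed to parse; carries the 1-based line number."""


@dataclass(frozen=True)
class TemporalNetwork:
    """A stream of timestamped undirected contact events.

    ``events`` are (time, i, j) triples sorted by time; ``nodes`` is the
    frozen, lexicographically sorted registry defining axis order everywhere
    downstream.  Counts of dropped self-loops / duplicates are retained for
    reporting.
    """

    events: tuple[tuple[int, str, str], ...]
    nodes: tuple[str, ...]
    undirected: bool = True
    n_selfloops_dropped: int = 0
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        registry = set(self.nodes)
        for t, i, j in self.events:
            if i == j:
                raise ValueError(f"self-loop event ({t}, {i}, {j})")
            if t < 0:
                raise ValueError(f"negative event time {t}")
            if i not in registry or j not in registry:
                raise ValueError(f"event endpoint outside the node registry: ({i}, {j})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def t_max(self) -> int:
        return max(t for t, _, _ in self.events)

    @classmethod
    def from_events(cls, events, undirected: bool = True,
                    n_selfloops_dropped: int = 0, n_duplicates_dropped: int = 0
                    ) -> "TemporalNetwork":
        """Normalize, sort and freeze an event iterable (node order sorted)."""
        normed = []
        for t, i, j in events:
            i, j = str(i), str(j)
            if undirected and j < i:
                i, j = j, i
            normed.append((int(t), i, j))
        normed.sort()
        nodes = tuple(sorted({n for _, i, j in normed for n in (i, j)}))
        return cls(events=tuple(normed), nodes=nodes, undirected=undirected,
                   n_selfloops_dropped=n_selfloops_dropped,
                   n_duplicates_dropped=n_duplicates_dropped)


@dataclass(frozen=True)
class SnapshotTensor:
    """N x N x S stack of per-interval adjacency slices plus index metadata."""

    values: np.ndarray
    nodes: tuple[str, ...]
    t0: int = 0
    interval_length: float = DEFAULT_INTERVAL

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        n = len(self.nodes)
        if values.ndim != 3 or values.shape[0] != n or values.shape[1] != n:
            raise ValueError(f"tensor shape {values.shape} inconsistent with {n} nodes")
        if n < 2 or values.shape[2] < 1:
            raise ValueError("need at least 2 nodes and 1 interval")
        if values.min() < 0:
            raise ValueError("tensor entries must be non-negative")
        if self.interval_length <= 0:
            raise ValueError("interval_length must be positive")
        object.__setattr__(self, "values", values)

    @property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_intervals(self) -> int:
        return self.values.shape[2]

    def interval_starts(self) -> np.ndarray:
        return self.t0 + self.interval_length * np.arange(self.n_intervals)

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0.0, 1.0)).all())


@dataclass(frozen=True)
class AggregatedNetwork:
    """Time-aggregated weighted network: weight(i,j) = number of active intervals."""

    weights: np.ndarray
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights)
        if not np.array_equal(weights, weights.T):
            raise ValueError("aggregated weights must be symmetric")
        if np.diagonal(weights).any():
            raise ValueError("aggregated weights must have a zero diagonal")
        object.__setattr__(self, "weights", weights.astype(int))


def read_edge_list(path: str | Path) -> TemporalNetwork:
    """Parse a SocioPatterns-style contact file into a :class:`TemporalNetwork`.

    Lines are ``t i j [extra...]``; blank lines and ``#`` comments are
    skipped; malformed lines raise :class:`EdgeListParseError` with the line
    number; self-loop lines and exact duplicate events are dropped and
    counted.  An empty file yields an empty network.
    """
    events: list[tuple[int, str, str]] = []
    selfloops = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) < 3:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 3 columns, got {len(fields)}"
                )
            try:
                t = int(fields[0])
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{path}:{lineno}: non-integer timestamp {fields[0]!r}"
                ) from exc
            i, j = fields[1], fields[2]
            if i == j:
                selfloops += 1
                continue
            if j < i:
                i, j = j, i
            events.append((t, i, j))
    unique = sorted(set(events))
    if not unique:
        return TemporalNetwork(events=(), nodes=(), undirected=True,
                               n_selfloops_dropped=selfloops)
    return TemporalNetwork(
        events=tuple(unique),
        nodes=tuple(sorted({n for _, i, j in unique for n in (i, j)})),
        undirected=True,
        n_selfloops_dropped=selfloops,
        n_duplicates_dropped=len(events) - len(unique),
    )


def _bin_index(t: int, t0: int, delta: float) -> int:
    return int((t - t0) // delta)


def build_tensor(
    net: TemporalNetwork,
    interval_length: float = DEFAULT_INTERVAL,
    t0: int = 0,
    weighted: bool = False,
) -> SnapshotTensor:
    """Aggregate contact events into the N x N x S snapshot tensor.

    ``S = ceil((t_max - t0 + 1) / interval_length)``; event at time t lands
    in slice ``(t - t0) // interval_length`` (half-open intervals).  Binary
    slices by default ("at least one contact"); ``weighted=True`` counts
    contacts instead.  Both (i, j, m) and (j, i, m) are set for undirected
    input.
    """
    if interval_length <= 0:
        raise ValueError("interval_length must be positive")
    if not net.events:
        raise ValueError("cannot build a tensor from an empty network")
    first = min(t for t, _, _ in net.events)
    if first < t0:
        raise ValueError(f"event at t={first} precedes t0={t0}; set t0 <= first event")
    n = net.n_nodes
    s = math.ceil((net.t_max - t0 + 1) / interval_length)
    index = {node: pos for pos, node in enumerate(net.nodes)}
    values = np.zeros((n, n, s))
    for t, i, j in net.events:
        m = _bin_index(t, t0, interval_length)
        a, b = index[i], index[j]
        if weighted:
            values[a, b, m] += 1.0
            values[b, a, m] += 1.0
        else:
            values[a, b, m] = 1.0
            values[b, a, m] = 1.0
    return SnapshotTensor(values=values, nodes=net.nodes, t0=t0,
                          interval_length=interval_length)


def aggregate_time(tensor: SnapshotTensor) -> AggregatedNetwork:
    """Time-aggregated weighted network: weight = sum of the binary slices."""
    if not tensor.is_binary:
        raise ValueError("aggregate_time requires a binary snapshot tensor")
    weights = tensor.values.sum(axis=2).astype(int)
    return AggregatedNetwork(weights=weights, nodes=tensor.nodes)


def read_metadata(path: str | Path, nodes: tuple[str, ...] | None = None) -> GroundTruth:
    """Read node metadata TSV ``node_id <tab> class [<tab> role]``.

    ``role`` defaults to student.  When ``nodes`` is given, metadata rows for
    unknown node-ids raise an error listing the offenders.
    """
    frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: metadata needs at least node_id and class columns")
    labels: dict[str, str] = {}
    roles: dict[str, str] = {}
    for row in frame.itertuples(index=False):
        node, label = str(row[0]), str(row[1])
        labels[node] = label
        roles[node] = str(row[2]) if frame.shape[1] > 2 and pd.notna(row[2]) else "student"
    if nodes is not None:
        unknown = sorted(set(labels) - set(nodes))
        if unknown:
            raise ValueError(f"{path}: metadata refers to unknown node-ids {unknown}")
    return GroundTruth(labels=labels, roles=roles)


def read_fingerprints(
    path: str | Path,
    interval_length: float = DEFAULT_INTERVAL,
    t0: int = 0,
    n_intervals: int | None = None,
) -> LocationFingerprints:
    """Read ``t <tab> node_id <tab> receiver_id <tab> count`` rows and bin them.

    Rows are binned with the same half-open rule as :func:`build_tensor` and
    counts accumulated per (node, receiver, interval).
    """
    frame = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["t", "node", "receiver", "count"],
                        dtype={"t": int, "node": str, "receiver": str, "count": int})
    if (frame["t"] < t0).any():
        raise ValueError(f"{path}: fingerprint rows precede t0={t0}")
    nodes = tuple(sorted(frame["node"].unique()))
    receivers = tuple(sorted(frame["receiver"].unique()))
    bins = ((frame["t"] - t0) // interval_length).astype(int)
    s = n_intervals if n_intervals is not None else (int(bins.max()) + 1 if len(bins) else 1)
    counts = np.zeros((len(nodes), len(receivers), s), dtype=int)
    n_idx = {n: i for i, n in enumerate(nodes)}
    r_idx = {r: i for i, r in enumerate(receivers)}
    for (node, receiver, count), m in zip(
        frame[["node", "receiver", "count"]].itertuples(index=False), bins
    ):
        if m >= s:
            raise ValueError(f"{path}: fingerprint row beyond interval range (bin {m})")
        counts[n_idx[node], r_idx[receiver], m] += count
    return LocationFingerprints(counts=counts, nodes=nodes, receivers=receivers)


# ---------------------------------------------------------------------------
# tabular writers / readers (round-trip exact for IEEE doubles via %.17g)

def write_tensor(tensor: SnapshotTensor, directory: str | Path) -> None:
    """Sparse COO TSV ``i j m value`` plus a JSON header (N, S, delta, t0, node order)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    idx = np.nonzero(tensor.values)
    with open(directory / "tensor.tsv", "w") as handle:
        handle.write("i\tj\tm\tvalue\n")
        for a, b, m in zip(*idx):
            handle.write(f"{a}\t{b}\t{m}\t{_FLOAT_FMT % tensor.values[a, b, m]}\n")
    header = {
        "n_nodes": tensor.n_nodes,
        "n_intervals": tensor.n_intervals,
        "interval_length": tensor.interval_length,
        "t0": tensor.t0,
        "nodes": list(tensor.nodes),
    }
    (directory / "tensor.json").write_text(json.dumps(header, indent=1))


def read_tensor(directory: str | Path) -> SnapshotTensor:
    directory = Path(directory)
    header = json.loads((directory / "tensor.json").read_text())
    values = np.zeros((header["n_nodes"], header["n_nodes"], header["n_intervals"]))
    frame = pd.read_csv(directory / "tensor.tsv", sep="\t")
    values[frame["i"], frame["j"], frame["m"]] = frame["value"]
    return SnapshotTensor(values=values, nodes=tuple(header["nodes"]),
                          t0=header["t0"], interval_length=header["interval_length"])


def write_factors(model: CPModel, directory: str | Path,
                  nodes: tuple[str, ...] | None = None) -> None:
    """Write A/B/C as TSV plus fit metadata JSON; exact round trip via %.17g."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, matrix in (("A", model.a), ("B", model.b), ("C", model.c)):
        np.savetxt(directory / f"{name}.tsv", matrix, delimiter="\t", fmt=_FLOAT_FMT)
    meta = {
        "rank": model.rank,
        "objective": model.objective,
        "fit": model.fit,
        "n_iter": model.n_iter,
        "seed": model.seed,
        "converged": model.converged,
        "asymmetry": None if np.isnan(model.asymmetry) else model.asymmetry,
        "collapsed": list(model.collapsed),
        "nodes": list(nodes) if nodes is not None else None,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=1))


def read_factors(directory: str | Path) -> tuple[CPModel, tuple[str, ...] | None]:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    a, b, c = (np.atleast_2d(np.loadtxt(directory / f"{n}.tsv", delimiter="\t", ndmin=2))
               for n in ("A", "B", "C"))
    model = CPModel(
        a=a, b=b, c=c,
        objective=meta["objective"], fit=meta["fit"], n_iter=meta["n_iter"],
        seed=meta["seed"], converged=meta["converged"],
        asymmetry=meta["asymmetry"] if meta["asymmetry"] is not None else np.nan,
        collapsed=tuple(meta["collapsed"]),
    )
    nodes = tuple(meta["nodes"]) if meta["nodes"] is not None else None
    return model, nodes


def write_memberships(membership, model: CPModel, path: str | Path) -> None:
    """TSV rows (node_id, component, weight, member) for every node/component pair."""
    with open(path, "w") as handle:
        handle.write("node_id\tcomponent\tweight\tmember\n")
        for pos, node in enumerate(membership.nodes):
            for k in range(membership.rank):
                handle.write(
                    f"{node}\t{k}\t{_FLOAT_FMT % model.a[pos, k]}\t"
                    f"{int(membership.values[pos, k])}\n"
                )


def write_activities(profile, tensor_meta: dict | SnapshotTensor, path: str | Path) -> None:
    """CSV rows (interval_start, component, strength)."""
    if isinstance(tensor_meta, SnapshotTensor):
        starts = tensor_meta.interval_starts()
    else:
        starts = tensor_meta["t0"] + tensor_meta["interval_length"] * np.arange(
            profile.values.shape[0])
    with open(path, "w") as handle:
        handle.write("interval_start,component,strength\n")
        for m, start in enumerate(starts):
            for k in range(profile.values.shape[1]):
                handle.write(f"{_FLOAT_FMT % start},{k},{_FLOAT_FMT % profile.values[m, k]}\n")
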