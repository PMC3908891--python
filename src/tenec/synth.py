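"""Planted community-activity benchmark generator.

Emulates a school-like population: disjoint groups (classes) with
per-interval activity schedules, dense within-group contacts while active,
sparse background noise, and scheduled mixed-group gatherings ("social
events", e.g. lunch in a cafeteria) that link members across groups and
place them at a common receiver.  Matching ground truth and location
fingerprints are emitted alongside the contact stream, so the whole
factorization/validation pipeline can be exercised without any download.

All randomness flows from the spec seed through a single generator with a
fixed draw order; regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .temporal_io import SnapshotTensor, TemporalNetwork, build_tensor
from .tensor import cp_reconstruct
from .validation import GroundTruth, LocationFingerprints

__all__ = [
    "PlantedEvent",
    "PlantedSpec",
    "SyntheticData",
    "exact_lowrank",
    "generate",
    "school_spec",
]


@dataclass(frozen=True)
class PlantedEvent:
    """A mixed-group gathering: the listed groups meet at ``location`` during
    ``intervals``, every cross pair linked with probability ``p_event``."""

    intervals: tuple[int, ...]
    groups: tuple[str, ...]
    p_event: float
    location: str


@dataclass(frozen=True)
class PlantedSpec:
    """Planted structure: groups, schedules, contact probabilities, events.

    ``schedule[g]`` gives the probability that group ``g`` is active in each
    interval; an active group links each internal pair with ``p_in``.
    ``p_noise`` links any pair per interval regardless of structure.
    """

    groups: dict[str, tuple[str, ...]]
    schedule: dict[str, np.ndarray]
    n_intervals: int
    p_in: float = 0.4
    p_noise: float = 0.0
    events: tuple[PlantedEvent, ...] = ()
    interval_length: int = 780
    fingerprint_rate: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.groups.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"groups overlap on nodes {sorted(overlap)}")
            seen.update(members)
        for label, probs in self.schedule.items():
            probs = np.asarray(probs, dtype=float)
            if probs.shape != (self.n_intervals,):
                raise ValueError(f"schedule for {label} must have {self.n_intervals} entries")
            if probs.min() < 0 or probs.max() > 1:
                raise ValueError(f"schedule for {label} has probabilities outside [0, 1]")
        for p, name in ((self.p_in, "p_in"), (self.p_noise, "p_noise")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for event in self.events:
            if not 0 <= event.p_event <= 1:
                raise ValueError("p_event must be in [0, 1]")
            if any(m < 0 or m >= self.n_intervals for m in event.intervals):
                raise ValueError("event interval outside range")
            unknown = set(event.groups) - set(self.groups)
            if unknown:
                raise ValueError(f"event refers to unknown groups {sorted(unknown)}")
        if self.fingerprint_rate < 1:
            raise ValueError("fingerprint_rate must be >= 1 (a detected node emits "
                             "at least one packet)")

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(n for members in self.groups.values() for n in members))


@dataclass(frozen=True)
class SyntheticData:
    """Generated contact stream, its tensor, ground truth and fingerprints."""

    network: TemporalNetwork
    tensor: SnapshotTensor
    truth: GroundTruth
    fingerprints: LocationFingerprints


def _home_receiver(group: str) -> str:
    return f"room_{group}"


def generate(spec: PlantedSpec) -> SyntheticData:
    """Draw one realization of the planted model.

    Per interval, in a fixed order: group activations (Bernoulli with the
    schedule probability), within-group pairs for active groups, background
    noise pairs, then event pairs and event fingerprints.  Fingerprint
    counts are ``1 + Poisson(rate - 1)``: a node whose presence was detected
    has at least one received packet, which keeps co-location products of
    gathered members strictly positive.

    Returns the event stream, the binary snapshot tensor built from it, the
    group ground truth (all students) and the binned fingerprints.
    """
    rng = np.random.default_rng(spec.seed)
    group_labels = sorted(spec.groups)
    nodes = spec.nodes
    receivers = tuple(sorted({_home_receiver(g) for g in group_labels}
                             | {e.location for e in spec.events}))
    n_idx = {n: i for i, n in enumerate(nodes)}
    r_idx = {r: i for i, r in enumerate(receivers)}
    counts = np.zeros((len(nodes), len(receivers), spec.n_intervals), dtype=int)
    events: list[tuple[int, str, str]] = []
    all_pairs = list(combinations(nodes, 2))
    delta = spec.interval_length

    def emit(i: str, j: str, m: int) -> None:
        t = m * delta  # event time at the interval start: binning is what matters
        events.append((t, i, j) if i < j else (t, j, i))

    for m in range(spec.n_intervals):
        at_event: set[str] = set()
        for event in spec.events:
            if m in event.intervals:
                at_event.update(n for g in event.groups for n in spec.groups[g])
        for g in group_labels:
            active = rng.random() < float(spec.schedule[g][m])
            members = sorted(spec.groups[g])
            pairs = list(combinations(members, 2))
            if active and pairs:
                draws = rng.random(len(pairs))
                for (i, j), u in zip(pairs, draws):
                    if u < spec.p_in:
                        emit(i, j, m)
            if active:
                here = [n for n in members if n not in at_event]
                if here:
                    packets = 1 + rng.poisson(spec.fingerprint_rate - 1, size=len(here))
                    for n, p in zip(here, packets):
                        counts[n_idx[n], r_idx[_home_receiver(g)], m] += p
        if spec.p_noise > 0:
            draws = rng.random(len(all_pairs))
            for (i, j), u in zip(all_pairs, draws):
                if u < spec.p_noise:
                    emit(i, j, m)
        for event in spec.events:
            if m not in event.intervals:
                continue
            participants = sorted(n for g in event.groups for n in spec.groups[g])
            pairs = list(combinations(participants, 2))
            draws = rng.random(len(pairs))
            for (i, j), u in zip(pairs, draws):
                if u < event.p_event:
                    emit(i, j, m)
            packets = 1 + rng.poisson(spec.fingerprint_rate - 1, size=len(participants))
            for n, p in zip(participants, packets):
                counts[n_idx[n], r_idx[event.location], m] += p

    if not events:
        raise ValueError("the realization produced no contacts; raise the probabilities")
    unique = sorted(set(events))
    network = TemporalNetwork(
        events=tuple(unique),
        nodes=tuple(sorted({x for _, i, j in unique for x in (i, j)})),
        undirected=True,
        n_duplicates_dropped=len(events) - len(unique),
    )
    tensor = build_tensor(network, interval_length=delta, t0=0)
    # pad trailing silent intervals so the tensor always spans the full schedule
    if tensor.n_intervals < spec.n_intervals:
        padded = np.zeros((tensor.n_nodes, tensor.n_nodes, spec.n_intervals))
        padded[:, :, : tensor.n_intervals] = tensor.values
        tensor = SnapshotTensor(values=padded, nodes=tensor.nodes, t0=0,
                                interval_length=delta)
    labels = {n: g for g, members in spec.groups.items() for n in members}
    truth = GroundTruth(labels=labels, roles={n: "student" for n in labels})
    # restrict fingerprints to nodes that appear in the contact stream so all
    # registries agree
    keep = [n_idx[n] for n in tensor.nodes]
    fingerprints = LocationFingerprints(
        counts=counts[keep], nodes=tensor.nodes, receivers=receivers)
    return SyntheticData(network=network, tensor=tensor, truth=truth,
                         fingerprints=fingerprints)


def school_spec(
    seed: int = 11,
    n_groups: int = 10,
    group_size: int = 6,
    n_intervals: int = 40,
    lunch_intervals: tuple[int, ...] = (18, 19, 20, 21),
    event_groups: int = 4,
    p_class_active: float = 0.7,
    p_in: float = 0.4,
    p_event: float = 0.5,
    p_noise: float = 0.001,
) -> PlantedSpec:
    """School-day-like planted spec: classes active outside lunch, one
    mixed-group lunch gathering in the cafeteria.

    Defaults model a small school: 10 classes of 6, a 40-interval day with a
    4-interval lunch break during which the first 4 classes gather.
    """
    groups = {
        f"G{g:02d}": tuple(f"g{g:02d}n{i:02d}" for i in range(group_size))
        for g in range(n_groups)
    }
    base = np.full(n_intervals, p_class_active)
    base[list(lunch_intervals)] = 0.0
    schedule = {g: base.copy() for g in groups}
    event = PlantedEvent(
        intervals=tuple(lunch_intervals),
        groups=tuple(sorted(groups)[:event_groups]),
        p_event=p_event,
        location="cafeteria",
    )
    return PlantedSpec(groups=groups, schedule=schedule, n_intervals=n_intervals,
                       p_in=p_in, p_noise=p_noise, events=(event,), seed=seed)


def exact_lowrank(
    rank: int, shape: tuple[int, int, int], seed: int = 0
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Exact non-negative rank-``rank`` tensor with known full-column-rank factors.

    Factors are sparse non-negative draws (uniform magnitudes with ~40% of
    entries zeroed); each is redrawn until it has full column rank, which
    requires every mode dimension >= ``rank``.
    """
    if min(shape) < rank:
        raise ValueError(f"shape {shape} too small for full column rank {rank}")
    rng = np.random.default_rng(seed)
    factors = []
    for dim in shape:
        for _ in range(100):
            m = rng.uniform(0.5, 1.5, size=(dim, rank))
            m *= rng.random(size=(dim, rank)) < 0.6
            if (m.max(axis=0) > 0).all() and np.linalg.matrix_rank(m) == rank:
                factors.append(m)
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not draw a full-column-rank factor")
    a, b, c = factors
    return cp_reconstruct(a, b, c), (a, b, c)
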