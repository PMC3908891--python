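"""Ground-truth validation of extracted components.

Structural validation matches components to known classes through Jaccard
overlap vectors: a component matches a class when its overlap vector has
exactly one non-zero entry (a deliberately strict criterion — a component
that mixes two classes matches nothing).  Recall is the fraction of students
of the matched classes that the matching components recover.  Score matrices
project any binary node-community assignment onto the class structure, and
co-location series validate mixed components against spatial fingerprints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interpret import MembershipMatrix

__all__ = [
    "ColocationSeries",
    "ComponentMatch",
    "GroundTruth",
    "LocationFingerprints",
    "RecallReport",
    "colocation",
    "jaccard",
    "match_components",
    "recall_and_coverage",
    "reference_score_matrix",
    "score_matrix",
]

STUDENT = "student"
TEACHER = "teacher"


@dataclass(frozen=True)
class GroundTruth:
    """Node -> class labels plus roles (student/teacher).

    Every labeled node has exactly one class; teachers carry a class label
    too (the class they teach) but are excluded from the student-only
    matching and recall computations.
    """

    labels: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [n for n, r in self.roles.items() if r not in (STUDENT, TEACHER)]
        if bad:
            raise ValueError(f"unknown roles for nodes {bad!r}")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels.values())))

    def role(self, node: str) -> str:
        return self.roles.get(node, STUDENT)

    def students(self) -> frozenset[str]:
        return frozenset(n for n in self.labels if self.role(n) == STUDENT)

    def class_members(self, label: str, students_only: bool = True) -> frozenset[str]:
        members = (n for n, c in self.labels.items() if c == label)
        if students_only:
            members = (n for n in members if self.role(n) == STUDENT)
        return frozenset(members)


def jaccard(set_a: frozenset | set, set_b: frozenset | set) -> float:
    """|A n B| / |A u B|, with 0 when both sets are empty."""
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return len(set_a & set_b) / union


@dataclass(frozen=True)
class ComponentMatch:
    """Jaccard overlap vector of one component against every class.

    ``matched_class`` is set iff exactly one class has non-zero overlap.
    """

    component: int
    overlaps: dict[str, float]
    matched_class: str | None

    @property
    def matched(self) -> bool:
        return self.matched_class is not None


def match_components(
    membership: MembershipMatrix,
    truth: GroundTruth,
    students_only: bool = True,
) -> list[ComponentMatch]:
    """Match each component to at most one class by the single-non-zero rule.

    Overlaps are computed between the component's member set and each class's
    member set, both restricted to students when ``students_only`` (the
    default, since teachers have no unambiguous class association).
    """
    classes = truth.classes
    class_sets = {c: truth.class_members(c, students_only) for c in classes}
    keep = truth.students() if students_only else frozenset(truth.labels)
    matches = []
    for k in range(membership.rank):
        members = membership.members(k) & keep
        overlaps = {c: jaccard(members, class_sets[c]) for c in classes}
        nonzero = [c for c, j in overlaps.items() if j > 0.0]
        matches.append(ComponentMatch(
            component=k,
            overlaps=overlaps,
            matched_class=nonzero[0] if len(nonzero) == 1 else None,
        ))
    return matches


@dataclass(frozen=True)
class RecallReport:
    """Coverage of the matched class structure.

    ``class_nodes`` counts the students the matched classes are known to
    comprise, ``covered_nodes`` those recovered inside the matching
    components; ``recall`` is their ratio (None when nothing matched).
    """

    n_matched_classes: int
    class_nodes: int
    covered_nodes: int
    recall: float | None


def recall_and_coverage(
    matches: list[ComponentMatch],
    membership: MembershipMatrix,
    truth: GroundTruth,
    students_only: bool = True,
) -> RecallReport:
    """Recall = covered / class_nodes over the matched classes.

    When several components match the same class, coverage counts the union
    of their members (each student once).
    """
    keep = truth.students() if students_only else frozenset(truth.labels)
    by_class: dict[str, set[str]] = {}
    for m in matches:
        if m.matched_class is not None:
            members = membership.members(m.component) & keep
            by_class.setdefault(m.matched_class, set()).update(members)
    class_nodes = 0
    covered = 0
    for label, found in by_class.items():
        known = truth.class_members(label, students_only)
        class_nodes += len(known)
        covered += len(found & known)
    recall = covered / class_nodes if class_nodes else None
    return RecallReport(
        n_matched_classes=len(by_class),
        class_nodes=class_nodes,
        covered_nodes=covered,
        recall=recall,
    )


def score_matrix(
    membership: MembershipMatrix,
    truth: GroundTruth,
    students_only: bool = True,
) -> pd.DataFrame:
    """Classes x components count matrix ``S = P^T Q``.

    Entry (c, k) is the number of students of class c assigned to component
    k.  When the membership encodes the true classes exactly, the matrix is
    a column permutation of the diagonal reference matrix of class sizes.
    """
    keep = truth.students() if students_only else frozenset(truth.labels)
    classes = truth.classes
    values = np.zeros((len(classes), membership.rank), dtype=int)
    for k in range(membership.rank):
        members = membership.members(k) & keep
        for node in members:
            label = truth.labels.get(node)
            if label is not None:
                values[classes.index(label), k] += 1
    return pd.DataFrame(values, index=list(classes),
                        columns=[f"comp{k}" for k in range(membership.rank)])


def reference_score_matrix(truth: GroundTruth, students_only: bool = True) -> pd.DataFrame:
    """``P^T P``: the diagonal matrix of class sizes (students by default)."""
    classes = truth.classes
    sizes = [len(truth.class_members(c, students_only)) for c in classes]
    return pd.DataFrame(np.diag(sizes), index=list(classes), columns=list(classes))


@dataclass(frozen=True)
class LocationFingerprints:
    """Packet counts per (node, receiver, interval): a room-level position proxy."""

    counts: np.ndarray  # nodes x receivers x intervals, non-negative ints
    nodes: tuple[str, ...]
    receivers: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.nodes), len(self.receivers), counts.shape[2]):
            raise ValueError("counts shape inconsistent with node/receiver registries")
        if counts.min(initial=0) < 0 or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("fingerprint counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def n_intervals(self) -> int:
        return self.counts.shape[2]

    def fingerprint(self, node: str) -> np.ndarray:
        return self.counts[self.nodes.index(node)]


@dataclass(frozen=True)
class ColocationSeries:
    """Per-receiver, per-interval co-location index of a component.

    An entry is non-zero iff every member of the component registered packets
    at that receiver in that interval.
    """

    values: np.ndarray  # receivers x intervals
    receivers: tuple[str, ...]
    log_domain: bool = False

    def series(self, receiver: str) -> np.ndarray:
        return self.values[self.receivers.index(receiver)]

    def peak_interval(self, receiver: str) -> int:
        return int(np.argmax(self.series(receiver)))

    def rescaled(self) -> np.ndarray:
        """Each receiver's series rescaled to max 1 (for plotting-style reports)."""
        if self.log_domain:
            raise ValueError("rescale the linear-domain series instead")
        peaks = self.values.max(axis=1, keepdims=True)
        return np.divide(self.values, peaks, where=peaks > 0,
                         out=np.zeros_like(self.values, dtype=float))


def colocation(
    members: frozenset[str] | set[str],
    fingerprints: LocationFingerprints,
    binarize: bool = False,
    log_domain: bool = False,
) -> ColocationSeries:
    """Element-wise product of the members' location fingerprints.

    ``binarize`` replaces counts by presence indicators (an AND across
    members), and ``log_domain`` returns ``sum(log(counts))`` with zero
    counts mapped to -inf — both useful for large components where raw
    products over/underflow.  Members without fingerprint data are treated
    as all-zero, with a warning.
    """
    missing = sorted(set(members) - set(fingerprints.nodes))
    if missing:
        warnings.warn(
            f"members without fingerprint data treated as all-zero: {missing}",
            stacklevel=2,
        )
    shape = (len(fingerprints.receivers), fingerprints.n_intervals)
    if missing:
        values = np.full(shape, -math.inf) if log_domain else np.zeros(shape)
        return ColocationSeries(values=values, receivers=fingerprints.receivers,
                                log_domain=log_domain)
    if not members:  # empty product convention
        values = np.zeros(shape) if log_domain else np.ones(shape)
        return ColocationSeries(values=values, receivers=fingerprints.receivers,
                                log_domain=log_domain)
    stack = np.stack([fingerprints.fingerprint(n).astype(float) for n in sorted(members)])
    if binarize:
        stack = (stack > 0).astype(float)
    if log_domain:
        with np.errstate(divide="ignore"):
            values = np.sum(np.log(stack), axis=0)
    else:
        values = np.prod(stack, axis=0)
    return ColocationSeries(values=values, receivers=fingerprints.receivers,
                            log_domain=log_domain)
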