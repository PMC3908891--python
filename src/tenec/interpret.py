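"""Turning factors into communities and activity timelines.

Membership binarization runs a deterministic scalar 2-means on each column of
the node factor: centers start at the column minimum and maximum, Lloyd
iterations run to a fixed point, and the cluster with the higher center is
the member set.  A node may belong to several components (overlap allowed)
or to none.

The activity strength of component k at interval t combines the temporal
factor and the membership weights: ``s_k(t) = c_tk * sum_i a_ik``.  A
normalized variant uses unit-norm columns with the absorbed component weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diagnostics import component_relevance
from .solver import CPModel, normalize_factors

__all__ = [
    "ActivityProfile",
    "MembershipMatrix",
    "activity_strength",
    "binarize_membership",
    "membership_matrix",
    "summarize_components",
]

_ZERO_EPS = 1e-9


@dataclass(frozen=True)
class MembershipMatrix:
    """Binary node-by-component assignment; rows follow the tensor node order."""

    values: np.ndarray  # N x R, entries in {0, 1}
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if not np.isin(values, (0, 1)).all():
            raise ValueError("membership matrix entries must be 0 or 1")
        object.__setattr__(self, "values", values.astype(np.int8))

    @property
    def rank(self) -> int:
        return self.values.shape[1]

    def members(self, component: int) -> frozenset[str]:
        idx = np.flatnonzero(self.values[:, component])
        return frozenset(self.nodes[i] for i in idx)

    def sizes(self) -> np.ndarray:
        return self.values.sum(axis=0)


@dataclass(frozen=True)
class ActivityProfile:
    """Per-interval activity strength of each component (S x R, non-negative)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.min(initial=0.0) < 0:
            raise ValueError("activity strengths must be non-negative")
        object.__setattr__(self, "values", values)

    def peak_interval(self, component: int) -> int:
        return int(np.argmax(self.values[:, component]))


def binarize_membership(column: np.ndarray, eps: float = _ZERO_EPS) -> np.ndarray:
    """Boolean member mask for one factor column via deterministic scalar 2-means.

    Centers initialize at the column min and max; an equidistant point joins
    the lower cluster; at most 100 Lloyd iterations (scalar 2-means converges
    far sooner).  A column whose maximum is <= ``eps`` has no members, and a
    constant positive column makes every node a member.
    """
    w = np.asarray(column, dtype=float).ravel()
    if w.min(initial=0.0) < 0:
        raise ValueError("membership weights must be non-negative")
    if w.size == 0 or w.max() <= eps:
        return np.zeros(w.size, dtype=bool)
    lo, hi = float(w.min()), float(w.max())
    if lo == hi:
        return np.ones(w.size, dtype=bool)
    high = np.abs(w - hi) < np.abs(w - lo)  # tie -> lower cluster
    for _ in range(100):
        new_lo = float(w[~high].mean()) if (~high).any() else lo
        new_hi = float(w[high].mean()) if high.any() else hi
        new_high = np.abs(w - new_hi) < np.abs(w - new_lo)
        if np.array_equal(new_high, high) and new_lo == lo and new_hi == hi:
            break
        lo, hi, high = new_lo, new_hi, new_high
    return high


def membership_matrix(
    model: CPModel, nodes: tuple[str, ...] | list[str], source: str = "a"
) -> MembershipMatrix:
    """Binarize every column of the node factor into an N x R membership matrix.

    ``source`` selects the first node mode (``"a"``, the default for
    undirected networks), the second (``"b"``), or their normalized average
    (``"mean"``).
    """
    if source == "a":
        weights = model.a
    elif source == "b":
        weights = model.b
    elif source == "mean":
        norm = normalize_factors(model)
        weights = 0.5 * (norm.a + norm.b)
    else:
        raise ValueError(f"unknown membership source {source!r}")
    if weights.shape[0] != len(nodes):
        raise ValueError(
            f"factor has {weights.shape[0]} rows but {len(nodes)} node ids were given"
        )
    cols = [binarize_membership(weights[:, k]) for k in range(model.rank)]
    return MembershipMatrix(values=np.column_stack(cols).astype(np.int8),
                            nodes=tuple(nodes))


def activity_strength(model: CPModel, normalized: bool = False) -> ActivityProfile:
    """Activity strength ``s_k(t) = c_tk * sum_i a_ik`` for every component.

    With ``normalized=True`` the columns of A and C are rescaled to unit L2
    norm and the absorbed component weight ||a_k||*||b_k||*||c_k|| multiplies
    the profile instead, which decouples the shape of the timeline from the
    raw factor scaling.
    """
    if normalized:
        lam = component_relevance(model)
        a_norms = np.linalg.norm(model.a, axis=0)
        c_norms = np.linalg.norm(model.c, axis=0)
        a = np.divide(model.a, a_norms, where=a_norms > 0, out=np.zeros_like(model.a))
        c = np.divide(model.c, c_norms, where=c_norms > 0, out=np.zeros_like(model.c))
        values = c * (a.sum(axis=0) * lam)
    else:
        values = model.c * model.a.sum(axis=0)
    return ActivityProfile(values=values)


def summarize_components(model: CPModel, membership: MembershipMatrix) -> pd.DataFrame:
    """Component table (size, relevance, activity peak), relevance-descending.

    Empty components are listed with size 0; ``component`` is the column
    index in the original factor order.
    """
    rel = component_relevance(model)
    profile = activity_strength(model)
    sizes = membership.sizes()
    frame = pd.DataFrame({
        "component": np.arange(model.rank),
        "size": sizes,
        "relevance": rel,
        "peak_interval": [profile.peak_interval(k) for k in range(model.rank)],
    })
    frame = frame.sort_values(
        ["relevance", "component"], ascending=[False, True], kind="mergesort"
    )
    return frame.reset_index(drop=True)
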