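"""Non-negative PARAFAC by alternating non-negative least squares (ANLS).

Each sweep solves the three matricized sub-problems exactly::

    min_{A>=0} || unfold(T,1) - A (C kr B)^T ||_F
    min_{B>=0} || unfold(T,2) - B (A kr C)^T ||_F
    min_{C>=0} || unfold(T,3) - C (B kr A)^T ||_F

using block principal pivoting on the normal equations, with the classic
Lawson-Hanson active-set solver as a fallback when pivoting cycles.  Exact
block minimization makes the objective monotone non-increasing, which the
sweep asserts at run time.  The multi-restart protocol draws every restart's
initial factors from an independently seeded generator so that a run list is
reproducible from ``(seed, run_index)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.optimize

from .tensor import cp_reconstruct, frobenius, khatri_rao, relative_fit, unfold

__all__ = [
    "CPModel",
    "SolverConfig",
    "SolverRegressionError",
    "als_sweep",
    "factorize",
    "nnls_block",
    "normalize_factors",
]

_FEAS_TOL = 1e-12


class SolverRegressionError(RuntimeError):
    """The ALS objective increased beyond numerical tolerance (solver bug guard)."""


@dataclass(frozen=True)
class CPModel:
    """A non-negative Kruskal model ``T ~ sum_r a_r o b_r o c_r``.

    ``a`` and ``b`` carry node-mode membership weights (identical up to noise
    for undirected input), ``c`` the per-interval activity of each component.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    objective: float = np.nan
    fit: float = np.nan
    n_iter: int = 0
    seed: int | None = None
    converged: bool = False
    asymmetry: float = np.nan
    collapsed: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        a, b, c = (np.atleast_2d(np.asarray(m, dtype=float)) for m in (self.a, self.b, self.c))
        if not (a.shape[1] == b.shape[1] == c.shape[1]):
            raise ValueError("factor column counts differ")
        if min(a.min(initial=0), b.min(initial=0), c.min(initial=0)) < 0:
            raise ValueError("CPModel factors must be non-negative")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    @property
    def rank(self) -> int:
        return self.a.shape[1]

    def reconstruct(self) -> np.ndarray:
        return cp_reconstruct(self.a, self.b, self.c)


@dataclass(frozen=True)
class SolverConfig:
    """Run protocol parameters.

    ``tol`` is the relative objective-change threshold declaring convergence;
    the iteration cap and restart count default to values suitable for
    hundreds of nodes and are fully configurable.
    """

    rank: int
    n_runs: int = 20
    max_iter: int = 500
    tol: float = 1e-7
    seed: int = 0
    nnls_method: str = "block-pivot"

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.nnls_method not in ("block-pivot", "active-set"):
            raise ValueError(f"unknown nnls_method {self.nnls_method!r}")


def _nnls_bpp_row(gram: np.ndarray, d: np.ndarray, max_steps: int = 1000) -> np.ndarray | None:
    """Single-RHS NNLS on normal equations (Kim & Park block principal pivoting).

    Solves min_{x>=0} 1/2 x' gram x - d' x.  Returns None if pivoting cycles.
    """
    r = len(d)
    passive = np.zeros(r, dtype=bool)
    x = np.zeros(r)
    y = -d.copy()
    backup = 3
    n_infeasible = r + 1
    for _ in range(max_steps):
        infeasible = (passive & (x < -_FEAS_TOL)) | (~passive & (y < -_FEAS_TOL))
        count = int(infeasible.sum())
        if count == 0:
            break
        if count < n_infeasible:
            n_infeasible = count
            backup = 3
            swap = infeasible
        elif backup > 0:
            backup -= 1
            swap = infeasible
        else:
            # cycle guard: swap only the lowest-index infeasible variable
            swap = np.zeros(r, dtype=bool)
            swap[np.flatnonzero(infeasible)[0]] = True
        passive = passive ^ swap
        x = np.zeros(r)
        y = -d.copy()
        if passive.any():
            sub = np.ix_(passive, passive)
            try:
                x[passive] = np.linalg.solve(gram[sub], d[passive])
            except np.linalg.LinAlgError:
                x[passive] = np.linalg.lstsq(gram[sub], d[passive], rcond=None)[0]
            y = gram @ x - d
            y[passive] = 0.0
    else:
        return None
    infeasible = (passive & (x < -_FEAS_TOL)) | (~passive & (y < -_FEAS_TOL))
    if infeasible.any():
        return None
    return np.maximum(x, 0.0)


def nnls_block(x: np.ndarray, k: np.ndarray, method: str = "block-pivot") -> np.ndarray:
    """Solve ``min_{F>=0} ||X - F K^T||_F`` row-wise exactly.

    Each row of ``F`` is the solution of an independent non-negative least
    squares problem in the columns of ``K``.  Zero columns of ``K`` leave the
    corresponding coefficient undetermined; it is fixed at 0 with a warning.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    k = np.atleast_2d(np.asarray(k, dtype=float))
    if np.isnan(k).any() or np.isnan(x).any():
        raise ValueError("nnls_block does not accept NaN entries")
    n_rows, r = x.shape[0], k.shape[1]
    if x.shape[1] != k.shape[0]:
        raise ValueError(f"shape mismatch: X {x.shape} vs K {k.shape}")
    live = np.linalg.norm(k, axis=0) > 0.0
    if not live.all():
        warnings.warn(
            f"{int((~live).sum())} zero column(s) in K; coefficients fixed at 0",
            stacklevel=2,
        )
    f = np.zeros((n_rows, r))
    ksub = k[:, live]
    if ksub.shape[1] == 0:
        return f
    gram = ksub.T @ ksub
    rhs = x @ ksub
    fsub = np.empty((n_rows, ksub.shape[1]))
    for row in range(n_rows):
        sol = None
        if method == "block-pivot":
            sol = _nnls_bpp_row(gram, rhs[row])
        if sol is None:  # active-set fallback (or explicit request)
            sol = scipy.optimize.nnls(ksub, x[row])[0]
        fsub[row] = sol
    f[:, live] = fsub
    return f


def _objective(values: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    return frobenius(values - cp_reconstruct(a, b, c))


def als_sweep(values: np.ndarray, model: CPModel, method: str | None = None) -> CPModel:
    """One cyclic ANLS sweep updating A, then B, then C by exact block solves.

    Raises :class:`SolverRegressionError` if the objective increases beyond
    1e-10 (relative), which with exact block minimization can only indicate a
    solver defect.
    """
    values = np.asarray(values, dtype=float)
    method = method or "block-pivot"
    before = _objective(values, model.a, model.b, model.c)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # collapsed columns handled by the caller
        a = nnls_block(unfold(values, 1), khatri_rao(model.c, model.b), method)
        b = nnls_block(unfold(values, 2), khatri_rao(a, model.c), method)
        c = nnls_block(unfold(values, 3), khatri_rao(b, a), method)
    after = _objective(values, a, b, c)
    if after - before > 1e-10 * max(1.0, before):
        raise SolverRegressionError(
            f"objective increased within a sweep: {before!r} -> {after!r}"
        )
    return replace(
        model,
        a=a,
        b=b,
        c=c,
        objective=after,
        fit=relative_fit(values, cp_reconstruct(a, b, c)) if frobenius(values) > 0 else np.nan,
        n_iter=model.n_iter + 1,
    )


def normalize_factors(model: CPModel) -> CPModel:
    """Rescale A and B columns to unit L2 norm, absorbing the scale into C.

    The reconstruction is unchanged; zero columns are left untouched.
    """
    a, b, c = model.a.copy(), model.b.copy(), model.c.copy()
    for col in range(model.rank):
        na, nb = np.linalg.norm(a[:, col]), np.linalg.norm(b[:, col])
        if na > 0:
            a[:, col] /= na
        if nb > 0:
            b[:, col] /= nb
        c[:, col] *= na * nb
    return replace(model, a=a, b=b, c=c)


def _asymmetry(model: CPModel) -> float:
    """||A_n - B_n||_F / ||A_n||_F on unit-normalized columns (0 when A == B)."""
    norm = normalize_factors(model)
    denom = frobenius(norm.a)
    return frobenius(norm.a - norm.b) / denom if denom > 0 else np.nan


def _init_factors(rng: np.random.Generator, shape: tuple[int, int, int], rank: int,
                  scale: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(rng.uniform(size=(dim, rank)) * scale for dim in shape)


def factorize(values: np.ndarray, config: SolverConfig) -> list[CPModel]:
    """Multi-restart non-negative PARAFAC; one :class:`CPModel` per run.

    Every restart draws i.i.d. uniform(0,1) factors scaled by ``mean(T)**(1/3)``
    and iterates ANLS sweeps until the relative objective change drops below
    ``config.tol`` or ``config.max_iter`` is hit.  A factor column that
    collapses to zero is re-seeded once from uniform noise; a second collapse
    leaves it at zero and flags the component index.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("expected a 3-way tensor")
    if values.min() < 0:
        raise ValueError("non-negative factorization requires a non-negative tensor")
    n1, n2, s = values.shape
    if config.rank > max(n1 * n2, s):
        warnings.warn(
            f"rank {config.rank} exceeds both N*N={n1 * n2} and S={s}", stacklevel=2
        )
    mean = float(values.mean())
    scale = mean ** (1.0 / 3.0) if mean > 0 else 1.0
    unfolds = {m: unfold(values, m) for m in (1, 2, 3)}
    models = []
    for run in range(config.n_runs):
        rng = np.random.default_rng([config.seed, run])
        a, b, c = _init_factors(rng, values.shape, config.rank, scale)
        prev = _objective(values, a, b, c)
        converged = False
        reseeded: set[int] = set()
        collapsed: set[int] = set()
        n_iter = 0
        for n_iter in range(1, config.max_iter + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a = nnls_block(unfolds[1], khatri_rao(c, b), config.nnls_method)
                b = nnls_block(unfolds[2], khatri_rao(a, c), config.nnls_method)
                c = nnls_block(unfolds[3], khatri_rao(b, a), config.nnls_method)
            for col in range(config.rank):
                if a[:, col].max() == 0 or b[:, col].max() == 0 or c[:, col].max() == 0:
                    if col in reseeded:
                        collapsed.add(col)
                        a[:, col] = b[:, col] = 0.0
                        c[:, col] = 0.0
                    else:
                        reseeded.add(col)
                        a[:, col] = rng.uniform(size=n1) * scale
                        b[:, col] = rng.uniform(size=n2) * scale
                        c[:, col] = rng.uniform(size=s) * scale
            cur = _objective(values, a, b, c)
            if abs(prev - cur) <= config.tol * max(prev, np.finfo(float).tiny):
                converged = True
                prev = cur
                break
            prev = cur
        fit = relative_fit(values, cp_reconstruct(a, b, c)) if frobenius(values) > 0 else np.nan
        model = CPModel(
            a=a, b=b, c=c,
            objective=prev, fit=fit, n_iter=n_iter,
            seed=run, converged=converged,
            collapsed=tuple(sorted(collapsed)),
        )
        models.append(replace(model, asymmetry=_asymmetry(model)))
    return models
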