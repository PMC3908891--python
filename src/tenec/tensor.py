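"""Dense three-way tensor algebra.

Unfolding/folding (matricization), Khatri-Rao products, Kruskal/CP
reconstruction, Frobenius norms and the fixed-factor Tucker core fit that
underlies the core-consistency diagnostic.

Conventions
-----------
Mode-``n`` unfolding follows a cyclic layout.  For a tensor of shape
``(I, J, K)``:

* mode 1 -> ``I x (J*K)``, column index ``j + J*k``
* mode 2 -> ``J x (K*I)``, column index ``k + K*i``
* mode 3 -> ``K x (I*J)``, column index ``i + I*j``

Under this layout the Kruskal identities read::

    unfold(T, 1) = A @ khatri_rao(C, B).T
    unfold(T, 2) = B @ khatri_rao(A, C).T
    unfold(T, 3) = C @ khatri_rao(B, A).T

where ``khatri_rao`` is the column-wise Kronecker product.  All public
functions accept and return plain :class:`numpy.ndarray` objects; a dense
3-d float array is the in-memory tensor carrier throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "CoreTensor",
    "cp_reconstruct",
    "fold",
    "frobenius",
    "khatri_rao",
    "mode_product",
    "relative_fit",
    "tucker_core_fit",
    "unfold",
    "unit_superdiagonal",
]

# axis permutations realizing the cyclic unfolding layout
_UNFOLD_PERM = {1: (0, 2, 1), 2: (1, 0, 2), 3: (2, 1, 0)}


def _check_mode(mode: int) -> None:
    if mode not in (1, 2, 3):
        raise ValueError(f"mode must be 1, 2 or 3, got {mode!r}")


def unfold(values: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` matricization of a 3-way tensor (cyclic layout)."""
    _check_mode(mode)
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected a 3-way tensor, got ndim={values.ndim}")
    perm = _UNFOLD_PERM[mode]
    t = values.transpose(perm)
    return t.reshape(t.shape[0], -1)


def fold(matrix: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold`: rebuild the 3-way tensor of ``shape``."""
    _check_mode(mode)
    matrix = np.asarray(matrix)
    perm = _UNFOLD_PERM[mode]
    inter = tuple(shape[p] for p in perm)
    if matrix.shape != (inter[0], inter[1] * inter[2]):
        raise ValueError(
            f"matrix of shape {matrix.shape} cannot be folded into {shape} along mode {mode}"
        )
    return matrix.reshape(inter).transpose(np.argsort(perm))


def khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product of ``a`` (I x R) and ``b`` (J x R) -> IJ x R."""
    a = np.atleast_2d(np.asarray(a))
    b = np.atleast_2d(np.asarray(b))
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"column counts differ: {a.shape[1]} vs {b.shape[1]}"
        )
    return scipy.linalg.khatri_rao(a, b)


def cp_reconstruct(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Dense tensor with entries ``sum_r a[i,r] * b[j,r] * c[k,r]`` (Kruskal form)."""
    a, b, c = (np.atleast_2d(np.asarray(m, dtype=float)) for m in (a, b, c))
    if not (a.shape[1] == b.shape[1] == c.shape[1]):
        raise ValueError(
            f"factor column counts differ: {a.shape[1]}, {b.shape[1]}, {c.shape[1]}"
        )
    shape = (a.shape[0], b.shape[0], c.shape[0])
    return fold(a @ khatri_rao(c, b).T, 1, shape)


def frobenius(values: np.ndarray) -> float:
    """Frobenius norm: square root of the sum of squared entries."""
    return float(np.sqrt(np.sum(np.square(np.asarray(values, dtype=float)))))


def relative_fit(values: np.ndarray, approx: np.ndarray) -> float:
    """``1 - ||T - That||_F / ||T||_F``; 1 for a perfect fit, 0 for the zero model."""
    denom = frobenius(values)
    if denom == 0.0:
        raise ValueError("relative fit is undefined for an all-zero tensor")
    return 1.0 - frobenius(np.asarray(values, float) - np.asarray(approx, float)) / denom


def mode_product(values: np.ndarray, matrix: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` product: contract axis ``mode-1`` of the tensor with ``matrix``."""
    _check_mode(mode)
    values = np.asarray(values, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    out = np.tensordot(matrix, values, axes=(1, mode - 1))
    # tensordot puts the new axis first; rotate it back into place
    return np.moveaxis(out, 0, mode - 1)


def unit_superdiagonal(r: int) -> np.ndarray:
    """R x R x R tensor with ones on the superdiagonal, zeros elsewhere."""
    eye = np.zeros((r, r, r))
    idx = np.arange(r)
    eye[idx, idx, idx] = 1.0
    return eye


@dataclass(frozen=True)
class CoreTensor:
    """Least-squares Tucker core for fixed factors.

    ``values`` is an R x R x R cube (entries may be negative even when the
    factors are non-negative).  ``rank_deficient`` is set when any factor
    matrix fell short of full column rank and the fit went through a
    pseudoinverse null-space.
    """

    values: np.ndarray
    rank_deficient: bool = False

    @property
    def r(self) -> int:
        return self.values.shape[0]


def tucker_core_fit(
    values: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> CoreTensor:
    """Core ``G`` minimizing ``||T - G x1 A x2 B x3 C||_F`` with the factors fixed.

    Because the Kronecker product of pseudoinverses is the pseudoinverse of the
    Kronecker product, the minimizer is ``G = T x1 pinv(A) x2 pinv(B) x3 pinv(C)``.
    Singular values below ``max(shape) * eps * sigma_max`` are truncated.
    """
    values = np.asarray(values, dtype=float)
    a, b, c = (np.atleast_2d(np.asarray(m, dtype=float)) for m in (a, b, c))
    r = a.shape[1]
    if not (b.shape[1] == c.shape[1] == r):
        raise ValueError("factors must share the same column count")
    if r > min(values.shape):
        warnings.warn(
            f"R={r} exceeds a tensor mode of shape {values.shape}; "
            "the core fit is rank-deficient by construction",
            stacklevel=2,
        )
    deficient = False
    pinvs = []
    for m in (a, b, c):
        rcond = max(m.shape) * np.finfo(float).eps
        if np.linalg.matrix_rank(m, tol=rcond * np.linalg.norm(m, 2)) < r:
            deficient = True
        pinvs.append(np.linalg.pinv(m, rcond=rcond))
    g = values
    for mode, p in enumerate(pinvs, start=1):
        g = mode_product(g, p, mode)
    return CoreTensor(values=g, rank_deficient=deficient)
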