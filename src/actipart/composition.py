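"""Aitchison-simplex arithmetic and descriptive compositional statistics.

A composition is a vector of D strictly positive parts carrying only
relative information; it is represented here as a plain ``numpy`` array
closed to sum 1.  The simplex is given the Aitchison geometry: perturbation
(the group operation), powering (scalar multiplication), and the inner
product induced by the centred log-ratio (clr) transform.  The isometric
log-ratio (ilr) transform maps the D-part simplex isometrically onto
R^(D-1) and is what the regression layer feeds to ordinary least squares.

All logarithms are natural.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "close",
    "multiplicative_replacement",
    "perturb",
    "inverse",
    "power",
    "clr",
    "clr_inv",
    "IlrBasis",
    "pivot_basis",
    "ilr",
    "ilr_inv",
    "aitchison_inner",
    "aitchison_norm",
    "aitchison_distance",
    "neutral",
    "closed_geometric_mean",
    "VariationSummary",
    "variation_summary",
]


def _as_parts(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("composition must be a 1-D vector of parts")
    return x


def close(raw) -> np.ndarray:
    """Closure: divide a nonnegative vector by its sum.

    Zeros are tolerated here (use :func:`multiplicative_replacement`
    before any log-ratio operation); an all-zero vector is rejected.
    """
    x = _as_parts(raw)
    if np.any(x < 0):
        raise ValueError("composition parts must be nonnegative")
    s = x.sum()
    if s <= 0:
        raise ValueError("cannot close an all-zero vector")
    return x / s


def multiplicative_replacement(x, delta: float | None = None) -> np.ndarray:
    """Replace zero parts by a small value delta, rescaling the rest.

    ``delta`` defaults to half the smallest nonzero proportion in ``x``.
    Nonzero parts are shrunk by the total mass given to zeros so the
    result still sums to one.
    """
    x = close(x)
    zero = x == 0
    if not zero.any():
        return x
    if delta is None:
        delta = 0.5 * x[x > 0].min()
    if delta <= 0 or delta * zero.sum() >= 1:
        raise ValueError("invalid replacement delta")
    out = x * (1.0 - delta * zero.sum())
    out[zero] = delta
    return out


def _require_positive(x: np.ndarray) -> np.ndarray:
    if np.any(x <= 0):
        raise ValueError("composition parts must be strictly positive")
    return x


def neutral(D: int) -> np.ndarray:
    """Neutral element of the simplex: (1/D, ..., 1/D)."""
    return np.full(D, 1.0 / D)


def perturb(x, y) -> np.ndarray:
    """Simplex addition: closed component-wise product."""
    x = _require_positive(_as_parts(x))
    y = _require_positive(_as_parts(y))
    return close(x * y)


def inverse(x) -> np.ndarray:
    """Perturbation inverse, so that perturb(x, inverse(x)) = neutral."""
    x = _require_positive(_as_parts(x))
    return close(1.0 / x)


def power(t: float, x) -> np.ndarray:
    """Simplex scalar multiplication: closed component-wise power."""
    x = _require_positive(_as_parts(x))
    return close(x**t)


def clr(x) -> np.ndarray:
    """Centred log-ratio: ln(x_i / g(x)) with g the geometric mean."""
    x = _require_positive(_as_parts(x))
    lx = np.log(x)
    return lx - lx.mean()


def clr_inv(v) -> np.ndarray:
    """Inverse clr; ``v`` must sum to zero (within 1e-8)."""
    v = np.asarray(v, dtype=float)
    if abs(v.sum()) > 1e-8:
        raise ValueError("clr vector must sum to zero")
    return close(np.exp(v))


@dataclass(frozen=True)
class IlrBasis:
    """An orthonormal ilr contrast basis: a (D-1) x D matrix whose rows
    sum to zero and are orthonormal in the ordinary Euclidean sense (which
    is orthonormality under the clr inner product for zero-sum vectors)."""

    contrast_matrix: np.ndarray

    def __post_init__(self):
        B = np.asarray(self.contrast_matrix, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1] - 1:
            raise ValueError("contrast matrix must be (D-1) x D")
        if np.abs(B.sum(axis=1)).max() > 1e-8:
            raise ValueError("contrast rows must sum to zero")
        if np.abs(B @ B.T - np.eye(B.shape[0])).max() > 1e-8:
            raise ValueError("contrast rows must be orthonormal")
        object.__setattr__(self, "contrast_matrix", B)

    @property
    def D(self) -> int:
        return self.contrast_matrix.shape[1]


def pivot_basis(D: int) -> IlrBasis:
    """Pivot (sequential binary partition) ilr basis in the given part order.

    Row r contrasts part r against the geometric mean of parts r+1..D.
    """
    if D < 2:
        raise ValueError("need at least two parts")
    B = np.zeros((D - 1, D))
    for r in range(D - 1):
        k = D - r - 1  # parts to the right of the pivot
        norm = np.sqrt(k / (k + 1.0))
        B[r, r] = norm
        B[r, r + 1 :] = -norm / k
    return IlrBasis(B)


def ilr(x, basis: IlrBasis) -> np.ndarray:
    """Isometric log-ratio coordinates: contrast_matrix . clr(x)."""
    return basis.contrast_matrix @ clr(x)


def ilr_inv(v, basis: IlrBasis) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (basis.D - 1,):
        raise ValueError("coordinate vector has wrong length for basis")
    return clr_inv(basis.contrast_matrix.T @ v)


def aitchison_inner(x, y) -> float:
    """Aitchison inner product: the Euclidean product of clr vectors."""
    return float(clr(x) @ clr(y))


def aitchison_norm(x) -> float:
    return float(np.linalg.norm(clr(x)))


def aitchison_distance(x, y) -> float:
    return float(np.linalg.norm(clr(x) - clr(y)))


def closed_geometric_mean(xs) -> np.ndarray:
    """Component-wise geometric mean of compositions, closed.

    This is the compositional center: identical to clr_inv of the mean of
    the clr vectors.
    """
    X = np.asarray(xs, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("need a nonempty 2-D array of compositions")
    _require_positive(X.ravel())
    return close(np.exp(np.log(X).mean(axis=0)))


@dataclass(frozen=True)
class VariationSummary:
    """Compositional center and clr covariance of a sample of compositions."""

    closed_geometric_mean: np.ndarray
    clr_covariance: np.ndarray


def variation_summary(xs) -> VariationSummary:
    """Closed geometric mean plus clr covariance matrix (rows/cols sum to 0)."""
    X = np.asarray(xs, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two compositions")
    C = np.stack([clr(row) for row in X])
    cov = np.cov(C, rowvar=False)
    return VariationSummary(closed_geometric_mean(X), np.atleast_2d(cov))
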