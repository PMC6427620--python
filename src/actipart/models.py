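"""The three model families linking behavior time use to health outcomes.

1. Compositional linear models: ordinary least squares on the ilr
   coordinates of the time budget plus covariates; the fitted ilr
   coefficients are mapped back to the simplex and reported as a
   unit-Aitchison-norm direction composition and a magnitude |beta|.
   Every reported quantity is invariant to the ilr basis.

2. Iso-temporal substitution models: OLS on the raw time-share
   proportions with one behavior (the displaced one) omitted; each
   included behavior's coefficient is the outcome change when one unit of
   time share moves from the displaced behavior to it.

3. Partitioning-index models: OLS of the outcome on a fragmentation
   index (median bout length, Gini, or bout/total ratio), optionally its
   square, with the ilr time budget and covariates as controls.

Prediction and contrast helpers evaluate fitted (or externally reported)
coefficients on hypothetical time-budget profiles via the Aitchison inner
product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .composition import (
    IlrBasis,
    aitchison_norm,
    clr,
    clr_inv,
    close,
    ilr,
    pivot_basis,
)

__all__ = [
    "CompositionalLMFit",
    "fit_compositional_lm",
    "predict_outcome",
    "profile_contrast",
    "IsotemporalFit",
    "fit_isotemporal",
    "ReallocationMatrix",
    "reallocation_matrix",
    "reallocation_effect",
    "PartitioningFit",
    "fit_partitioning",
    "effect_delta",
    "vertex",
    "significance_tier",
]


def significance_tier(p: float) -> str:
    """Footnote markers: dagger <0.1, * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "†"
    return ""


def _design(ilr_coords, covariates):
    parts = [np.ones((ilr_coords.shape[0], 1)), ilr_coords]
    if covariates is not None and covariates.shape[1] > 0:
        parts.append(covariates)
    return np.hstack(parts)


def _as_2d(a):
    if a is None:
        return None
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    return a


# ---------------------------------------------------------------------------
# Compositional linear model


@dataclass
class CompositionalLMFit:
    """OLS fit of outcome on [ilr(x) | z], reported in Aitchison form.

    beta_direction is a composition with unit Aitchison norm; the full
    coefficient composition is beta_direction powered by beta_norm, and
    the compositional contribution to a prediction is
    beta_norm * <beta_direction, x>_A.
    """

    alpha: float
    beta_direction: np.ndarray
    beta_norm: float
    gamma: np.ndarray
    basis: IlrBasis
    sigma_resid: float
    model_p: float
    n: int
    ilr_coefs: np.ndarray

    @property
    def beta_clr(self) -> np.ndarray:
        return self.beta_norm * clr(self.beta_direction)


def fit_compositional_lm(outcomes, compositions, covariates=None, basis: IlrBasis | None = None) -> CompositionalLMFit:
    """Fit the compositional linear model Y = a + <beta, x>_A + gamma.z + eps.

    The D-1 ilr coefficients b are mapped to clr space as B^T b (B the
    contrast matrix); beta_norm is that vector's Euclidean norm and
    beta_direction its clr_inv after normalization.  model_p is the
    partial F-test of the whole ilr block being jointly zero.
    """
    y = np.asarray(outcomes, dtype=float)
    X = np.asarray(compositions, dtype=float)
    Z = _as_2d(covariates)
    D = X.shape[1]
    if basis is None:
        basis = pivot_basis(D)
    n = y.size
    n_cov = 0 if Z is None else Z.shape[1]
    if n <= D - 1 + n_cov + 1:
        raise ValueError("not enough subjects for the model's parameters")
    coords = np.stack([ilr(row, basis) for row in X])
    design = _design(coords, Z)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.OLS(y, design).fit()

    b_ilr = res.params[1:D]
    beta_clr = basis.contrast_matrix.T @ b_ilr
    beta_norm = float(np.linalg.norm(beta_clr))
    if beta_norm > 0:
        direction = clr_inv(beta_clr / beta_norm)
    else:
        direction = close(np.ones(D))
    # joint F-test: ilr block = 0
    R = np.zeros((D - 1, design.shape[1]))
    R[:, 1:D] = np.eye(D - 1)
    model_p = float(res.f_test(R).pvalue)
    gamma = res.params[D:] if Z is not None else np.zeros(0)
    return CompositionalLMFit(
        alpha=float(res.params[0]),
        beta_direction=direction,
        beta_norm=beta_norm,
        gamma=np.asarray(gamma, dtype=float),
        basis=basis,
        sigma_resid=float(np.sqrt(res.scale)),
        model_p=model_p,
        n=n,
        ilr_coefs=np.asarray(b_ilr, dtype=float),
    )


def predict_outcome(fit: CompositionalLMFit, x, z=None) -> float:
    """alpha + <beta, x>_A + gamma.z for one composition x."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("composition must be strictly positive")
    comp_term = float(fit.beta_clr @ clr(x))
    cov_term = 0.0
    if fit.gamma.size:
        z = np.asarray(z, dtype=float)
        if z.shape != fit.gamma.shape:
            raise ValueError("covariate vector length does not match the fit")
        cov_term = float(fit.gamma @ z)
    return fit.alpha + comp_term + cov_term


def profile_contrast(
    coefficients,
    profile,
    reference,
    log_outcome: bool = False,
) -> float:
    """Predicted outcome change when the time budget moves from
    ``reference`` to ``profile``: Delta = <beta, profile (-) reference>_A.

    ``coefficients`` is a :class:`CompositionalLMFit` or a
    ``(direction, norm)`` pair, e.g. a published normalized coefficient
    vector and its magnitude.  With ``log_outcome`` the result is returned
    on the original outcome scale as the ratio exp(Delta).
    """
    if isinstance(coefficients, CompositionalLMFit):
        beta_clr = coefficients.beta_clr
    else:
        direction, norm = coefficients
        dvec = clr(close(np.asarray(direction, dtype=float)))
        nrm = np.linalg.norm(dvec)
        if nrm == 0:
            raise ValueError("direction cannot be the neutral element")
        beta_clr = float(norm) * dvec / nrm
    p = close(np.asarray(profile, dtype=float))
    r = close(np.asarray(reference, dtype=float))
    delta = float(beta_clr @ (clr(p) - clr(r)))
    return float(np.exp(delta)) if log_outcome else delta


# ---------------------------------------------------------------------------
# Iso-temporal substitution


@dataclass
class IsotemporalFit:
    """OLS on time-share proportions with one behavior displaced.

    ``estimates[b]`` is the outcome change per unit of time share moved
    from the displaced behavior to behavior ``b``."""

    displaced: str
    behaviors: tuple
    estimates: dict
    ci_low: dict
    ci_high: dict
    p_values: dict
    tiers: dict
    gamma: np.ndarray
    alpha: float
    n: int


def fit_isotemporal(outcomes, proportions, behavior_names, displaced, covariates=None, alpha_level: float = 0.05) -> IsotemporalFit:
    """Iso-temporal substitution model for one displaced behavior."""
    y = np.asarray(outcomes, dtype=float)
    P = np.asarray(proportions, dtype=float)
    names = tuple(behavior_names)
    if displaced not in names:
        raise ValueError(f"displaced behavior {displaced!r} not in {names}")
    if np.abs(P.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("proportions must sum to 1 for every subject")
    Z = _as_2d(covariates)
    keep = [i for i, b in enumerate(names) if b != displaced]
    design = _design(P[:, keep], Z)
    res = sm.OLS(y, design).fit()
    ci = res.conf_int(alpha=alpha_level)
    est, lo, hi, pv, tier = {}, {}, {}, {}, {}
    for j, i in enumerate(keep, start=1):
        b = names[i]
        est[b] = float(res.params[j])
        lo[b] = float(ci[j, 0])
        hi[b] = float(ci[j, 1])
        pv[b] = float(res.pvalues[j])
        tier[b] = significance_tier(pv[b])
    n_b = len(keep)
    gamma = res.params[1 + n_b :] if Z is not None else np.zeros(0)
    return IsotemporalFit(
        displaced=displaced,
        behaviors=names,
        estimates=est,
        ci_low=lo,
        ci_high=hi,
        p_values=pv,
        tiers=tier,
        gamma=np.asarray(gamma, dtype=float),
        alpha=float(res.params[0]),
        n=y.size,
    )


@dataclass
class ReallocationMatrix:
    """D x D grid of pairwise reallocation effects.

    ``estimate[i, j]`` is the outcome change when one unit of time share
    moves from behavior j (column) to behavior i (row); the grid is
    antisymmetric with a zero diagonal."""

    behaviors: tuple
    estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray

    def effect(self, coefficient_or_pair, reallocation: float) -> float:
        """Outcome change for a given reallocated share, e.g. a matrix
        entry times 0.01 for a one-percent shift."""
        if isinstance(coefficient_or_pair, tuple):
            frm, to = coefficient_or_pair
            i = self.behaviors.index(to)
            j = self.behaviors.index(frm)
            coef = self.estimate[i, j]
        else:
            coef = float(coefficient_or_pair)
        return coef * reallocation


def reallocation_effect(coefficient: float, reallocated_share: float) -> float:
    """Outcome change for a given reallocated time share: the model
    coefficient times the share moved (e.g. 0.01 for one percent of the
    time budget)."""
    return float(coefficient) * float(reallocated_share)


def reallocation_matrix(outcomes, proportions, behavior_names, covariates=None) -> ReallocationMatrix:
    """Assemble the full pairwise reallocation grid by looping the
    displaced behavior over all D classes."""
    names = tuple(behavior_names)
    D = len(names)
    est = np.zeros((D, D))
    lo = np.full((D, D), np.nan)
    hi = np.full((D, D), np.nan)
    pv = np.full((D, D), np.nan)
    for j, displaced in enumerate(names):
        fit = fit_isotemporal(outcomes, proportions, names, displaced, covariates)
        for i, b in enumerate(names):
            if b == displaced:
                continue
            est[i, j] = fit.estimates[b]
            lo[i, j] = fit.ci_low[b]
            hi[i, j] = fit.ci_high[b]
            pv[i, j] = fit.p_values[b]
    return ReallocationMatrix(names, est, lo, hi, pv)


# ---------------------------------------------------------------------------
# Partitioning-index models


@dataclass
class PartitioningFit:
    """OLS of outcome on [index (, index^2) | ilr(x) | z]."""

    coef_index: float
    ci_index: tuple
    p_index: float
    coef_index_sq: float | None
    ci_index_sq: tuple | None
    p_index_sq: float | None
    quadratic_included: bool
    gamma: np.ndarray
    ilr_coefs: np.ndarray
    alpha: float
    n: int
    n_dropped: int

    @property
    def tier_index(self) -> str:
        return significance_tier(self.p_index)


def fit_partitioning(
    outcomes,
    index,
    compositions,
    covariates=None,
    quadratic: str = "auto",
    basis: IlrBasis | None = None,
    alpha_level: float = 0.05,
) -> PartitioningFit:
    """Partitioning-index regression with the ilr time budget as control.

    ``quadratic`` is 'auto' (include index^2 iff its partial F-test has
    p < 0.05), 'on' or 'off'.  Subjects with a non-finite index (e.g. no
    bout of the class-set) are dropped and counted in ``n_dropped``.
    """
    y = np.asarray(outcomes, dtype=float)
    idx = np.asarray(index, dtype=float)
    X = np.asarray(compositions, dtype=float)
    Z = _as_2d(covariates)
    ok = np.isfinite(idx)
    n_dropped = int((~ok).sum())
    y, idx, X = y[ok], idx[ok], X[ok]
    if Z is not None:
        Z = Z[ok]
    if np.ptp(idx) == 0:
        raise ValueError("index is constant; cannot fit")
    D = X.shape[1]
    if basis is None:
        basis = pivot_basis(D)
    coords = np.stack([ilr(row, basis) for row in X])

    def build(with_sq: bool):
        cols = [idx[:, None]]
        if with_sq:
            cols.append(idx[:, None] ** 2)
        cols.append(coords)
        if Z is not None:
            cols.append(Z)
        return _design(np.hstack(cols), None)

    if quadratic not in ("auto", "on", "off"):
        raise ValueError("quadratic must be 'auto', 'on' or 'off'")
    include_sq = quadratic == "on"
    if quadratic == "auto":
        res_q = sm.OLS(y, build(True)).fit()
        include_sq = res_q.pvalues[2] < 0.05
    res = sm.OLS(y, build(include_sq)).fit()
    ci = res.conf_int(alpha=alpha_level)
    off = 2
    sq = (None, None, None)
    if include_sq:
        sq = (float(res.params[2]), (float(ci[2, 0]), float(ci[2, 1])), float(res.pvalues[2]))
        off = 3
    n_cov = 0 if Z is None else Z.shape[1]
    return PartitioningFit(
        coef_index=float(res.params[1]),
        ci_index=(float(ci[1, 0]), float(ci[1, 1])),
        p_index=float(res.pvalues[1]),
        coef_index_sq=sq[0],
        ci_index_sq=sq[1],
        p_index_sq=sq[2],
        quadratic_included=include_sq,
        gamma=np.asarray(res.params[off + D - 1 :], dtype=float),
        ilr_coefs=np.asarray(res.params[off : off + D - 1], dtype=float),
        alpha=float(res.params[0]),
        n=int(y.size),
        n_dropped=n_dropped,
    )


def effect_delta(fit_or_coefs, from_value: float, to_value: float) -> float:
    """Outcome change when the index moves from one value to another:
    b1*(to - from) + b2*(to^2 - from^2), with b2 = 0 for a linear fit.

    ``fit_or_coefs`` is a :class:`PartitioningFit` or a (b1, b2) pair
    (b2 may be None), so published table coefficients can be evaluated
    directly.
    """
    b1, b2 = _index_coefs(fit_or_coefs)
    delta = b1 * (to_value - from_value)
    if b2 is not None:
        delta += b2 * (to_value**2 - from_value**2)
    return float(delta)


def vertex(fit_or_coefs) -> float:
    """Index value -b1/(2 b2) where the fitted parabola peaks or bottoms."""
    b1, b2 = _index_coefs(fit_or_coefs)
    if b2 is None or b2 == 0:
        raise ValueError("vertex requires a quadratic term")
    return float(-b1 / (2.0 * b2))


def _index_coefs(fit_or_coefs):
    if isinstance(fit_or_coefs, PartitioningFit):
        return fit_or_coefs.coef_index, fit_or_coefs.coef_index_sq
    b1, b2 = fit_or_coefs
    return float(b1), (None if b2 is None else float(b2))
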