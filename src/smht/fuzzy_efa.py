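"""Outlier-robust ("fuzzy") exploratory factor analysis.

Classical EFA estimates the item correlation matrix with equal weight on every
respondent, so a handful of aberrant response vectors can distort the factor
structure.  The fuzzy variant iterates between

1. a membership-weighted mean/SD of the response matrix, and
2. a per-respondent membership ``U_k = 1 / (1 + (d_k / s)^2)`` where ``d_k``
   is the Euclidean distance of the standardized response vector from the
   weighted mean and ``s`` a median-distance scale,

until the weighted mean stabilizes.  The membership-weighted correlation
matrix is then eigendecomposed; factors are retained by the Kaiser rule
(eigenvalue strictly greater than 1) and loadings are ``sqrt(lambda_j) e_j``.
With memberships pinned to 1 the procedure reduces exactly to a classical
principal-component extraction from the sample correlation matrix.

Sampling-adequacy diagnostics (KMO, Bartlett's sphericity test) live here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import ResponseMatrix, ValidationError


class DegenerateWeightError(ValidationError):
    """Raised when fuzzy membership weights sum to zero."""


def _as_values(X) -> np.ndarray:
    if isinstance(X, ResponseMatrix):
        return X.values.astype(float)
    return np.asarray(X, dtype=float)


# --------------------------------------------------------------------------
# Weighted moments and memberships
# --------------------------------------------------------------------------

def fuzzy_mean(X, U) -> np.ndarray:
    """Membership-weighted column means ``sum(x_k U_k) / sum(U_k)``."""
    values = _as_values(X)
    U = np.asarray(U, dtype=float)
    total = U.sum()
    if total <= 0:
        raise DegenerateWeightError("membership weights sum to zero")
    return (U[:, None] * values).sum(axis=0) / total


def fuzzy_covariance(X, U, mean: np.ndarray) -> np.ndarray:
    """Membership-weighted covariance ``sum U_k (x_k-m)(x_k-m)^T / sum U_k``."""
    values = _as_values(X)
    U = np.asarray(U, dtype=float)
    total = U.sum()
    if total <= 0:
        raise DegenerateWeightError("membership weights sum to zero")
    centered = values - np.asarray(mean, dtype=float)
    cov = (U[:, None] * centered).T @ centered / total
    return 0.5 * (cov + cov.T)


def update_membership(
    X, current_mean: np.ndarray, scale: float = 1.0, item_sd=None
) -> np.ndarray:
    """Cauchy-type membership weights ``U_k = 1 / (1 + (d_k/s)^2)``.

    ``d_k`` is the Euclidean distance of the standardized row ``k`` from
    ``current_mean``; ``s`` is ``scale`` times the median distance.  A row at
    the weighted mean gets weight 1; a row at the median distance gets 0.5.
    If all rows coincide (``s = 0``) every weight is 1.
    """
    if scale <= 0:
        raise ValidationError("scale must be positive")
    values = _as_values(X)
    if item_sd is None:
        item_sd = values.std(axis=0)
    item_sd = np.where(np.asarray(item_sd, dtype=float) > 0, item_sd, 1.0)
    z = (values - np.asarray(current_mean, dtype=float)) / item_sd
    d = np.sqrt((z**2).sum(axis=1))
    s = scale * float(np.median(d))
    if s == 0.0:
        return np.ones(values.shape[0])
    return 1.0 / (1.0 + (d / s) ** 2)


# --------------------------------------------------------------------------
# The fitted model
# --------------------------------------------------------------------------

@dataclass
class FuzzyFactorModel:
    """Result of a fuzzy (or classical) factor extraction.

    ``loadings`` holds the retained columns ``sqrt(lambda_j) e_j`` of the
    membership-weighted correlation matrix; ``variance_contribution`` is
    ``lambda_j / p`` per retained factor with ``cumulative_contribution`` its
    running sum.
    """

    fuzzy_mean: np.ndarray
    fuzzy_sd: np.ndarray
    fuzzy_cov: np.ndarray
    correlation: np.ndarray
    eigenvalues: np.ndarray           # all p, descending
    eigenvectors: np.ndarray          # p x p, columns match eigenvalues
    loadings: np.ndarray              # p x retained_k
    retained_k: int
    variance_contribution: np.ndarray
    cumulative_contribution: np.ndarray
    memberships: np.ndarray
    iterations_run: int
    converged: bool
    item_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "item_names": list(self.item_names),
            "fuzzy_mean": self.fuzzy_mean.tolist(),
            "fuzzy_sd": self.fuzzy_sd.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "loadings": self.loadings.tolist(),
            "retained_k": int(self.retained_k),
            "variance_contribution": self.variance_contribution.tolist(),
            "cumulative_contribution": self.cumulative_contribution.tolist(),
            "memberships": self.memberships.tolist(),
            "iterations_run": int(self.iterations_run),
            "converged": bool(self.converged),
        }


def _fix_eigenvector_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude entry positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def fit_fuzzy_fa(
    X,
    max_iter: int = 50,
    tol: float = 1e-4,
    scale: float = 1.0,
    kaiser_threshold: float = 1.0,
    fuzzy: bool = True,
    item_names: list[str] | None = None,
) -> FuzzyFactorModel:
    """Fit the fuzzy factor model by alternating mean/membership updates.

    With ``fuzzy=False`` (or ``max_iter=0``) memberships stay pinned at 1 and
    the extraction is the classical one.  Convergence is declared when the
    largest change in the weighted mean falls below ``tol``; non-convergence
    yields a model with ``converged=False`` plus a warning, never a silent
    failure.  Retention uses the strict Kaiser rule ``lambda > threshold``
    (eigenvalues exactly at the threshold are excluded).
    """
    values = _as_values(X)
    n, p = values.shape
    if item_names is None:
        item_names = (
            list(X.item_names)
            if isinstance(X, ResponseMatrix)
            else [f"item_{j + 1}" for j in range(p)]
        )
    if np.all(values.std(axis=0) == 0):
        raise ValidationError("response matrix is constant; no factor structure")
    if n <= p:
        warnings.warn(
            f"n={n} <= p={p}: factor extraction is poorly determined",
            stacklevel=2,
        )

    U = np.ones(n)
    mean = fuzzy_mean(values, U)
    iterations = 0
    converged = True
    if fuzzy and max_iter > 0:
        converged = False
        for iterations in range(1, max_iter + 1):
            var = fuzzy_covariance(values, U, mean).diagonal()
            sd = np.sqrt(np.maximum(var, 0.0))
            U = update_membership(values, mean, scale=scale, item_sd=sd)
            new_mean = fuzzy_mean(values, U)
            delta = float(np.max(np.abs(new_mean - mean)))
            mean = new_mean
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"fuzzy iteration did not converge within {max_iter} steps",
                stacklevel=2,
            )

    cov = fuzzy_covariance(values, U, mean)
    var = cov.diagonal()
    if np.any(var <= 0):
        dead = [item_names[j] for j in np.flatnonzero(var <= 0)]
        raise ValidationError(f"items with zero weighted variance: {dead}")
    sd = np.sqrt(var)
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)

    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = _fix_eigenvector_signs(eigvec[:, order])
    retained = int(np.sum(eigval > kaiser_threshold))
    loadings = eigvec[:, :retained] * np.sqrt(np.maximum(eigval[:retained], 0.0))
    contribution = eigval[:retained] / p
    return FuzzyFactorModel(
        fuzzy_mean=mean,
        fuzzy_sd=sd,
        fuzzy_cov=cov,
        correlation=corr,
        eigenvalues=eigval,
        eigenvectors=eigvec,
        loadings=loadings,
        retained_k=retained,
        variance_contribution=contribution,
        cumulative_contribution=np.cumsum(contribution),
        memberships=U,
        iterations_run=iterations,
        converged=converged,
        item_names=item_names,
    )


def factor_scores(model: FuzzyFactorModel, X) -> np.ndarray:
    """Least-squares factor scores ``(L^T L)^-1 L^T z`` per respondent.

    Rows are standardized by the model's weighted mean and SD before
    projection.  A rank-deficient ``L^T L`` falls back to the pseudo-inverse
    with a warning.
    """
    if model.retained_k < 1:
        raise ValidationError("model retained no factors; scores undefined")
    values = _as_values(X)
    z = (values - model.fuzzy_mean) / model.fuzzy_sd
    L = model.loadings
    gram = L.T @ L
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        warnings.warn("L^T L is rank-deficient; using pseudo-inverse", stacklevel=2)
        solve = np.linalg.pinv(gram)
        return z @ L @ solve.T
    return np.linalg.solve(gram, L.T @ z.T).T


def varimax(loadings: np.ndarray, max_iter: int = 100, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation (optional; extraction reports unrotated)."""
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    R = np.eye(k)
    last = 0.0
    for _ in range(max_iter):
        rotated = L @ R
        b = rotated**3 - rotated * (rotated**2).mean(axis=0)
        u, s, vt = np.linalg.svd(L.T @ b)
        R = u @ vt
        crit = s.sum()
        if crit - last < tol * max(crit, 1.0):
            break
        last = crit
    return L @ R


# --------------------------------------------------------------------------
# Sampling adequacy
# --------------------------------------------------------------------------

def kmo_statistic(R: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin sampling-adequacy statistic in [0, 1].

    Compares raw off-diagonal correlations with anti-image partial
    correlations derived from the inverse correlation matrix.
    """
    R = np.asarray(R, dtype=float)
    try:
        S = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "correlation matrix is singular; prune collinear items before KMO"
        ) from exc
    d = np.sqrt(np.abs(S.diagonal()))
    partial = -S / np.outer(d, d)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = float((R[off] ** 2).sum())
    a2 = float((partial[off] ** 2).sum())
    return r2 / (r2 + a2)


def bartlett_sphericity(R: np.ndarray, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    Returns ``(chi2, df, p)`` with
    ``chi2 = -(n - 1 - (2p + 5)/6) ln|R|`` and ``df = p(p-1)/2``.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValidationError("Bartlett's test requires n > p")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValidationError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


# --------------------------------------------------------------------------
# Loading comparison helpers
# --------------------------------------------------------------------------

def align_loadings(est: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Permute and sign-flip the columns of ``est`` to best match ``ref``.

    Factor extractions are identified only up to column permutation and sign;
    alignment uses the Hungarian assignment on absolute column inner products.
    """
    from scipy.optimize import linear_sum_assignment

    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValidationError(f"shape mismatch {est.shape} vs {ref.shape}")
    gram = est.T @ ref
    rows, cols = linear_sum_assignment(-np.abs(gram))
    perm = np.empty(est.shape[1], dtype=int)
    perm[cols] = rows
    aligned = est[:, perm]
    signs = np.sign(np.sum(aligned * ref, axis=0))
    signs[signs == 0] = 1.0
    return aligned * signs


def aligned_loading_rmse(est: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square loading error after permutation/sign alignment."""
    aligned = align_loadings(est, ref)
    return float(np.sqrt(np.mean((aligned - np.asarray(ref, dtype=float)) ** 2)))
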