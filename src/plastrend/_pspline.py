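"""Penalized B-spline (P-spline) regression with REML/GCV smoothing selection.

This is the numerical engine behind both stages of the trend model: a
Gaussian additive model

    y = intercept + linear terms + sum_j f_j(x_j) + eps,   eps ~ N(0, sigma^2)

where each smooth f_j is represented in a cubic B-spline basis with a
second-order difference penalty (Eilers & Marx style). The smoothing
parameter of each penalized block is chosen by minimizing either the
profiled restricted likelihood (REML, the default) or generalized
cross-validation (GCV).

Notation for the fit: with full design X (n x q) and block penalties S_j,

    A(lambda) = X'X + sum_j lambda_j S_j
    beta_hat  = A^{-1} X'y

The REML criterion (up to constants independent of lambda) is

    (n - M) / 2 * log(RSS + sum_j lambda_j beta'S_j beta)
        + 1/2 log|A| - 1/2 sum_j (r_j log lambda_j + log|S_j|_+)

where r_j = rank(S_j), |S_j|_+ is the product of positive eigenvalues and
M = q - sum_j r_j is the total null-space dimension. Pointwise standard
errors use the Bayesian posterior covariance sigma^2 A^{-1}, the standard
choice for additive-model confidence bands.

Smooth bases are column-centered so the model intercept stays identifiable;
the same column offsets are applied to prediction design rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_solve
from scipy.optimize import minimize, minimize_scalar

from .exceptions import ModelError

__all__ = ["Smooth", "PenalizedFit", "fit_additive_model"]


def _bspline_design(x: np.ndarray, lo: float, hi: float, nbasis: int, degree: int) -> np.ndarray:
    """Design matrix of ``nbasis`` B-splines of ``degree`` on [lo, hi]."""
    if hi <= lo:
        raise ModelError("smooth covariate has zero range")
    inner = np.linspace(lo, hi, nbasis - degree + 1)
    knots = np.r_[[lo] * degree, inner, [hi] * degree]
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()


class Smooth:
    """One penalized smooth term f(x) in B-spline form.

    Parameters
    ----------
    x : array-like
        Covariate values at the observations.
    nbasis : int
        Number of basis functions before centering. Shrunk automatically
        (with a warning) when there are fewer distinct covariate values.
    degree : int
        Spline degree (3 = cubic).
    diff_order : int
        Order of the difference penalty; 2 penalizes curvature, leaving
        straight lines unpenalized.
    """

    def __init__(self, x, nbasis: int = 20, degree: int = 3, diff_order: int = 2,
                 lo: float | None = None, hi: float | None = None):
        x = np.asarray(x, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ModelError("smooth covariate must be a non-empty 1-D array")
        n_distinct = np.unique(x).size
        min_basis = degree + diff_order
        if max(min_basis, n_distinct) < nbasis:
            shrunk = max(min_basis, n_distinct)
            warnings.warn(
                f"smooth basis shrunk from {nbasis} to {shrunk}: "
                f"only {n_distinct} distinct covariate values",
                stacklevel=2,
            )
            nbasis = shrunk
        self.nbasis = int(nbasis)
        self.degree = int(degree)
        self.diff_order = int(diff_order)
        self.lo = float(np.min(x) if lo is None else lo)
        self.hi = float(np.max(x) if hi is None else hi)
        B = _bspline_design(x, self.lo, self.hi, self.nbasis, self.degree)
        self.col_means = B.mean(axis=0)
        self.B = B - self.col_means
        D = np.diff(np.eye(self.nbasis), n=self.diff_order, axis=0)
        self.S = D.T @ D
        self.rank = self.nbasis - self.diff_order

    def design(self, xnew) -> np.ndarray:
        """Centered design rows for new covariate values (clipped to range)."""
        B = _bspline_design(np.asarray(xnew, dtype=float), self.lo, self.hi,
                            self.nbasis, self.degree)
        return B - self.col_means


@dataclass
class PenalizedFit:
    """Result of :func:`fit_additive_model`."""

    coef: np.ndarray
    cov: np.ndarray              # Bayesian posterior covariance of coef
    sigma2: float
    edf: float                   # effective degrees of freedom (trace of hat)
    lambdas: np.ndarray          # chosen smoothing parameters, one per smooth
    method: str
    rss: float
    n_obs: int
    deviance_explained: float
    fitted: np.ndarray
    smooth_slices: list = field(default_factory=list)  # column slices per smooth

    def predict(self, Xnew: np.ndarray, se: bool = False):
        mu = Xnew @ self.coef
        if not se:
            return mu
        var = np.einsum("ij,jk,ik->i", Xnew, self.cov, Xnew)
        return mu, np.sqrt(np.maximum(var, 0.0))


def _assemble(smooths, linear, n):
    """Stack [1 | linear | smooth blocks]; return X, penalties, ranks, logdets."""
    cols = [np.ones((n, 1))]
    if linear is not None:
        linear = np.asarray(linear, dtype=float)
        if linear.ndim == 1:
            linear = linear[:, None]
        cols.append(linear)
    offset = sum(c.shape[1] for c in cols)
    slices, blocks = [], []
    for sm in smooths:
        slices.append(slice(offset, offset + sm.nbasis))
        cols.append(sm.B)
        offset += sm.nbasis
    X = np.hstack(cols)
    q = X.shape[1]
    for sm, sl in zip(smooths, slices):
        S = np.zeros((q, q))
        S[sl, sl] = sm.S
        blocks.append(S)
    return X, blocks, slices


def fit_additive_model(y, smooths, linear=None, method: str = "reml",
                       log_lambda_bounds=(-8.0, 22.0)) -> PenalizedFit:
    """Fit a Gaussian additive model with penalized smooths.

    Parameters
    ----------
    y : array-like
        Response vector.
    smooths : list[Smooth]
        Penalized smooth terms (may be empty).
    linear : array-like, optional
        Unpenalized design columns (e.g. factor dummies); an intercept is
        always added and must not be duplicated here.
    method : {"reml", "gcv"}
        Smoothing-parameter selection criterion.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not np.all(np.isfinite(y)):
        raise ModelError("response contains non-finite values")
    method = method.lower()
    if method not in ("reml", "gcv"):
        raise ModelError(f"unknown smoothing selection method: {method!r}")

    X, penalties, slices = _assemble(smooths, linear, n)
    q = X.shape[1]
    if n <= q - sum(sm.rank for sm in smooths):
        raise ModelError(f"too few observations ({n}) for {q} coefficients")

    XtX = X.T @ X
    Xty = X.T @ y
    ranks = [sm.rank for sm in smooths]
    # log of the product of positive eigenvalues of each penalty block
    logdet_plus = []
    for sm in smooths:
        ev = np.linalg.eigvalsh(sm.S)
        logdet_plus.append(float(np.sum(np.log(ev[ev > 1e-10 * ev.max()]))))
    null_dim = q - sum(ranks)

    def solve(lams):
        A = XtX.copy()
        for lam, S in zip(lams, penalties):
            A += lam * S
        # basis columns with little data support can leave A numerically
        # semidefinite at very small lambda; a vanishing ridge restores
        # definiteness without measurably changing the fit
        scale = float(np.mean(np.diag(A)))
        L = None
        for jitter in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
            try:
                Aj = A + jitter * scale * np.eye(q) if jitter else A
                L = np.linalg.cholesky(Aj)
                A = Aj
                break
            except np.linalg.LinAlgError:
                continue
        if L is None:
            raise ModelError("singular penalized system (design not identifiable)")
        beta = cho_solve((L, True), Xty)
        resid = y - X @ beta
        rss = float(resid @ resid)
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(L))))
        return (L, A), beta, rss, logdet_A

    def reml_score(rho):
        lams = np.exp(rho)
        _, beta, rss, logdet_A = solve(lams)
        pen = sum(lam * float(beta @ S @ beta) for lam, S in zip(lams, penalties))
        score = (0.5 * (n - null_dim) * np.log(max(rss + pen, 1e-300))
                 + 0.5 * logdet_A
                 - 0.5 * sum(r * rh + ld for r, rh, ld in zip(ranks, rho, logdet_plus)))
        return score

    def gcv_score(rho):
        lams = np.exp(rho)
        (L, _), _, rss, _ = solve(lams)
        edf = float(np.trace(cho_solve((L, True), XtX)))
        denom = max(n - edf, 1e-8)
        return n * max(rss, 1e-300) / denom ** 2

    score = reml_score if method == "reml" else gcv_score
    k = len(smooths)
    if k == 0:
        lams = np.empty(0)
    elif k == 1:
        grid = np.linspace(log_lambda_bounds[0], log_lambda_bounds[1], 31)
        vals = [score(np.array([g])) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = minimize_scalar(
            lambda r: score(np.array([r])),
            bounds=(max(g0 - 2.0, log_lambda_bounds[0]), min(g0 + 2.0, log_lambda_bounds[1])),
            method="bounded",
            options={"xatol": 1e-4},
        )
        lams = np.exp([res.x])
    else:
        grid = np.linspace(log_lambda_bounds[0], log_lambda_bounds[1], 9)
        best, best_val = None, np.inf
        mesh = np.meshgrid(*([grid] * k), indexing="ij")
        for idx in np.ndindex(*mesh[0].shape):
            rho = np.array([m[idx] for m in mesh])
            v = score(rho)
            if v < best_val:
                best, best_val = rho, v
        res = minimize(score, best, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000})
        lams = np.exp(np.clip(res.x, *log_lambda_bounds))

    (L, _), beta, rss, _ = solve(lams)
    A_inv = cho_solve((L, True), np.eye(q))
    edf = float(np.trace(A_inv @ XtX))
    sigma2 = max(rss / max(n - edf, 1.0), 1e-24)
    fitted = X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    dev_expl = 1.0 - rss / tss if tss > 0 else 1.0
    return PenalizedFit(
        coef=beta,
        cov=sigma2 * A_inv,
        sigma2=sigma2,
        edf=edf,
        lambdas=lams,
        method=method,
        rss=rss,
        n_obs=n,
        deviance_explained=dev_expl,
        fitted=fitted,
        smooth_slices=slices,
    )
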