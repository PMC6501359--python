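"""Phylogenetic generalized least squares with profile-ML Pagel's lambda.

The model is y = X beta + e with e ~ N(0, sigma^2 * C(lambda)), where C is
the shared-branch-length covariance of the tree and lambda scales its
off-diagonal entries. For a fixed lambda, beta and sigma^2 have closed-form
GLS/ML solutions, so lambda is found by a bounded one-dimensional search of
the profile log-likelihood on [0, 1] (21-point grid to bracket, then
Brent refinement — the profile can be very flat).

Reported standard errors use the unbiased residual variance RSS/(n - k)
(so a lambda = 0 fit on a unit star tree reproduces textbook OLS exactly);
the log-likelihood used for AICc is the ML one, with sigma^2 = RSS/n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .trees import Phylogeny, covariance

__all__ = ["PGLSFit", "pgls_fit", "pgls_residuals", "design_matrix", "gls_solve"]

_GRID = np.linspace(0.0, 1.0, 21)


class RankDeficientError(ValueError):
    """Design matrix is not full column rank."""


def design_matrix(traits: pd.DataFrame, predictors: list,
                  interactions: list | None = None):
    """Build (X, column names) with an intercept, mains, then interactions.

    Interactions are ``"a:b"`` strings (or (a, b) pairs); their columns are
    elementwise products, and callers are expected to respect marginality.
    """
    cols = [np.ones(len(traits))]
    names = ["intercept"]
    for p in predictors:
        if p not in traits.columns:
            raise KeyError(f"unknown predictor {p!r}")
        cols.append(np.asarray(traits[p], dtype=float))
        names.append(p)
    for term in interactions or []:
        a, b = term.split(":") if isinstance(term, str) else term
        for v in (a, b):
            if v not in traits.columns:
                raise KeyError(f"unknown predictor {v!r} in interaction")
        cols.append(np.asarray(traits[a], dtype=float) * np.asarray(traits[b], dtype=float))
        names.append(f"{a}:{b}")
    X = np.column_stack(cols)
    return X, names


def _check_rank(X: np.ndarray, names: list) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j in range(X.shape[1]):
            rest = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(X):
                bad.append(names[j])
        raise RankDeficientError(f"design matrix rank-deficient; collinear columns: {bad}")


def gls_solve(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Closed-form GLS for fixed covariance V (up to sigma^2).

    Returns ``(beta, rss, logdetV, cov_unit)`` where ``rss`` is the
    V-weighted residual sum of squares and ``cov_unit = (X' V^-1 X)^-1``.
    """
    cf = cho_factor(V, lower=True)
    Vi_X = cho_solve(cf, X)
    Vi_y = cho_solve(cf, y)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    r = y - X @ beta
    rss = float(r @ cho_solve(cf, r))
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    cov_unit = np.linalg.inv(XtViX)
    return beta, rss, logdetV, cov_unit


def _ml_loglik(y, X, V):
    n = len(y)
    beta, rss, logdetV, cov_unit = gls_solve(y, X, V)
    # an exact fit has RSS = 0; clamp so the log-likelihood stays finite
    sigma2 = max(rss, 1e-300) / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdetV)
    return ll, beta, rss, cov_unit, sigma2


def profile_lambda(y: np.ndarray, X: np.ndarray, C: np.ndarray, xatol: float = 1e-6):
    """Maximize the ML log-likelihood over lambda in [0, 1].

    C is the raw (lambda = 1) covariance. Returns ``(lambda_hat, ll_hat)``.
    If the tree is a star (zero off-diagonals) the likelihood is constant in
    lambda and (0.0, ll) is returned.
    """
    diag = np.diag(np.diag(C))

    def V_of(lam):
        return lam * C + (1.0 - lam) * diag

    offdiag = C - diag
    if np.max(np.abs(offdiag)) == 0.0:
        return 0.0, _ml_loglik(y, X, C)[0]

    grid_ll = np.array([_ml_loglik(y, X, V_of(l))[0] for l in _GRID])
    i = int(np.argmax(grid_ll))
    lo = _GRID[max(i - 1, 0)]
    hi = _GRID[min(i + 1, len(_GRID) - 1)]
    res = minimize_scalar(lambda l: -_ml_loglik(y, X, V_of(l))[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": xatol})
    lam, ll = float(res.x), float(-res.fun)
    # never return worse than the best grid point
    if grid_ll[i] > ll:
        lam, ll = float(_GRID[i]), float(grid_ll[i])
    return lam, ll


@dataclass
class PGLSFit:
    response: str
    terms: list
    beta: np.ndarray
    se: np.ndarray
    sigma2_ml: float
    lambda_hat: float
    lambda_fixed: bool
    loglik: float
    n: int
    k_coefficients: int
    r_squared: float
    residuals: pd.Series = field(repr=False)
    fitted: pd.Series = field(repr=False)

    def summary_frame(self) -> pd.DataFrame:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = self.beta / self.se
        return pd.DataFrame({"term": self.terms, "estimate": self.beta,
                             "se": self.se, "t": t})


def pgls_fit(tree: Phylogeny, traits: pd.DataFrame, response: str,
             predictors: list, interactions: list | None = None,
             lambda_mode="ml") -> PGLSFit:
    """Fit a PGLS regression on an aligned (tree, trait-table) pair.

    ``traits`` rows must match ``tree.tip_labels`` (same order).
    ``lambda_mode`` is ``"ml"`` or a fixed value in [0, 1].
    """
    if list(traits["species"]) != tree.tip_labels:
        raise ValueError("trait rows must be aligned to tree tip order; use trees.align")
    y = np.asarray(traits[response], dtype=float)
    X, names = design_matrix(traits, predictors, interactions)
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"{n} species cannot support {k} coefficients (need >= k+2)")
    _check_rank(X, names)

    C, _ = covariance(tree, 1.0)
    diag = np.diag(np.diag(C))
    if lambda_mode == "ml":
        lam, _ = profile_lambda(y, X, C)
        fixed = False
    else:
        lam = float(lambda_mode)
        if not (0.0 <= lam <= 1.0):
            raise ValueError("fixed lambda must lie in [0, 1]")
        fixed = True
    V = lam * C + (1.0 - lam) * diag
    ll, beta, rss, cov_unit, sigma2_ml = _ml_loglik(y, X, V)
    sigma2_unbiased = rss / (n - k)
    se = np.sqrt(sigma2_unbiased * np.diag(cov_unit))

    # R^2 against the GLS intercept-only fit under the same covariance
    _, rss0, _, _ = gls_solve(y, np.ones((n, 1)), V)
    r2 = 1.0 - rss / rss0 if rss0 > 0 else 1.0

    fitted = X @ beta
    resid = y - fitted
    idx = pd.Index(traits["species"], name="species")
    return PGLSFit(response=response, terms=names, beta=beta, se=se,
                   sigma2_ml=sigma2_ml, lambda_hat=lam, lambda_fixed=fixed,
                   loglik=ll, n=n, k_coefficients=k, r_squared=float(r2),
                   residuals=pd.Series(resid, index=idx, name="residual"),
                   fitted=pd.Series(fitted, index=idx, name="fitted"))


def pgls_residuals(fit: PGLSFit) -> pd.DataFrame:
    """Per-species residuals (observed - fitted) on the response scale."""
    return pd.DataFrame({"species": fit.residuals.index,
                         "fitted": fit.fitted.to_numpy(),
                         "residual": fit.residuals.to_numpy()})
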