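"""Generalized estimating equations, Gaussian family, identity link,
exchangeable working correlation.

Eyes are nested within subjects, so eye-level regressions must account
for inter-eye correlation.  The marginal model is

    E[y_ij] = x_ij' beta,      Cov working model: phi * R(rho),

with R exchangeable (all within-cluster pairs share correlation rho).
Estimation alternates (i) a weighted estimating-equation update of beta
under the current working covariance with (ii) moment re-estimation of
the dispersion phi and correlation rho from Pearson residuals, until
beta changes by less than ``tol``.  Standard errors are the robust
(sandwich) estimator, so they remain valid when the working correlation
is misspecified.

The exchangeable structure gives a closed-form cluster inverse

    V_i^{-1} = (I - c_i J) / (phi (1 - rho)),
    c_i = rho / (1 + (n_i - 1) rho),

which lets every cluster be handled with vectorised cluster sums — no
per-cluster Python loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearDesignError, VitrehazeError


@dataclass(eq=False)
class GeeFit:
    """Fitted GEE: coefficients with robust inference and the working
    correlation/dispersion estimates."""

    params: pd.Series
    robust_se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    rho_hat: float
    phi_hat: float
    n_clusters: int
    n_obs: int
    converged: bool
    n_iter: int
    cov_robust: np.ndarray = None

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.robust_se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )


def _check_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _q, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < 1e-10 * diag[0]]
        bad = bad or [names[p] for p in piv[rank:]]
        raise CollinearDesignError(bad)


def fit_gee(
    data: pd.DataFrame,
    outcome: str,
    covariates,
    cluster: str = "subject_id",
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GeeFit:
    """Fit the exchangeable-GEE linear model.

    Rows with missing values in the model columns are dropped (listwise
    deletion); the remaining counts are reported on the fit.  With all
    clusters of size one the estimate reduces to ordinary least squares
    exactly.
    """
    covariates = list(covariates)
    cols = [outcome] + covariates + [cluster]
    for c in cols:
        if c not in data.columns:
            raise VitrehazeError(f"column {c!r} not found")
    d = data[cols].dropna()
    if d.empty:
        raise VitrehazeError("no complete rows for the model")
    d = d.sort_values(cluster, kind="stable")

    y = d[outcome].to_numpy(dtype=np.float64)
    X = d[covariates].to_numpy(dtype=np.float64)
    names = list(covariates)
    if add_intercept:
        X = np.column_stack([np.ones(len(d)), X])
        names = ["intercept"] + names
    n, p = X.shape
    codes, _uniq = pd.factorize(d[cluster].to_numpy())
    n_clusters = codes.max() + 1
    if n_clusters < 2:
        raise VitrehazeError("need at least 2 clusters")
    _check_rank(X, names)

    starts = np.flatnonzero(np.r_[1, np.diff(codes)])
    sizes = np.diff(np.r_[starts, n]).astype(np.float64)
    pairs = float((sizes * (sizes - 1) / 2).sum())

    def cluster_sum(arr):
        return np.add.reduceat(arr, starts, axis=0)

    # independence (OLS) start
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rho = 0.0
    converged = False
    it = 0
    XtX = X.T @ X
    S = cluster_sum(X)  # (n_clusters, p)
    for it in range(1, max_iter + 1):
        r = y - X @ beta
        phi = float(r @ r) / max(n - p, 1)
        if pairs > p:
            Sr = cluster_sum(r)
            cross = float(Sr @ Sr - r @ r) / 2.0
            rho = cross / ((pairs - p) * phi) if phi > 0 else 0.0
        else:
            rho = 0.0
        rho = float(np.clip(rho, -0.99, 0.99))

        c = rho / (1.0 + (sizes - 1.0) * rho)  # per-cluster J-weight
        Sy = cluster_sum(y)
        A = XtX - (S * c[:, None]).T @ S
        b = X.T @ y - S.T @ (c * Sy)
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise CollinearDesignError(names) from exc
        delta = float(np.max(np.abs(beta_new - beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break

    # robust sandwich covariance (the 1/(phi(1-rho)) factors cancel)
    r = y - X @ beta
    phi = float(r @ r) / max(n - p, 1)
    c = rho / (1.0 + (sizes - 1.0) * rho)
    Sr = cluster_sum(r)
    A = XtX - (S * c[:, None]).T @ S
    G = cluster_sum(X * r[:, None]) - S * (c * Sr)[:, None]  # per-cluster X_i'V_i^-1 r_i (scaled)
    M = G.T @ G
    Ainv = np.linalg.inv(A)
    cov = Ainv @ M @ Ainv

    se = np.sqrt(np.diag(cov))
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2 * stats.norm.sf(np.abs(z))
    idx = pd.Index(names)
    return GeeFit(
        params=pd.Series(beta, index=idx),
        robust_se=pd.Series(se, index=idx),
        ci_low=pd.Series(beta - 1.96 * se, index=idx),
        ci_high=pd.Series(beta + 1.96 * se, index=idx),
        p_values=pd.Series(pvals, index=idx),
        rho_hat=float(rho),
        phi_hat=phi,
        n_clusters=int(n_clusters),
        n_obs=int(n),
        converged=converged,
        n_iter=it,
        cov_robust=cov,
    )


def group_contrast(fit: GeeFit, term: str) -> float:
    """Percent difference on the original haze scale implied by a
    log-scale coefficient: ``(exp(beta) - 1) * 100``."""
    if term not in fit.params.index:
        raise VitrehazeError(f"term {term!r} not in the fitted model")
    return float((np.exp(fit.params[term]) - 1.0) * 100.0)
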