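"""Height–education mean association with twin-pair cluster-robust errors.

Twins are sampled as pairs, not as independent individuals, so ordinary OLS
standard errors for a regression at the individual level are too small.  The
cluster-robust (sandwich) covariance

    (XᵀX)⁻¹ [ Σ_g X_gᵀ e_g e_gᵀ X_g ] (XᵀX)⁻¹ · c

with clusters g = twin pairs corrects for the arbitrary within-pair error
correlation.  The default small-sample factor is the convention of the major
survey-regression implementations, c = G/(G−1) · (N−1)/(N−k); alternatives
are selectable because different software applies different corrections.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin


def fit_ols(y: np.ndarray, X: np.ndarray):
    """Least squares of ``y`` on ``X``.

    Returns ``(beta, residuals, XtX_inv)``.  Collinear columns are pruned
    (coefficient fixed at 0) with a warning; ``XtX_inv`` is the
    pseudo-inverse on the retained columns, zero elsewhere.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    q, r, piv = _qr_pivot(X)
    rank = int(np.sum(np.abs(np.diag(r)) > np.abs(r[0, 0]) * max(n, k) * np.finfo(float).eps))
    keep = np.sort(piv[:rank])
    if rank < k:
        warnings.warn(f"design matrix rank {rank} < {k}; collinear columns pruned", stacklevel=2)
    Xk = X[:, keep]
    beta_k, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    beta = np.zeros(k)
    beta[keep] = beta_k
    resid = y - X @ beta
    XtX_inv = np.zeros((k, k))
    XtX_inv[np.ix_(keep, keep)] = np.linalg.inv(Xk.T @ Xk)
    return beta, resid, XtX_inv


def _qr_pivot(X):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def cluster_robust_cov(
    X: np.ndarray,
    resid: np.ndarray,
    cluster_ids: np.ndarray,
    XtX_inv: np.ndarray | None = None,
    small_sample: str = "stata",
) -> np.ndarray:
    """Sandwich covariance of OLS coefficients under within-cluster correlation.

    Parameters
    ----------
    X : (n, k) design matrix.
    resid : (n,) OLS residuals.
    cluster_ids : (n,) cluster labels (e.g. twin-pair ids).
    XtX_inv : optional precomputed (XᵀX)⁻¹.
    small_sample : {"stata", "cr0", "g-only"}
        ``stata``: c = G/(G−1)·(N−1)/(N−k); ``g-only``: G/(G−1); ``cr0``: 1.

    Raises
    ------
    ValueError if fewer than two clusters are present.
    """
    X = np.asarray(X, dtype=float)
    resid = np.asarray(resid, dtype=float)
    n, k = X.shape
    if XtX_inv is None:
        XtX_inv = np.linalg.pinv(X.T @ X)
    codes, _ = pd.factorize(np.asarray(cluster_ids))
    G = codes.max() + 1
    if G < 2:
        raise ValueError("cluster-robust covariance requires at least 2 clusters")
    # per-cluster score sums Σ_{i∈g} x_i e_i, accumulated without a python loop
    Xe = X * resid[:, None]
    S = np.zeros((G, k))
    np.add.at(S, codes, Xe)
    meat = S.T @ S
    if small_sample == "stata":
        c = (G / (G - 1.0)) * ((n - 1.0) / (n - k))
    elif small_sample == "g-only":
        c = G / (G - 1.0)
    elif small_sample == "cr0":
        c = 1.0
    else:
        raise ValueError(f"unknown small_sample convention {small_sample!r}")
    cov = c * XtX_inv @ meat @ XtX_inv
    return (cov + cov.T) / 2.0


class ClusterRobustOLS(BaseEstimator, RegressorMixin):
    """OLS with cluster-robust standard errors.

    Parameters
    ----------
    small_sample : {"stata", "cr0", "g-only"}, default "stata"
        Small-sample correction of the sandwich covariance.
    use_t : bool, default False
        If True, confidence intervals use the t distribution with G−1
        degrees of freedom instead of the normal quantile.

    Attributes
    ----------
    coef_ : (k,) estimated coefficients.
    cov_ : (k, k) cluster-robust covariance.
    bse_ : (k,) cluster-robust standard errors.
    n_obs_, n_clusters_ : int
    """

    def __init__(self, small_sample: str = "stata", use_t: bool = False):
        self.small_sample = small_sample
        self.use_t = use_t

    def fit(self, X, y, clusters=None) -> "ClusterRobustOLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if clusters is None:
            raise ValueError("clusters (e.g. pair ids) must be supplied")
        beta, resid, XtX_inv = fit_ols(y, X)
        self.coef_ = beta
        self.resid_ = resid
        self.XtX_inv_ = XtX_inv
        self.cov_ = cluster_robust_cov(X, resid, clusters, XtX_inv, self.small_sample)
        self.bse_ = np.sqrt(np.diag(self.cov_))
        self.n_obs_ = len(y)
        self.n_clusters_ = int(pd.factorize(np.asarray(clusters))[0].max() + 1)
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        """(k, 2) confidence bounds at ``level``."""
        alpha = 1.0 - level
        if self.use_t:
            q = stats.t.ppf(1 - alpha / 2, df=self.n_clusters_ - 1)
        else:
            q = stats.norm.ppf(1 - alpha / 2)
        return np.column_stack([self.coef_ - q * self.bse_, self.coef_ + q * self.bse_])


def _pairs_to_long(pairs: pd.DataFrame) -> pd.DataFrame:
    """Unstack paired observations back to one row per individual."""
    rows = []
    for m in (1, 2):
        sub = pairs[["pair_id", "age_group", "zygosity", "region",
                     f"sex{m}", f"height_resid{m}", "edu_years_combined", "edu_category"]].copy()
        sub.columns = ["pair_id", "age_group", "zygosity", "region",
                       "sex", "height_resid", "edu_years_combined", "edu_category"]
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def association_by_group(
    pairs: pd.DataFrame,
    by_region: bool = False,
    min_n: int = 30,
    small_sample: str = "stata",
    use_t: bool = False,
) -> pd.DataFrame:
    """Estimate the height–education slope per age × sex (× region) group.

    Within each group, the height residual is regressed at the individual
    level on the combined (standardized) parental-education score, adjusted
    for zygosity (MZ / SSDZ / OSDZ indicators), with twin-pair
    cluster-robust standard errors.  Groups with fewer than ``min_n``
    individuals are skipped.

    Returns a DataFrame with one row per group: ``beta`` (cm per unit of the
    education score), ``se_cluster``, ``ci_low``/``ci_high`` (95%),
    ``n_individuals`` and ``n_pairs``.
    """
    long = _pairs_to_long(pairs).dropna(subset=["height_resid", "edu_years_combined"])
    keys = ["age_group", "sex"] + (["region"] if by_region else [])
    out = []
    for key, sub in long.groupby(keys):
        if len(sub) < min_n:
            continue
        zyg = pd.get_dummies(sub["zygosity"], drop_first=True).to_numpy(float)
        X = np.column_stack(
            [np.ones(len(sub)), sub["edu_years_combined"].to_numpy(float), zyg]
        )
        est = ClusterRobustOLS(small_sample=small_sample, use_t=use_t).fit(
            X, sub["height_resid"].to_numpy(float), clusters=sub["pair_id"].to_numpy()
        )
        lo, hi = est.conf_int()[1]
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(
            beta=est.coef_[1],
            se_cluster=est.bse_[1],
            ci_low=lo,
            ci_high=hi,
            n_individuals=len(sub),
            n_pairs=sub["pair_id"].nunique(),
        )
        out.append(row)
    return pd.DataFrame(out)
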