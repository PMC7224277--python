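"""Random-effects meta-regression of stratum-level variance components.

Each (age group × sex × region × education category) cell contributes one
effect estimate y_i (a raw variance component in cm², or a standardized
proportion) with known sampling variance v_i.  The random-effects model

    y_i = x_iᵀβ + u_i + ε_i,   u_i ~ (0, τ²),   ε_i ~ (0, v_i)

is fitted by weighted least squares with weights 1/(v_i + τ²).  τ² is
estimated by the method of moments (the DerSimonian–Laird estimator
generalized to a moderator design: τ̂² = max(0, (Q_res − (k−p)) / tr(P)) with
P the weighted residual-projection matrix), deterministic and reproducible;
REML is available by flag.  Inference uses normal-approximation Wald
intervals, with the Knapp–Hartung adjustment as an option.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    Xw = X * w[:, None]
    XtWX = X.T @ Xw
    cov = np.linalg.pinv(XtWX)
    beta = cov @ (Xw.T @ y)
    return beta, cov


def estimate_tau2(
    y: np.ndarray, v: np.ndarray, X: np.ndarray | None = None, method: str = "mom"
) -> float:
    """Between-stratum variance τ² of a (meta-)regression of ``y`` on ``X``.

    ``method="mom"``: generalized DerSimonian–Laird moments estimator,
    τ̂² = max(0, (Q_res − (k − p)) / tr(P)), where Q_res is the fixed-effect
    weighted residual sum of squares with weights 1/v and
    P = W − W X (XᵀWX)⁻¹ XᵀW.  ``method="reml"``: restricted maximum
    likelihood by scalar optimization.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    if (v <= 0).any():
        raise ValueError("all sampling variances must be positive")
    k = len(y)
    if X is None:
        X = np.ones((k, 1))
    X = np.asarray(X, dtype=float)
    p = np.linalg.matrix_rank(X)
    if k <= p:
        raise ValueError(f"need more strata than moderators: k={k}, p={p}")

    if method == "mom":
        w = 1.0 / v
        beta, cov = _wls(X, y, w)
        resid = y - X @ beta
        Q = float(w @ resid**2)
        # tr(P) = Σw − tr((XᵀWX)⁻¹ XᵀW²X)
        trP = float(w.sum() - np.trace(cov @ ((X * (w**2)[:, None]).T @ X)))
        return max(0.0, (Q - (k - p)) / trP)
    if method == "reml":
        def nll(log_tau2):
            t2 = np.exp(log_tau2)
            wi = 1.0 / (v + t2)
            beta, cov_b = _wls(X, y, wi)
            resid = y - X @ beta
            sign, logdet = np.linalg.slogdet((X * wi[:, None]).T @ X)
            return 0.5 * (-np.sum(np.log(wi)) + float(wi @ resid**2) + logdet)

        res = optimize.minimize_scalar(nll, bounds=(-30.0, 15.0), method="bounded")
        t2 = float(np.exp(res.x))
        return 0.0 if t2 < 1e-10 else t2
    raise ValueError(f"unknown tau2 method {method!r}")


class RandomEffectsMetaRegression(BaseEstimator):
    """Random-effects meta-regression with known sampling variances.

    Parameters
    ----------
    tau2_method : {"mom", "reml"}, default "mom"
    knapp_hartung : bool, default False
        Use the Knapp–Hartung variance scaling and t-quantiles.

    Attributes
    ----------
    coef_ : (p,) moderator coefficients (component units).
    se_ : (p,) standard errors from the weighted information matrix.
    tau2_ : between-stratum variance.
    cov_ : (p, p) coefficient covariance.
    k_ : number of strata.
    """

    def __init__(self, tau2_method: str = "mom", knapp_hartung: bool = False):
        self.tau2_method = tau2_method
        self.knapp_hartung = knapp_hartung

    def fit(self, X, y, v, clusters=None) -> "RandomEffectsMetaRegression":
        """Fit the weighted regression.

        ``clusters`` (optional) marks groups of effect rows that come from
        the same underlying fit (e.g. the male and female components of one
        joint five-group model) and are therefore correlated; when given,
        the coefficient covariance is the cluster-robust sandwich over those
        groups instead of the model-based weighted information matrix.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        v = np.asarray(v, dtype=float)
        self.tau2_ = estimate_tau2(y, v, X, method=self.tau2_method)
        w = 1.0 / (v + self.tau2_)
        beta, cov = _wls(X, y, w)
        self.k_ = len(y)
        self.p_ = int(np.linalg.matrix_rank(X))
        resid = y - X @ beta
        if clusters is not None:
            codes, _ = pd.factorize(np.asarray(clusters))
            G = codes.max() + 1
            scores = X * (w * resid)[:, None]
            S = np.zeros((G, X.shape[1]))
            np.add.at(S, codes, scores)
            cov = cov @ (S.T @ S) @ cov * (G / max(G - 1.0, 1.0))
            cov = (cov + cov.T) / 2.0
            self.n_clusters_ = int(G)
        elif self.knapp_hartung:
            s2 = float(w @ resid**2) / (self.k_ - self.p_)
            cov = cov * max(s2, 1.0)  # truncated Knapp–Hartung
        self.coef_ = beta
        self.cov_ = cov
        self.se_ = np.sqrt(np.diag(cov))
        self.resid_ = resid
        return self

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        if self.knapp_hartung:
            q = stats.t.ppf(0.5 + level / 2.0, df=self.k_ - self.p_)
        else:
            q = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.coef_ - q * self.se_, self.coef_ + q * self.se_])


RAW_COMPONENT_COLS = {"a2": ("A", "var_A"), "c2": ("C", "var_C"), "e2": ("E", "var_E")}
STD_COMPONENT_COLS = {"a2": ("a2", "var_a2"), "c2": ("c2", "var_c2"), "e2": ("e2", "var_e2")}


def _build_design(df: pd.DataFrame, include_sex: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for cat, ref in (("edu_category", "low"),):
        levels = [l for l in ("mid", "high") if (df[cat] == l).any()]
        for l in levels:
            cols.append((df[cat] == l).to_numpy(float))
            names.append(f"edu_{l}")
    for key in ("age_group", "region"):
        if key in df.columns and df[key].nunique() > 1:
            levels = sorted(df[key].unique())[1:]
            for l in levels:
                cols.append((df[key] == l).to_numpy(float))
                names.append(f"{key}_{l}")
    if include_sex and df["sex"].nunique() > 1:
        cols.append((df["sex"] == "F").to_numpy(float))
        names.append("sex_F")
    return np.column_stack(cols), names


def fit_meta_regression(
    strata: pd.DataFrame,
    component: str = "c2",
    scale: str = "raw",
    sex: str = "both",
    tau2_method: str = "mom",
    knapp_hartung: bool = False,
) -> pd.DataFrame:
    """Meta-regress one variance component on the education category.

    ``strata`` is the stratum table of :func:`twinmod.ace.fit_by_stratum`.
    The effect is the raw component (cm²; ``scale="raw"``) or the
    standardized proportion (``scale="standardized"``) named by
    ``component`` in {"a2", "c2", "e2"}.  Moderators: education category
    indicators (reference = low), plus age-group and region indicators when
    present; ``sex="both"`` pools male and female rows with a sex indicator.

    Returns a coefficient table (one row per moderator) with ``beta``,
    ``se``, ``ci_low``, ``ci_high``, ``tau2`` and ``k``.
    """
    if component not in RAW_COMPONENT_COLS:
        raise ValueError(f"component must be one of {list(RAW_COMPONENT_COLS)}")
    if scale not in ("raw", "standardized"):
        raise ValueError("scale must be 'raw' or 'standardized'")
    ycol, vcol = (RAW_COMPONENT_COLS if scale == "raw" else STD_COMPONENT_COLS)[component]
    df = strata.copy()
    if sex != "both":
        df = df[df["sex"] == sex.upper()]
    df = df[np.isfinite(df[ycol]) & (df[vcol] > 0)]
    if df.empty:
        raise ValueError("no usable strata for the requested component/sex")
    X, names = _build_design(df, include_sex=(sex == "both"))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("collinear moderators pruned from the meta-regression design",
                      stacklevel=2)
        keep = _independent_columns(X)
        X, names = X[:, keep], [names[i] for i in keep]
    est = RandomEffectsMetaRegression(tau2_method=tau2_method,
                                      knapp_hartung=knapp_hartung).fit(
        X, df[ycol].to_numpy(float), df[vcol].to_numpy(float)
    )
    ci = est.conf_int()
    return pd.DataFrame(
        {
            "moderator": names,
            "beta": est.coef_,
            "se": est.se_,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "tau2": est.tau2_,
            "k": est.k_,
            "component": component,
            "scale": scale,
            "sex": sex,
        }
    )


def _independent_columns(X: np.ndarray) -> list[int]:
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    rank = int(np.sum(np.abs(np.diag(r)) > np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps))
    return sorted(piv[:rank])


def warn_if_repeated_individuals(pairs: pd.DataFrame) -> bool:
    """Warn that meta-regression CIs are too narrow when the same pairs
    contribute to multiple age-group strata (SEs are not corrected for the
    resulting dependence)."""
    repeated = pairs.groupby("pair_id")["age_group"].nunique().gt(1).any()
    if repeated:
        warnings.warn(
            "the same twin pairs contribute to multiple age-group strata; "
            "meta-regression standard errors are not corrected for this "
            "dependence and the 95% CIs are likely too narrow",
            stacklevel=2,
        )
    return bool(repeated)


def summarize_table(results: list[pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Arrange meta-regression outputs as a components × sex-blocks table.

    Rows are (sex block, component); columns the mid-vs-low and high-vs-low
    contrasts, each formatted ``beta (ci_low, ci_high)``.  Missing
    combinations are left blank.
    """
    if isinstance(results, pd.DataFrame):
        results = [results]
    allres = pd.concat(results, ignore_index=True)
    sex_order = {"m": "Males", "f": "Females", "both": "Both sexes"}
    rows = []
    for sex_key, sex_label in sex_order.items():
        for comp in ("a2", "c2", "e2"):
            sub = allres[(allres["sex"] == sex_key) & (allres["component"] == comp)]
            row = {"block": sex_label, "component": comp, "mid_vs_low": "", "high_vs_low": ""}
            for mod, col in (("edu_mid", "mid_vs_low"), ("edu_high", "high_vs_low")):
                m = sub[sub["moderator"] == mod]
                if len(m):
                    b = m.iloc[0]
                    row[col] = f"{b.beta:.2f} ({b.ci_low:.2f}, {b.ci_high:.2f})"
            if len(sub):
                rows.append(row)
    return pd.DataFrame(rows)


def render_markdown(table: pd.DataFrame) -> str:
    """Render the :func:`summarize_table` output as a Markdown table."""
    lines = ["| Block | Component | Mid vs low | High vs low |",
             "|---|---|---|---|"]
    for _, r in table.iterrows():
        lines.append(f"| {r.block} | {r.component} | {r.mid_vs_low} | {r.high_vs_low} |")
    return "\n".join(lines)


def parse_markdown(text: str) -> pd.DataFrame:
    """Parse a :func:`render_markdown` table back into numbers (round-trip)."""
    import re

    rows = []
    for line in text.strip().splitlines()[2:]:
        cells = [c.strip() for c in line.strip("|").split("|")]
        row = {"block": cells[0], "component": cells[1]}
        for name, cell in zip(("mid_vs_low", "high_vs_low"), cells[2:]):
            m = re.match(r"(-?[\d.]+) \((-?[\d.]+), (-?[\d.]+)\)", cell)
            if m:
                row[name] = float(m.group(1))
                row[f"{name}_ci"] = (float(m.group(2)), float(m.group(3)))
        rows.append(row)
    return pd.DataFrame(rows)
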