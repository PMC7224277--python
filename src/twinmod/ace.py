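"""Five-group sex-limitation ACE variance decomposition by maximum likelihood.

The classical twin design identifies additive-genetic (A), shared-
environmental (C) and unique-environmental (E) variance from the different
cross-twin covariances of monozygotic (MZ) and dizygotic (DZ) pairs: the
additive-genetic correlation is 1.0 for MZ and 0.5 for same-sex DZ pairs,
the shared environment is by definition correlated 1.0 in both, and the
unique environment is uncorrelated.  The sex-limitation extension fits the
five zygosity-sex groups (MZ male, MZ female, same-sex DZ male and female,
opposite-sex DZ) jointly, with sex-specific components and an opposite-sex
additive-genetic correlation ``r_os`` allowed below the standard 0.5.
Because DZ twins run slightly taller than MZ twins, separate MZ and DZ means
are estimated per sex.

An ADE variant replaces the shared environment with dominance genetic
variance D (cross-twin coefficient 1.0 for MZ, 0.25 for DZ); C and D are not
jointly identifiable in the classical design.

Components are parameterized directly as variances with nonnegativity
bounds, so a boundary solution (e.g. Ĉ = 0) is representable and the
reported estimates are the raw variances that feed the meta-regression.
The likelihood is evaluated from per-group sufficient statistics (count,
mean vector and scatter matrix), which makes each evaluation O(1) in the
number of pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

GROUPS = ("MZM", "MZF", "DZM", "DZF", "OSDZ")
PARAM_NAMES = (
    "A_m", "C_m", "E_m", "A_f", "C_f", "E_f", "r_os",
    "mu_MZ_m", "mu_DZ_m", "mu_MZ_f", "mu_DZ_f",
)
_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SexLimitationParams:
    """Parameter vector of the five-group sex-limitation model.

    ``A_m, C_m, E_m, A_f, C_f, E_f`` are variances (cm²); under the ADE
    variant the ``C`` slots carry the dominance variance D.  ``r_os`` is the
    opposite-sex additive-genetic correlation in [0, 0.5].  The four means
    (cm, residual scale) are zygosity- and sex-specific.
    """

    A_m: float
    C_m: float
    E_m: float
    A_f: float
    C_f: float
    E_f: float
    r_os: float = 0.5
    mu_MZ_m: float = 0.0
    mu_DZ_m: float = 0.0
    mu_MZ_f: float = 0.0
    mu_DZ_f: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A_m", "C_m", "E_m", "A_f", "C_f", "E_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.r_os <= 0.5:
            raise ValueError(f"r_os must lie in [0, 0.5], got {self.r_os}")
        if self.A_m + self.C_m + self.E_m <= 0 or self.A_f + self.C_f + self.E_f <= 0:
            raise ValueError("total variance per sex must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "SexLimitationParams":
        return cls(**dict(zip(PARAM_NAMES, map(float, theta))))

    def to_dict(self) -> dict:
        return asdict(self)


def expected_covariance(
    params: SexLimitationParams, group: str, variant: str = "ace"
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied (mean, covariance) of a twin pair in ``group``.

    Returns the 2-vector of member means and the 2×2 covariance.  For OSDZ
    the male twin is member 1.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if variant not in ("ace", "ade"):
        raise ValueError(f"variant must be 'ace' or 'ade', got {variant!r}")
    p = params
    Vm = p.A_m + p.C_m + p.E_m
    Vf = p.A_f + p.C_f + p.E_f
    # DZ coefficient of the non-additive/shared slot: C is fully shared (1.0),
    # dominance D has DZ coefficient 0.25
    cdz = 1.0 if variant == "ace" else 0.25
    if group == "MZM":
        mean = np.array([p.mu_MZ_m, p.mu_MZ_m])
        cov = np.array([[Vm, p.A_m + p.C_m], [p.A_m + p.C_m, Vm]])
    elif group == "MZF":
        mean = np.array([p.mu_MZ_f, p.mu_MZ_f])
        cov = np.array([[Vf, p.A_f + p.C_f], [p.A_f + p.C_f, Vf]])
    elif group == "DZM":
        w = 0.5 * p.A_m + cdz * p.C_m
        mean = np.array([p.mu_DZ_m, p.mu_DZ_m])
        cov = np.array([[Vm, w], [w, Vm]])
    elif group == "DZF":
        w = 0.5 * p.A_f + cdz * p.C_f
        mean = np.array([p.mu_DZ_f, p.mu_DZ_f])
        cov = np.array([[Vf, w], [w, Vf]])
    else:  # OSDZ, male first
        w = p.r_os * math.sqrt(p.A_m * p.A_f) + cdz * math.sqrt(p.C_m * p.C_f)
        mean = np.array([p.mu_DZ_m, p.mu_DZ_f])
        cov = np.array([[Vm, w], [w, Vf]])
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
    if det <= 0 or cov[0, 0] <= 0:
        warnings.warn(f"model-implied covariance for {group} is not positive definite", stacklevel=2)
    return mean, cov


def group_pairs(pairs: pd.DataFrame) -> dict[str, np.ndarray]:
    """Split paired observations into the five zygosity-sex groups.

    Returns ``group -> (n, 2)`` array of (height_resid1, height_resid2);
    OSDZ arrays have the male twin in column 0 (the ordering produced by
    :func:`twinmod.preprocess.make_pairs`).
    """
    out: dict[str, np.ndarray] = {}
    z = pairs["zygosity"].to_numpy()
    s1 = pairs["sex1"].to_numpy()
    h = pairs[["height_resid1", "height_resid2"]].to_numpy(float)
    masks = {
        "MZM": (z == "MZ") & (s1 == "M"),
        "MZF": (z == "MZ") & (s1 == "F"),
        "DZM": (z == "SSDZ") & (s1 == "M"),
        "DZF": (z == "SSDZ") & (s1 == "F"),
        "OSDZ": z == "OSDZ",
    }
    for g, m in masks.items():
        if m.any():
            arr = h[m]
            if g == "OSDZ" and (pairs.loc[m, "sex1"] == "F").any():
                raise ValueError("OSDZ pairs must be ordered male-first")
            out[g] = arr
    return out


def _as_group_dict(pairs) -> dict[str, np.ndarray]:
    if isinstance(pairs, dict):
        return {g: np.asarray(a, dtype=float) for g, a in pairs.items() if len(a)}
    return group_pairs(pairs)


def neg_loglik(params: SexLimitationParams, pairs, variant: str = "ace") -> float:
    """Negative log-likelihood of paired data under the five-group model.

    ``pairs`` is either the paired DataFrame or a ``group -> (n, 2)`` dict.
    Each pair contributes the negative log bivariate-normal density under its
    group's model-implied mean and covariance.  A singular model-implied
    covariance yields ``+inf`` (optimizer-safe), never an exception.
    """
    data = _as_group_dict(pairs)
    total = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g, x in data.items():
            mean, cov = expected_covariance(params, g, variant)
            det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
            if det <= 0 or cov[0, 0] <= 0 or cov[1, 1] <= 0:
                return math.inf
            d1 = x[:, 0] - mean[0]
            d2 = x[:, 1] - mean[1]
            quad = (cov[1, 1] * d1 * d1 - 2.0 * cov[0, 1] * d1 * d2 + cov[0, 0] * d2 * d2) / det
            total += len(x) * (_LOG2PI + 0.5 * math.log(det)) + 0.5 * float(quad.sum())
    return total


# ---------------------------------------------------------------------------
# sufficient statistics and the fast objective

def _suff_stats(data: dict[str, np.ndarray]):
    """(group, n, mean1, mean2, s11, s22, s12) with s* the scatter about the
    sample mean; the likelihood depends on the data only through these."""
    out = []
    for g, x in data.items():
        n = len(x)
        m = x.mean(axis=0)
        d = x - m
        out.append((g, float(n), float(m[0]), float(m[1]),
                    float(d[:, 0] @ d[:, 0]), float(d[:, 1] @ d[:, 1]),
                    float(d[:, 0] @ d[:, 1])))
    return out


def _nll_theta(theta, stats_list, cdz: float) -> float:
    Am, Cm, Em, Af, Cf, Ef, r, mMZm, mDZm, mMZf, mDZf = theta
    Vm = Am + Cm + Em
    Vf = Af + Cf + Ef
    total = 0.0
    for g, n, m1, m2, s11, s22, s12 in stats_list:
        if g == "MZM":
            v1 = v2 = Vm
            w = Am + Cm
            u1 = u2 = mMZm
        elif g == "MZF":
            v1 = v2 = Vf
            w = Af + Cf
            u1 = u2 = mMZf
        elif g == "DZM":
            v1 = v2 = Vm
            w = 0.5 * Am + cdz * Cm
            u1 = u2 = mDZm
        elif g == "DZF":
            v1 = v2 = Vf
            w = 0.5 * Af + cdz * Cf
            u1 = u2 = mDZf
        else:
            v1, v2 = Vm, Vf
            w = r * math.sqrt(Am * Af) + cdz * math.sqrt(Cm * Cf)
            u1, u2 = mDZm, mDZf
        det = v1 * v2 - w * w
        if det <= 0 or v1 <= 0 or v2 <= 0:
            return 1e12
        e1 = m1 - u1
        e2 = m2 - u2
        quad = (v2 * (s11 + n * e1 * e1) - 2.0 * w * (s12 + n * e1 * e2)
                + v1 * (s22 + n * e2 * e2)) / det
        total += n * (_LOG2PI + 0.5 * math.log(det)) + 0.5 * quad
    return total


def _moment_start(data: dict[str, np.ndarray]) -> np.ndarray:
    """Moment-based initial values: A₀ = 2(r_MZ − r_DZ)·V̂, C₀ from
    2r_DZ − r_MZ clipped at 0, E₀ the remainder."""
    theta = np.zeros(11)
    for j, sex in enumerate(("m", "f")):
        mz = data.get("MZM" if sex == "m" else "MZF")
        dz = data.get("DZM" if sex == "m" else "DZF")
        col = 0 if sex == "m" else 1
        os_ = data.get("OSDZ")
        vals = []
        if mz is not None:
            vals.append(mz.ravel())
        if dz is not None:
            vals.append(dz.ravel())
        if os_ is not None:
            vals.append(os_[:, col])
        V = float(np.var(np.concatenate(vals))) if vals else 1.0
        r_mz = _safe_corr(mz)
        r_dz = _safe_corr(dz)
        if r_mz is None:
            r_mz = 0.7
        if r_dz is None:
            r_dz = 0.45
        A0 = np.clip(2.0 * (r_mz - r_dz) * V, 0.05 * V, 0.95 * V)
        C0 = np.clip((2.0 * r_dz - r_mz) * V, 0.0, 0.9 * V)
        E0 = max(V - A0 - C0, 0.05 * V)
        base = 3 * j
        theta[base:base + 3] = A0, C0, E0
        if mz is not None:
            theta[7 + 2 * j] = float(mz.mean())
        if dz is not None or os_ is not None:
            parts = []
            if dz is not None:
                parts.append(dz.ravel())
            if os_ is not None:
                parts.append(os_[:, col])
            theta[8 + 2 * j] = float(np.concatenate(parts).mean())
    theta[6] = 0.4
    return theta


def _safe_corr(x):
    if x is None or len(x) < 3:
        return None
    c = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
    return None if not np.isfinite(c) else float(c)


_E_FLOOR = 1e-8


def _bounds():
    return [(0.0, None), (0.0, None), (_E_FLOOR, None),
            (0.0, None), (0.0, None), (_E_FLOOR, None),
            (0.0, 0.5),
            (None, None), (None, None), (None, None), (None, None)]


def _fd_hessian(f, theta, bounds, rel_step=1e-4):
    """Central finite-difference Hessian, shifting evaluation points inward
    when a parameter sits at a box bound (one-sided curvature there)."""
    k = len(theta)
    h = np.array([rel_step * max(abs(t), 1e-2) for t in theta])
    lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])

    def shift(t):
        return np.clip(t, lo, hi)

    H = np.zeros((k, k))
    f0 = f(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        # diagonal
        tp, tm = shift(theta + ei), shift(theta - ei)
        fp, fm = f(tp), f(tm)
        dp = tp[i] - theta[i]
        dm = theta[i] - tm[i]
        if dp == 0 and dm == 0:  # parameter pinned by equal bounds
            continue
        if dp > 0 and dm > 0:
            H[i, i] = (fp - 2 * f0 + fm) / (dp * dm)
        elif dp > 0:  # at lower bound: one-sided second difference
            t2 = shift(theta + 2 * ei)
            H[i, i] = (f(t2) - 2 * fp + f0) / (dp * dp)
        else:
            t2 = shift(theta - 2 * ei)
            H[i, i] = (f(t2) - 2 * fm + f0) / (dm * dm)
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h[j]
            tpp = shift(theta + ei + ej)
            tpm = shift(theta + ei - ej)
            tmp = shift(theta - ei + ej)
            tmm = shift(theta - ei - ej)
            denom = (tpp[i] - tmm[i]) * (tpp[j] - tmm[j])
            if denom > 0:
                H[i, j] = H[j, i] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / denom
    return H


class SexLimitationACE(BaseEstimator):
    """Maximum-likelihood five-group sex-limitation variance decomposition.

    Parameters
    ----------
    variant : {"ace", "ade"}, default "ace"
        ``ace`` fits additive genetic + shared environment + unique
        environment; ``ade`` replaces the shared environment with dominance
        (DZ cross-twin coefficient 0.25).
    n_restarts : int, default 3
        Jittered restarts added to the moment-based start.
    random_state : int, default 0
        Seed of the restart jitter (and of any bootstrap fallback).
    bootstrap_fallback : int, default 100
        Parametric-bootstrap replicates used for sampling variances when the
        observed information is singular (boundary estimates); 0 disables.

    Attributes
    ----------
    params_ : SexLimitationParams
    loglik_ : float
    converged_ : bool
    n_pairs_ : dict group -> count
    vcov_ : (11, 11) sampling covariance of the parameter vector from the
        inverse observed information (finite differences); rows/columns of
        parameters held fixed (unidentified) are zero.
    bootstrap_used_ : bool
    """

    def __init__(self, variant: str = "ace", n_restarts: int = 3,
                 random_state: int = 0, bootstrap_fallback: int = 100):
        self.variant = variant
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.bootstrap_fallback = bootstrap_fallback

    # -- fitting ------------------------------------------------------------

    def fit(self, pairs, y=None) -> "SexLimitationACE":
        if self.variant not in ("ace", "ade"):
            raise ValueError(f"variant must be 'ace' or 'ade', got {self.variant!r}")
        data = _as_group_dict(pairs)
        if not data:
            raise ValueError("no twin pairs supplied")
        missing = [g for g in GROUPS if g not in data]
        if missing:
            warnings.warn(
                f"group(s) {missing} empty; parameters identified only by the "
                "remaining groups (r_os fixed if OSDZ absent)",
                stacklevel=2,
            )
        self.n_pairs_ = {g: len(a) for g, a in data.items()}
        stats_list = _suff_stats(data)
        cdz = 1.0 if self.variant == "ace" else 0.25
        obj = lambda th: _nll_theta(th, stats_list, cdz)

        start = _moment_start(data)
        rng = np.random.default_rng(self.random_state)
        starts = [start]
        for _ in range(self.n_restarts):
            s = start.copy()
            s[:6] = np.maximum(s[:6] * rng.lognormal(0.0, 0.4, size=6), 1e-3)
            s[6] = rng.uniform(0.05, 0.45)
            starts.append(s)

        bounds = _bounds()
        if "OSDZ" not in data:
            bounds[6] = (start[6], start[6])  # r_os unidentified
        best = None
        for s in starts:
            res = optimize.minimize(obj, s, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 500, "ftol": 1e-11})
            if best is None or res.fun < best.fun:
                best = res
        self._stats = stats_list
        self._cdz = cdz
        self._obj = obj
        self._bounds = bounds
        theta = np.asarray(best.x, dtype=float)
        theta[:6] = np.maximum(theta[:6], 0.0)
        self.theta_ = theta
        self.params_ = SexLimitationParams.from_array(theta)
        self.nll_ = float(best.fun)
        self.loglik_ = -self.nll_
        self.converged_ = bool(best.success) and np.isfinite(best.fun)
        if not self.converged_:
            warnings.warn(f"optimizer did not converge: {best.message}", stacklevel=2)
        self._compute_vcov()
        return self

    # -- sampling variances -------------------------------------------------

    def _compute_vcov(self) -> None:
        theta = self.theta_
        fixed = np.zeros(len(theta), dtype=bool)
        fixed[6] = self._bounds[6][0] == self._bounds[6][1]
        H = _fd_hessian(self._obj, theta, self._bounds)
        free = ~fixed
        Hf = H[np.ix_(free, free)]
        self.bootstrap_used_ = False
        try:
            # PD check via Cholesky; boundary estimates often leave H singular
            np.linalg.cholesky(Hf + 0.0)
            cov_f = np.linalg.inv(Hf)
            if (np.diag(cov_f) < 0).any():
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            if self.bootstrap_fallback > 0:
                self.vcov_ = self._bootstrap_vcov(self.bootstrap_fallback)
                self.bootstrap_used_ = True
                return
            cov_f = np.linalg.pinv(Hf)
        vcov = np.zeros((len(theta), len(theta)))
        vcov[np.ix_(free, free)] = cov_f
        self.vcov_ = vcov

    def _bootstrap_vcov(self, n_boot: int) -> np.ndarray:
        """Parametric bootstrap of the parameter covariance (used when the
        observed information is singular at a boundary estimate)."""
        rng = np.random.default_rng(self.random_state + 1_000_003)
        self.bootstrap_seed_ = self.random_state + 1_000_003
        est = []
        for _ in range(n_boot):
            data = {}
            for g, n in self.n_pairs_.items():
                mean, cov = expected_covariance(self.params_, g, self.variant)
                data[g] = rng.multivariate_normal(mean, cov, size=n)
            sub = SexLimitationACE(variant=self.variant, n_restarts=0,
                                   random_state=self.random_state,
                                   bootstrap_fallback=0)
            # avoid recursion into vcov machinery: fit point estimates only
            stats_list = _suff_stats(data)
            obj = lambda th: _nll_theta(th, stats_list, self._cdz)
            res = optimize.minimize(obj, self.theta_, method="L-BFGS-B",
                                    bounds=self._bounds,
                                    options={"maxiter": 300, "ftol": 1e-10})
            est.append(res.x)
        return np.cov(np.asarray(est).T, ddof=1)

    def component_sampling_variance(self) -> dict[str, float]:
        """Sampling variances of the raw components A, C, E per sex."""
        d = np.diag(self.vcov_)
        return {name: float(max(d[i], 0.0)) for i, name in enumerate(PARAM_NAMES[:6])}

    # -- derived quantities -------------------------------------------------

    def standardize(self) -> dict[str, float]:
        """Standardized components a², c², e² per sex (each triple sums to 1)."""
        p = self.params_
        out = {}
        for sex, (A, C, E) in (("m", (p.A_m, p.C_m, p.E_m)), ("f", (p.A_f, p.C_f, p.E_f))):
            T = A + C + E
            out[f"a2_{sex}"] = A / T
            out[f"c2_{sex}"] = C / T
            out[f"e2_{sex}"] = E / T
        return out

    def standardized_sampling_variance(self) -> dict[str, float]:
        """Delta-method sampling variances of a², c², e² per sex."""
        out = {}
        for j, sex in enumerate(("m", "f")):
            idx = slice(3 * j, 3 * j + 3)
            A, C, E = self.theta_[idx]
            T = A + C + E
            V = self.vcov_[idx, idx]
            grads = {
                "a2": np.array([C + E, -A, -A]) / T**2,
                "c2": np.array([-C, A + E, -C]) / T**2,
                "e2": np.array([-E, -E, A + C]) / T**2,
            }
            for comp, g in grads.items():
                out[f"{comp}_{sex}"] = float(max(g @ V @ g, 0.0))
        return out

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        """Wald intervals for all parameters from the observed information."""
        q = stats.norm.ppf(0.5 + level / 2.0)
        se = np.sqrt(np.maximum(np.diag(self.vcov_), 0.0))
        return pd.DataFrame(
            {"estimate": self.theta_, "se": se,
             "ci_low": self.theta_ - q * se, "ci_high": self.theta_ + q * se},
            index=list(PARAM_NAMES),
        )

    def profile_ci(self, param: str, level: float = 0.95,
                   max_expand: float = 8.0) -> tuple[float, float]:
        """Profile-likelihood confidence interval for one parameter.

        The bound solves 2·(profiled nll − minimum nll) = χ²₁(level), with
        all other parameters re-optimized at each candidate value; a bound
        that runs into the parameter's box constraint is reported at the
        constraint.
        """
        i = PARAM_NAMES.index(param)
        crit = stats.chi2.ppf(level, df=1) / 2.0
        lo_b, hi_b = self._bounds[i]
        lo_b = -np.inf if lo_b is None else lo_b
        hi_b = np.inf if hi_b is None else hi_b

        def profiled(v):
            bnds = list(self._bounds)
            bnds[i] = (v, v)
            s = self.theta_.copy()
            s[i] = v
            res = optimize.minimize(self._obj, s, method="L-BFGS-B", bounds=bnds,
                                    options={"maxiter": 300, "ftol": 1e-10})
            return res.fun - self.nll_ - crit

        se = math.sqrt(max(self.vcov_[i, i], 1e-12))
        step = max(se, 1e-3 * max(abs(self.theta_[i]), 1.0))
        out = []
        for sign in (-1.0, 1.0):
            x0 = self.theta_[i]
            x1 = x0
            found = None
            for mult in np.linspace(0.5, max_expand, 16):
                x1 = np.clip(x0 + sign * mult * 2.0 * step, lo_b, hi_b)
                if profiled(x1) > 0:
                    found = x1
                    break
                if x1 in (lo_b, hi_b):
                    break
            if found is None:
                out.append(float(x1))  # bound at the constraint
            else:
                lo, hi = sorted((x0, found))
                out.append(float(optimize.brentq(profiled, lo, hi, xtol=1e-5)))
        return out[0], out[1]


def fit_ml(pairs, variant: str = "ace", **kwargs) -> SexLimitationACE:
    """Fit the five-group sex-limitation model; thin wrapper over
    :class:`SexLimitationACE`."""
    return SexLimitationACE(variant=variant, **kwargs).fit(pairs)


def fit_by_stratum(
    pairs: pd.DataFrame,
    by: tuple[str, ...] = ("age_group", "edu_category"),
    variant: str = "ace",
    min_pairs: int = 50,
    random_state: int = 0,
    bootstrap_fallback: int = 100,
    n_restarts: int = 2,
) -> pd.DataFrame:
    """Joint five-group fit per stratification cell; one output row per sex.

    Cells with fewer than ``min_pairs`` total pairs are skipped (logged via
    a warning).  Each row carries the raw components with their sampling
    variances (inverse observed information, or parametric bootstrap at
    boundary estimates) and the standardized proportions with delta-method
    sampling variances — the inputs of the meta-regression stage.
    """
    rows = []
    skipped = []
    for key, sub in pairs.groupby(list(by)):
        key = key if isinstance(key, tuple) else (key,)
        if len(sub) < min_pairs:
            skipped.append(key)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = SexLimitationACE(
                variant=variant, random_state=random_state,
                bootstrap_fallback=bootstrap_fallback, n_restarts=n_restarts,
            ).fit(sub)
        comp_var = est.component_sampling_variance()
        std = est.standardize()
        std_var = est.standardized_sampling_variance()
        p = est.params_
        for sex in ("m", "f"):
            A, C, E = (p.A_m, p.C_m, p.E_m) if sex == "m" else (p.A_f, p.C_f, p.E_f)
            n_sex = sum(
                n for g, n in est.n_pairs_.items()
                if (sex == "m" and g in ("MZM", "DZM", "OSDZ"))
                or (sex == "f" and g in ("MZF", "DZF", "OSDZ"))
            )
            row = dict(zip(by, key))
            row.update(
                sex=sex.upper(),
                A=A, C=C, E=E,
                var_A=comp_var[f"A_{sex}"], var_C=comp_var[f"C_{sex}"],
                var_E=comp_var[f"E_{sex}"],
                a2=std[f"a2_{sex}"], c2=std[f"c2_{sex}"], e2=std[f"e2_{sex}"],
                var_a2=std_var[f"a2_{sex}"], var_c2=std_var[f"c2_{sex}"],
                var_e2=std_var[f"e2_{sex}"],
                r_os=p.r_os,
                n_pairs=n_sex,
                converged=est.converged_,
                bootstrap_used=est.bootstrap_used_,
            )
            rows.append(row)
    if skipped:
        warnings.warn(
            f"{len(skipped)} stratum cell(s) below min_pairs={min_pairs} skipped: "
            f"{skipped[:5]}{'...' if len(skipped) > 5 else ''}",
            stacklevel=2,
        )
    return pd.DataFrame(rows)
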