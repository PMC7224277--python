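"""Sex-limitation ACE model: covariance algebra, likelihood, fitting."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from twinmod.ace import (
    GROUPS,
    SexLimitationACE,
    SexLimitationParams,
    expected_covariance,
    fit_by_stratum,
    fit_ml,
    neg_loglik,
)
from twinmod.simulate import StratumSpec, simulate_group

from conftest import exact_moment_pairs


def _params(**kw):
    base = dict(A_m=60, C_m=20, E_m=20, A_f=60, C_f=20, E_f=20, r_os=0.5)
    base.update(kw)
    return SexLimitationParams(**base)


class TestExpectedCovariance:
    def test_mz_male(self):
        _, cov = expected_covariance(_params(), "MZM")
        np.testing.assert_allclose(cov, [[100, 80], [80, 100]])

    def test_ade_ssdz_quarter_coefficient(self):
        # dominance: cross-twin coefficient 0.25 for DZ pairs
        p = _params(A_m=60, C_m=20, E_m=20)
        _, cov = expected_covariance(p, "DZM", variant="ade")
        assert cov[0, 1] == pytest.approx(0.5 * 60 + 0.25 * 20)

    def test_osdz_reduces_to_ssdz_in_symmetric_limit(self):
        p = _params(r_os=0.5)
        _, cov_os = expected_covariance(p, "OSDZ")
        _, cov_ss = expected_covariance(p, "DZM")
        np.testing.assert_allclose(cov_os, cov_ss)

    def test_means_follow_zygosity_and_sex(self):
        p = _params(mu_MZ_m=1.0, mu_DZ_m=2.0, mu_MZ_f=3.0, mu_DZ_f=4.0)
        assert expected_covariance(p, "MZM")[0].tolist() == [1.0, 1.0]
        assert expected_covariance(p, "OSDZ")[0].tolist() == [2.0, 4.0]

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            expected_covariance(_params(), "DOS")


class TestNegLoglik:
    def test_closed_form_at_the_mean(self):
        # a single MZ pair at the group mean: −log density = log 2π + ½·log(V²−W²)
        p = _params()
        data = {"MZM": np.zeros((1, 2))}
        V, W = 100.0, 80.0
        expected = math.log(2 * math.pi) + 0.5 * math.log(V**2 - W**2)
        assert neg_loglik(p, data) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_density_oracle(self, rng):
        for _ in range(5):
            v = rng.uniform(1, 50, 6)
            p = SexLimitationParams(*v, r_os=rng.uniform(0, 0.5),
                                    mu_MZ_m=rng.normal(), mu_DZ_m=rng.normal(),
                                    mu_MZ_f=rng.normal(), mu_DZ_f=rng.normal())
            data = {g: rng.normal(scale=8.0, size=(20, 2)) for g in GROUPS}
            oracle = 0.0
            for g, x in data.items():
                mean, cov = expected_covariance(p, g)
                oracle -= multivariate_normal(mean, cov).logpdf(x).sum()
            assert neg_loglik(p, data) == pytest.approx(oracle, abs=1e-8)

    def test_duplicate_pair_adds_its_own_contribution(self, rng):
        p = _params()
        x = rng.normal(size=(10, 2))
        base = neg_loglik(p, {"MZM": x})
        extra = neg_loglik(p, {"MZM": x[:1]})
        dup = neg_loglik(p, {"MZM": np.vstack([x, x[:1]])})
        assert dup == pytest.approx(base + extra, abs=1e-9)

    def test_singular_covariance_gives_inf(self):
        p = SexLimitationParams(A_m=0, C_m=0, E_m=1e-300, A_f=1, C_f=0, E_f=1)
        assert neg_loglik(p, {"MZM": np.ones((2, 2))}) == math.inf


class TestFit:
    def test_parameter_recovery(self, balanced_group_data):
        spec, data = balanced_group_data
        est = SexLimitationACE().fit(data)
        assert est.converged_
        std = est.standardize()
        assert std["a2_m"] == pytest.approx(0.8, abs=0.05)
        assert std["c2_m"] == pytest.approx(0.1, abs=0.05)
        assert std["a2_f"] == pytest.approx(0.8, abs=0.05)
        assert est.params_.r_os == pytest.approx(0.4, abs=0.15)

    def test_loglik_at_optimum_beats_truth(self, balanced_group_data):
        spec, data = balanced_group_data
        est = SexLimitationACE().fit(data)
        truth = SexLimitationParams(A_m=48, C_m=6, E_m=6, A_f=40, C_f=5, E_f=5, r_os=0.4)
        assert -est.loglik_ <= neg_loglik(truth, data) + 1e-6

    def test_boundary_c_zero(self, rng):
        """Sample moments with r_MZ > 2·r_DZ force the shared-environment
        MLE onto the 0 boundary; moments are pinned exactly by construction."""
        data = {
            "MZM": exact_moment_pairs([[100, 80], [80, 100]], [0, 0], 800, rng),
            "DZM": exact_moment_pairs([[100, 30], [30, 100]], [0, 0], 800, rng),
            "MZF": exact_moment_pairs([[90, 72], [72, 90]], [0, 0], 800, rng),
            "DZF": exact_moment_pairs([[90, 27], [27, 90]], [0, 0], 800, rng),
            "OSDZ": exact_moment_pairs([[100, 28], [28, 90]], [0, 0], 800, rng),
        }
        est = SexLimitationACE().fit(data)
        assert est.converged_
        assert est.params_.C_m == pytest.approx(0.0, abs=1e-4)
        assert est.params_.C_f == pytest.approx(0.0, abs=1e-4)

    def test_fit_ml_wrapper_on_dataframe(self, small_pairs):
        est = fit_ml(small_pairs)
        assert est.converged_
        assert set(est.n_pairs_) <= set(GROUPS)

    def test_missing_group_warns(self, balanced_group_data):
        _, data = balanced_group_data
        partial = {g: v for g, v in data.items() if g != "OSDZ"}
        with pytest.warns(UserWarning, match="OSDZ"):
            est = SexLimitationACE().fit(partial)
        assert est.converged_


class TestStandardize:
    def test_simple_proportions(self):
        est = SexLimitationACE()
        est.params_ = _params(A_m=60, C_m=20, E_m=20)
        est.theta_ = est.params_.as_array()
        est.vcov_ = np.eye(11)
        std = est.standardize()
        assert (std["a2_m"], std["c2_m"], std["e2_m"]) == (0.6, 0.2, 0.2)
        assert std["a2_m"] + std["c2_m"] + std["e2_m"] == pytest.approx(1.0, abs=1e-12)

    def test_invariant_under_height_rescaling(self, balanced_group_data):
        _, data = balanced_group_data
        est1 = SexLimitationACE().fit(data)
        est2 = SexLimitationACE().fit({g: 2.0 * x for g, x in data.items()})
        s1, s2 = est1.standardize(), est2.standardize()
        for k in s1:
            assert s1[k] == pytest.approx(s2[k], abs=5e-3)


class TestSamplingVariance:
    def test_variance_scales_inversely_with_n(self):
        rng = np.random.default_rng(15)
        spec = StratumSpec("x", A_m=48, C_m=6, E_m=6, A_f=40, C_f=5, E_f=5, r_os=0.4)
        v = {}
        for n in (800, 3200):
            data = {g: simulate_group(spec, g, n, rng) for g in GROUPS}
            est = SexLimitationACE().fit(data)
            v[n] = est.component_sampling_variance()["A_m"]
        ratio = v[3200] / v[800]
        assert 0.1 < ratio < 0.5  # ≈ 1/4 expected, generous band

    def test_e_variance_positive(self, balanced_group_data):
        _, data = balanced_group_data
        est = SexLimitationACE().fit(data)
        sv = est.component_sampling_variance()
        assert sv["E_m"] > 0 and sv["E_f"] > 0

    def test_delta_method_matches_bootstrap(self):
        """Delta-method variance of â² agrees with a parametric-bootstrap
        oracle within 30%."""
        rng = np.random.default_rng(31)
        spec = StratumSpec("x", A_m=48, C_m=12, E_m=12, A_f=48, C_f=12, E_f=12, r_os=0.45)
        data = {g: simulate_group(spec, g, 1000, rng) for g in GROUPS}
        est = SexLimitationACE().fit(data)
        delta = est.standardized_sampling_variance()["a2_m"]
        boots = []
        for _ in range(150):
            bdata = {}
            for g, n in est.n_pairs_.items():
                mean, cov = expected_covariance(est.params_, g)
                bdata[g] = rng.multivariate_normal(mean, cov, size=n)
            b = SexLimitationACE(n_restarts=0, bootstrap_fallback=0).fit(bdata)
            boots.append(b.standardize()["a2_m"])
        emp = float(np.var(boots, ddof=1))
        assert delta == pytest.approx(emp, rel=0.30)

    def test_profile_ci_contains_estimate(self, balanced_group_data):
        _, data = balanced_group_data
        est = SexLimitationACE().fit(data)
        lo, hi = est.profile_ci("A_m")
        assert lo < est.params_.A_m < hi
        # comparable magnitude to the Wald interval at this n
        wald = est.conf_int().loc["A_m"]
        assert (hi - lo) == pytest.approx(wald.ci_high - wald.ci_low, rel=0.5)


class TestModelComparison:
    def test_ade_beats_ace_on_dominance_data(self):
        """Data generated with real dominance variance: the ADE variant
        attains a higher likelihood than ACE on the same pairs."""
        rng = np.random.default_rng(10)
        truth = SexLimitationParams(A_m=40, C_m=25, E_m=15, A_f=40, C_f=25, E_f=15, r_os=0.5)
        data = {}
        for g in GROUPS:
            mean, cov = expected_covariance(truth, g, variant="ade")
            data[g] = rng.multivariate_normal(mean, cov, size=4000)
        ace = SexLimitationACE(variant="ace").fit(data)
        ade = SexLimitationACE(variant="ade").fit(data)
        assert ade.loglik_ > ace.loglik_

    def test_saturated_mz_reduction_reproduces_sample_covariance(self, rng):
        """On MZ-male data alone the (A or C)+E model is exactly identified:
        the fitted total variance and cross-twin covariance reproduce the
        sample moments."""
        x = exact_moment_pairs([[100, 80], [80, 100]], [1.0, 1.0], 500, rng)
        with pytest.warns(UserWarning):
            est = SexLimitationACE(bootstrap_fallback=0).fit({"MZM": x})
        _, cov = expected_covariance(est.params_, "MZM")
        assert cov[0, 0] == pytest.approx(100.0, rel=1e-3)
        assert cov[0, 1] == pytest.approx(80.0, rel=1e-3)


class TestFitByStratum:
    def _pairs(self, specs, n=400, seed=0):
        rng = np.random.default_rng(seed)
        frames = []
        pid = 0
        for lab, spec in specs.items():
            for g in GROUPS:
                x = simulate_group(spec, g, n, rng)
                z = {"MZM": "MZ", "MZF": "MZ", "DZM": "SSDZ", "DZF": "SSDZ", "OSDZ": "OSDZ"}[g]
                s1 = "M" if g in ("MZM", "DZM", "OSDZ") else "F"
                s2 = "F" if g in ("MZF", "DZF", "OSDZ") else "M"
                if g in ("MZM", "DZM"):
                    s2 = "M"
                frames.append(pd.DataFrame({
                    "pair_id": np.arange(pid, pid + n),
                    "age_group": 10,
                    "zygosity": z,
                    "sex1": s1,
                    "sex2": s2,
                    "height_resid1": x[:, 0],
                    "height_resid2": x[:, 1],
                    "edu_category": lab,
                }))
                pid += n
        return pd.concat(frames, ignore_index=True)

    def test_only_moderated_stratum_shows_inflated_c(self):
        base = dict(A_m=40, C_m=5, E_m=10, A_f=40, C_f=5, E_f=10, r_os=0.45)
        lowd = dict(base, C_m=15, C_f=15)
        specs = {
            "low": StratumSpec("low", **lowd),
            "mid": StratumSpec("mid", **base),
            "high": StratumSpec("high", **base),
        }
        strata = fit_by_stratum(self._pairs(specs, n=800, seed=6), by=("edu_category",))
        low_c = strata.loc[(strata.edu_category == "low") & (strata.sex == "M"), "C"].iloc[0]
        mid_c = strata.loc[(strata.edu_category == "mid") & (strata.sex == "M"), "C"].iloc[0]
        var_low = strata.loc[(strata.edu_category == "low") & (strata.sex == "M"), "var_C"].iloc[0]
        assert low_c > mid_c
        assert abs(low_c - 15.0) < 2.5 * np.sqrt(var_low) + 1.0

    def test_small_stratum_skipped_with_warning(self, small_pairs):
        with pytest.warns(UserWarning, match="min_pairs"):
            out = fit_by_stratum(small_pairs, min_pairs=10**6)
        assert len(out) == 0

    def test_row_schema(self, small_pairs):
        out = fit_by_stratum(small_pairs, min_pairs=50)
        need = {"A", "C", "E", "var_A", "var_C", "var_E", "a2", "c2", "e2",
                "var_a2", "var_c2", "var_e2", "sex", "n_pairs", "converged"}
        assert need <= set(out.columns)
        assert set(out["sex"]) <= {"M", "F"}
        np.testing.assert_allclose(out[["a2", "c2", "e2"]].sum(axis=1), 1.0, atol=1e-9)
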