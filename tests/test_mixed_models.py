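"""Design construction, LMM/GLMM fitting, R-squared, Wald tests, reduction."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snailmorph.mixed_models import (GeneralizedLinearMixedModel,
                                     LinearMixedModel, ModelSpec,
                                     NestingViolationError, build_design,
                                     fit_glmm, fit_lmm, r2_nakagawa,
                                     reduce_model, wald_type2)


def _nested_frame(rng, n=400, n_hap=2, genos_per_hap=5, sd_hap=0.5, sd_gen=0.3,
                  sd_res=0.4, beta=(1.0, 0.5), extra_noise_cols=0):
    hap = rng.integers(0, n_hap, n)
    geno = hap * genos_per_hap + rng.integers(0, genos_per_hap, n)
    x = rng.normal(size=n)
    u1 = rng.normal(0, sd_hap, n_hap)
    u2 = rng.normal(0, sd_gen, n_hap * genos_per_hap)
    y = beta[0] + beta[1] * x + u1[hap] + u2[geno] + rng.normal(0, sd_res, n)
    df = pd.DataFrame({"y": y, "x": x, "haplotype": hap, "genotype": geno})
    for j in range(extra_noise_cols):
        df[f"noise{j}"] = rng.normal(size=n)
    return df


class TestBuildDesign:
    def test_standardization_and_ordinal_coding(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(size=30),
            "temp": rng.uniform(10, 25, 30),
            "flow": rng.choice(["none", "low", "high"], 30),
            "haplotype": rng.integers(0, 2, 30),
        })
        df["genotype"] = df["haplotype"] * 2
        spec = ModelSpec(response="y", fixed=["temp", "flow"])
        d = build_design(df, spec)
        temp = d.X[:, d.terms["temp"][0]]
        assert abs(temp.mean()) < 1e-12
        assert temp.std(ddof=0) == pytest.approx(1.0)
        flow_raw = df["flow"].map({"none": 0, "low": 1, "high": 2}).to_numpy(float)
        flow_std = (flow_raw - flow_raw.mean()) / flow_raw.std(ddof=0)
        np.testing.assert_allclose(d.X[:, d.terms["flow"][0]], flow_std)

    def test_interaction_formed_after_standardization(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(size=30), "a": rng.normal(5, 2, 30),
            "b": rng.normal(-3, 1, 30),
            "haplotype": np.zeros(30, int), "genotype": np.zeros(30, int),
        })
        d = build_design(df, ModelSpec(response="y", fixed=["a", "b"],
                                       interactions=[("a", "b")]))
        prod = d.X[:, d.terms["a"][0]] * d.X[:, d.terms["b"][0]]
        np.testing.assert_allclose(d.X[:, d.terms["a:b"][0]], prod)

    def test_nesting_violation(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(size=10), "x": rng.normal(size=10),
            "haplotype": [0] * 5 + [1] * 5, "genotype": [7] * 10,
        })
        with pytest.raises(NestingViolationError):
            build_design(df, ModelSpec(response="y", fixed=["x"]))

    def test_missing_rows_excluded_with_count(self, rng):
        df = pd.DataFrame({
            "y": [1.0, np.nan, 2.0, 3.0], "x": [0.1, 0.2, np.nan, 0.4],
            "haplotype": [0, 0, 1, 1], "genotype": [0, 0, 1, 1],
        })
        d = build_design(df, ModelSpec(response="y", fixed=["x"], standardize=False))
        assert d.n == 2 and d.n_excluded == 2


class TestLMM:
    def test_zero_variance_matches_ols(self, rng):
        df = _nested_frame(rng, n=300, sd_hap=0.0, sd_gen=0.0)
        d = build_design(df, ModelSpec(response="y", fixed=["x"], standardize=False))
        fit = fit_lmm(d)
        beta_ols = np.linalg.lstsq(d.X, d.y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta_ols, atol=1e-6)

    def test_balanced_oneway_matches_anova_moments(self, rng):
        """Balanced one-way design: ML variance components match the
        method-of-moments ANOVA estimator (interior case)."""
        n_groups, m = 20, 15
        sd_g, sd_e = 1.0, 0.5
        g = np.repeat(np.arange(n_groups), m)
        y = rng.normal(0, sd_g, n_groups)[g] + rng.normal(0, sd_e, len(g))
        # the inner factor duplicates the outer grouping, so the one-way
        # group variance is the sum of the two (ridge-shared) components
        df = pd.DataFrame({"y": y, "haplotype": g, "genotype": g})
        d = build_design(df, ModelSpec(response="y", fixed=[]))
        fit = LinearMixedModel(method="reml").fit(d).fit_
        grand = y.mean()
        group_means = y.reshape(n_groups, m).mean(axis=1)
        msb = m * ((group_means - grand) ** 2).sum() / (n_groups - 1)
        msw = ((y.reshape(n_groups, m) - group_means[:, None]) ** 2).sum() / (
            n_groups * (m - 1))
        sigma_g_mom = (msb - msw) / m
        total_group_var = (fit.variance_components["haplotype"]
                           + fit.variance_components["genotype_in_haplotype"])
        assert total_group_var == pytest.approx(sigma_g_mom, abs=1e-6 + 0.02 * sigma_g_mom)
        assert fit.variance_components["residual"] == pytest.approx(msw, rel=0.02)

    def test_loglik_matches_statsmodels(self, rng):
        """Independent oracle: statsmodels MixedLM with the same two
        variance-component structure reaches the same ML log-likelihood."""
        import statsmodels.formula.api as smf

        df = _nested_frame(rng, n=250)
        d = build_design(df, ModelSpec(response="y", fixed=["x"], standardize=False))
        ours = fit_lmm(d, method="ml")
        df2 = df.assign(one=1, h=df["haplotype"].astype(str),
                        g=df["genotype"].astype(str))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm("y ~ x", df2, groups=df2["one"],
                                 vc_formula={"h": "0 + C(h)", "g": "0 + C(g)"}) \
                .fit(reml=False, method="lbfgs")
        # our profiled optimum must not fall below the oracle's, and the two
        # should agree closely (optimizer stopping rules differ slightly)
        assert ours.log_likelihood >= sm_fit.llf - 1e-3
        assert ours.log_likelihood == pytest.approx(sm_fit.llf, abs=0.05)
        assert ours.variance_components["residual"] == pytest.approx(
            sm_fit.scale, rel=1e-3)

    def test_boundary_reported_as_exact_zero(self, rng):
        df = _nested_frame(rng, n=300, sd_hap=0.0, sd_gen=0.0)
        d = build_design(df, ModelSpec(response="y", fixed=["x"], standardize=False))
        fit = fit_lmm(d)
        assert fit.variance_components["haplotype"] == 0.0
        assert fit.boundary["haplotype"]


class TestGLMM:
    def test_zero_variance_matches_glm(self, rng):
        import statsmodels.api as sm

        n = 500
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.3 * x))
        df = pd.DataFrame({"y": y, "x": x,
                           "haplotype": rng.integers(0, 2, n)})
        df["genotype"] = df["haplotype"]
        d = build_design(df, ModelSpec(response="y", family="poisson",
                                       fixed=["x"], standardize=False))
        fit = fit_glmm(d, "poisson")
        glm = sm.GLM(d.y, d.X, family=sm.families.Poisson()).fit()
        if fit.variance_components["haplotype"] == 0.0 and \
                fit.variance_components["genotype_in_haplotype"] == 0.0:
            np.testing.assert_allclose(fit.coefficients.to_numpy(),
                                       glm.params, atol=1e-4)

    def test_poisson_slope_recovery(self, rng):
        n = 2000
        hap = rng.integers(0, 2, n)
        geno = hap * 5 + rng.integers(0, 5, n)
        cs = rng.normal(size=n)
        y = rng.poisson(np.exp(3 + 0.5 * cs
                               + rng.normal(0, 0.2, 2)[hap]
                               + rng.normal(0, 0.1, 10)[geno]))
        df = pd.DataFrame({"y": y, "cs": cs, "haplotype": hap, "genotype": geno})
        d = build_design(df, ModelSpec(response="y", family="poisson",
                                       fixed=["cs"], standardize=False))
        fit = fit_glmm(d, "poisson")
        assert fit.coefficients["cs"] == pytest.approx(0.5, rel=0.10)

    def test_logistic_sigma_order_of_magnitude(self, rng):
        """Two groups of 200 with sigma_hap = 2: the median estimated sd over
        seeds recovers the sign and order of magnitude.  With two levels the
        variance is estimated from a single realized contrast (the intercept
        absorbs the mean), so the estimator is biased low by construction;
        the order-of-magnitude band reflects that."""
        sds = []
        for _ in range(31):
            hap = np.repeat([0, 1], 200)
            geno = hap * 3 + rng.integers(0, 3, 400)
            u = rng.normal(0, 2.0, 2)
            eta = 0.3 + u[hap]
            y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
            df = pd.DataFrame({"y": y, "x": rng.normal(size=400),
                               "haplotype": hap, "genotype": geno})
            d = build_design(df, ModelSpec(response="y", family="binomial",
                                           fixed=["x"], standardize=False))
            fit = fit_glmm(d, "binomial")
            sds.append(np.sqrt(fit.variance_components["haplotype"]))
        med = np.median(sds)
        assert 0.5 <= med <= 4.0

    def test_binary_response_validation(self, rng):
        df = pd.DataFrame({"y": [0, 1, 2.0, 1], "x": rng.normal(size=4),
                           "haplotype": [0, 0, 1, 1], "genotype": [0, 0, 1, 1]})
        d = build_design(df, ModelSpec(response="y", family="binomial",
                                       fixed=["x"], standardize=False))
        with pytest.raises(ValueError):
            fit_glmm(d, "binomial")


class TestR2:
    def test_noiseless_fixed_only_limit(self, rng):
        df = _nested_frame(rng, n=200, sd_hap=0.0, sd_gen=0.0, sd_res=1e-6)
        d = build_design(df, ModelSpec(response="y", fixed=["x"], standardize=False))
        r2m, r2c = r2_nakagawa(fit_lmm(d))
        assert r2m == pytest.approx(1.0, abs=1e-3)
        assert r2c == pytest.approx(1.0, abs=1e-3)

    def test_ordering_invariant(self, rng):
        df = _nested_frame(rng, n=300)
        d = build_design(df, ModelSpec(response="y", fixed=["x"]))
        r2m, r2c = r2_nakagawa(fit_lmm(d))
        assert 0 <= r2m <= r2c <= 1

    def test_affine_rescaling_invariance(self, rng):
        df = _nested_frame(rng, n=300)
        d1 = build_design(df, ModelSpec(response="y", fixed=["x"]))
        df2 = df.assign(x=df["x"] * 37.0 + 5.0)
        d2 = build_design(df2, ModelSpec(response="y", fixed=["x"]))
        r1 = r2_nakagawa(fit_lmm(d1))
        r2 = r2_nakagawa(fit_lmm(d2))
        assert r1 == pytest.approx(r2, abs=1e-6)

    def test_binomial_uses_logit_variance(self, rng):
        n = 400
        hap = rng.integers(0, 2, n)
        y = (rng.random(n) < 0.5).astype(float)
        df = pd.DataFrame({"y": y, "x": rng.normal(size=n),
                           "haplotype": hap, "genotype": hap})
        d = build_design(df, ModelSpec(response="y", family="binomial", fixed=["x"]))
        fit = fit_glmm(d, "binomial")
        r2m, r2c = r2_nakagawa(fit)
        assert 0 <= r2m <= r2c <= 1


class TestWaldAndReduction:
    def test_single_coefficient_equals_squared_z(self, rng):
        df = _nested_frame(rng, n=300)
        d = build_design(df, ModelSpec(response="y", fixed=["x"]))
        fit = fit_lmm(d)
        table = wald_type2(fit)
        z = fit.coefficients["x"] / fit.standard_errors["x"]
        row = table[table["term"] == "x"].iloc[0]
        assert row["chi2"] == pytest.approx(z**2, rel=1e-9)
        assert row["df"] == 1

    def test_null_predictor_p_uniform(self, rng):
        ps = []
        for _ in range(200):
            df = _nested_frame(rng, n=150, extra_noise_cols=1)
            d = build_design(df, ModelSpec(response="y", fixed=["x", "noise0"]))
            ps.append(float(wald_type2(fit_lmm(d)).set_index("term")
                            .loc["noise0", "p"]))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_agrees_with_likelihood_ratio(self, rng):
        df = _nested_frame(rng, n=2000, beta=(1.0, 0.15))
        d = build_design(df, ModelSpec(response="y", fixed=["x"]))
        fit = fit_lmm(d)
        chi2_wald = float(wald_type2(fit).set_index("term").loc["x", "chi2"])
        from snailmorph.mixed_models import _refit
        fit0 = _refit(d, ["Intercept"], fit)
        chi2_lr = 2 * (fit.log_likelihood - fit0.log_likelihood)
        assert chi2_wald == pytest.approx(chi2_lr, rel=0.15)

    def test_all_noise_reduces_to_intercept(self, rng):
        df = _nested_frame(rng, n=200, beta=(1.0, 0.0), extra_noise_cols=2)
        d = build_design(df, ModelSpec(response="y",
                                       fixed=["x", "noise0", "noise1"]))
        final, trail = reduce_model(d)
        assert list(final.design.terms) == ["Intercept"]
        assert len(trail) == 3

    def test_strong_effect_retained_and_deterministic(self, rng):
        df = _nested_frame(rng, n=400, beta=(1.0, 2.0), extra_noise_cols=2)
        d = build_design(df, ModelSpec(response="y",
                                       fixed=["x", "noise0", "noise1"]))
        f1, t1 = reduce_model(d)
        f2, t2 = reduce_model(d)
        assert "x" in f1.design.terms
        assert [s.dropped for s in t1] == [s.dropped for s in t2]

    def test_interactions_dropped_before_main_effects(self, rng):
        df = _nested_frame(rng, n=300, beta=(1.0, 0.0), extra_noise_cols=1)
        d = build_design(df, ModelSpec(response="y", fixed=["x", "noise0"],
                                       interactions=[("x", "noise0")]))
        _, trail = reduce_model(d)
        dropped = [s.dropped for s in trail]
        if "x:noise0" in dropped and "x" in dropped:
            assert dropped.index("x:noise0") < dropped.index("x")
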