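"""The MCMC mixed-model sampler and its convergence diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import avimeta as am
from avimeta.glmm import GlmmSpec, autocorrelation, fit_glmm, gelman_rubin, pmcmc


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def binomial_rows(rng, corr, n_rows=40, beta=(-0.5, 0.3, -0.4, 0.6),
                  total=200, resid_sd=1.0, n_studies=8):
    sp = list(corr.labels)
    rows = []
    for i in range(n_rows):
        season = "breeding" if rng.random() < 0.5 else "non-breeding"
        sex = "male" if rng.random() < 0.5 else "female"
        x = np.array([1.0, season == "breeding", sex == "male",
                      (season == "breeding") * (sex == "male")])
        eta = float(x @ np.asarray(beta)) + rng.normal(0.0, resid_sd)
        rows.append(
            dict(species=sp[i % len(sp)], study=f"st{rng.integers(n_studies)}",
                 season=season, sex=sex,
                 count=int(rng.binomial(total, _expit(eta))), total=total)
        )
    return pd.DataFrame(rows)


class TestPmcmc:
    def test_arithmetic(self):
        draws = np.concatenate([np.ones(975), -np.ones(25)])
        assert pmcmc(draws) == pytest.approx(0.05)

    def test_one_sided_floor(self):
        assert pmcmc(np.ones(500)) == pytest.approx(2.0 / 500)

    def test_symmetric_draws_near_one(self):
        rng = np.random.default_rng(0)
        assert pmcmc(rng.standard_normal(20000)) == pytest.approx(1.0, abs=0.03)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pmcmc(np.array([]))


class TestGelmanRubin:
    def test_identical_chains_report_one(self):
        x = np.tile(np.random.default_rng(1).standard_normal(200), (2, 1))
        assert gelman_rubin(x) == 1.0

    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(2)
        assert gelman_rubin(rng.standard_normal((3, 2000))) < 1.1

    def test_displaced_chains_flagged(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 500))
        x[0] += 5.0
        x[1] -= 5.0
        assert gelman_rubin(x) > 3.0

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))


class TestAutocorrelation:
    def test_lag_zero_is_exactly_one(self):
        rho = autocorrelation(np.random.default_rng(0).standard_normal(500), 10)
        assert rho[0] == 1.0

    def test_white_noise_lag1_small(self):
        n = 20000
        rho = autocorrelation(np.random.default_rng(4).standard_normal(n), 1)
        assert abs(rho[1]) < 3.0 / np.sqrt(n)

    def test_ar1_profile(self):
        rng = np.random.default_rng(5)
        phi, n = 0.9, 50000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        rho = autocorrelation(x, 2)
        assert rho[1] == pytest.approx(phi, abs=0.02)

    def test_max_lag_bound(self):
        with pytest.raises(ValueError):
            autocorrelation(np.arange(10.0), 10)


class TestSpecValidation:
    def test_bad_specs_rejected(self):
        with pytest.raises(ValueError):
            GlmmSpec(response="x", family="poisson").validate()
        with pytest.raises(ValueError):
            GlmmSpec(response="x", iterations=100, burnin=100).validate()
        with pytest.raises(ValueError):
            GlmmSpec(response="x", chains=1).validate()
        with pytest.raises(ValueError):
            GlmmSpec(response="x", thin=0).validate()

    def test_non_integer_binomial_rejected(self, yule_corr):
        df = pd.DataFrame(
            dict(species=["sp001"] * 4, study=["s"] * 4,
                 season=["breeding"] * 2 + ["non-breeding"] * 2,
                 sex=["male", "female"] * 2, count=[0.5, 1, 2, 3], total=[10] * 4)
        )
        spec = GlmmSpec(response="x", family="binomial", chains=2,
                        iterations=200, burnin=50, thin=1)
        with pytest.raises(ValueError, match="integer"):
            fit_glmm(df, spec, yule_corr)


class TestSampler:
    def test_seeded_determinism(self, yule_corr):
        rng = np.random.default_rng(0)
        df = binomial_rows(rng, yule_corr, n_rows=20)
        spec = GlmmSpec(response="het", family="binomial", chains=2,
                        iterations=400, burnin=100, thin=2, seed=9)
        a = fit_glmm(df, spec, yule_corr)
        b = fit_glmm(df, spec, yule_corr)
        for name in a.draws:
            np.testing.assert_array_equal(a.draws[name], b.draws[name])

    def test_conjugate_posterior_exact(self):
        """Gaussian, fixed-effect-only, known residual variance: the sampler
        must reproduce the closed-form normal posterior (KS check)."""
        rng = np.random.default_rng(0)
        n = 50
        y = rng.normal(0.7, 1.0, n)
        df = pd.DataFrame(
            {"species": "a", "study": "s", "season": "breeding", "sex": "female", "mean": y}
        )
        spec = GlmmSpec(response="x", family="gaussian", random_terms=(),
                        chains=2, iterations=3000, burnin=500, thin=1,
                        seed=1, fix_residual=1.0)
        fit = fit_glmm(df, spec)
        draws = fit.draws["intercept"].ravel()
        post_var = 1.0 / (n + 1e-8)
        post_mean = post_var * y.sum()
        ks = stats.kstest(draws, stats.norm(post_mean, np.sqrt(post_var)).cdf)
        assert ks.statistic < 0.05

    def test_gaussian_ols_limit(self, yule_corr):
        """With no true random variation, fixed-effect posteriors concentrate
        on the ordinary least-squares solution."""
        rng = np.random.default_rng(6)
        sp = list(yule_corr.labels)
        beta = np.array([1.0, 0.5, -0.3, 0.4])
        rows = []
        for i in range(160):
            season = "breeding" if rng.random() < 0.5 else "non-breeding"
            sex = "male" if rng.random() < 0.5 else "female"
            x = np.array([1.0, season == "breeding", sex == "male",
                          (season == "breeding") * (sex == "male")])
            rows.append(dict(species=sp[i % 10], study=f"st{i % 12}", season=season,
                             sex=sex, mean=float(x @ beta + rng.normal(0, 0.5))))
        df = pd.DataFrame(rows)
        X = np.column_stack([
            np.ones(len(df)),
            (df["season"] == "breeding").to_numpy(float),
            (df["sex"] == "male").to_numpy(float),
            ((df["season"] == "breeding") & (df["sex"] == "male")).to_numpy(float),
        ])
        ols = np.linalg.lstsq(X, df["mean"].to_numpy(), rcond=None)[0]
        spec = GlmmSpec(response="x", family="gaussian", chains=2,
                        iterations=2000, burnin=500, thin=2, seed=4)
        fit = fit_glmm(df, spec, yule_corr)
        for j, name in enumerate(fit.fixed_names):
            lo, hi = fit.ci95[name]
            assert lo - 0.1 < ols[j] < hi + 0.1

    def test_binomial_intercept_concentrates_at_empirical_logit(self):
        df = pd.DataFrame(
            dict(species=["a"] * 12, study=["s"] * 12, season=["breeding"] * 12,
                 sex=["female"] * 12, count=[30] * 12, total=[100] * 12)
        )
        spec = GlmmSpec(response="x", family="binomial", random_terms=(),
                        chains=2, iterations=3000, burnin=500, thin=2, seed=3)
        fit = fit_glmm(df, spec)
        lo, hi = fit.ci95["intercept"]
        target = np.log(0.3 / 0.7)
        assert lo < target < hi
        assert abs(fit.post_mean["intercept"] - target) < 0.5

    def test_design_labels_stable_under_species_subset(self, yule_corr):
        rng = np.random.default_rng(8)
        df = binomial_rows(rng, yule_corr, n_rows=30)
        spec = GlmmSpec(response="het", family="binomial", chains=2,
                        iterations=300, burnin=100, thin=2, seed=0)
        full = fit_glmm(df, spec, yule_corr)
        subset = fit_glmm(
            df[df["species"].isin(list(yule_corr.labels)[:6])].reset_index(drop=True),
            spec, yule_corr,
        )
        assert full.fixed_names == subset.fixed_names == (
            "intercept", "season_breeding", "sex_male", "season_breeding:sex_male"
        )

    def test_summary_shape(self, yule_corr):
        rng = np.random.default_rng(1)
        df = binomial_rows(rng, yule_corr, n_rows=24)
        spec = GlmmSpec(response="het", family="binomial", chains=2,
                        iterations=400, burnin=100, thin=2, seed=5)
        fit = fit_glmm(df, spec, yule_corr)
        summ = fit.summary()
        assert list(summ["term"]) == list(fit.fixed_names) + list(fit.variance_names)
        assert (summ["lower"] <= summ["upper"]).all()
        assert summ["pMCMC"].notna().sum() == len(fit.fixed_names)
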