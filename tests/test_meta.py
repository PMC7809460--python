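"""REML multilevel meta-analysis and its test battery."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import avimeta as am
from avimeta.meta import _design, _reml_at

from conftest import make_effects


def _arrays(effects, corr, moderator=None):
    y = np.array([e.g for e in effects])
    v = np.array([e.v for e in effects])
    species = np.array([e.species for e in effects], dtype=object)
    studies = np.array([e.study for e in effects], dtype=object)
    seasons = np.array([e.season for e in effects], dtype=object)
    X, _ = _design(seasons, moderator, None)
    M_p = corr.expand(species)
    M_s = (studies[:, None] == studies[None, :]).astype(float)
    return y, v, X, M_p, M_s


def grid_reml_oracle(y, v, X, M_p, M_s, hi=0.4, step=1e-3):
    """Brute-force REML surface over a (sigma2_phylo, sigma2_study) grid.

    Batched over the grid with numpy's stacked Cholesky; independent of the
    optimiser code path.
    """
    grid = np.arange(0.0, hi + step / 2, step)
    return _grid_eval(grid, grid, y, v, X, M_p, M_s)


def grid_reml_oracle_adaptive(y, v, X, M_p, M_s):
    """Two-stage brute force: coarse sweep over [0, 2]^2 at 0.01, then a
    1e-3-resolution grid around the coarse optimum."""
    coarse = np.arange(0.0, 2.0 + 5e-3, 0.01)
    _, cp, cs = _grid_eval(coarse, coarse, y, v, X, M_p, M_s)
    fine_p = np.arange(max(0.0, cp - 0.02), cp + 0.02 + 5e-4, 1e-3)
    fine_s = np.arange(max(0.0, cs - 0.02), cs + 0.02 + 5e-4, 1e-3)
    return _grid_eval(fine_p, fine_s, y, v, X, M_p, M_s)


def _grid_eval(grid_p, grid_s, y, v, X, M_p, M_s):
    gp, gs = np.meshgrid(grid_p, grid_s, indexing="ij")
    G = gp.size
    k, p = X.shape
    V = (
        np.diag(v)[None, :, :]
        + gp.ravel()[:, None, None] * M_p[None, :, :]
        + gs.ravel()[:, None, None] * M_s[None, :, :]
    )
    L = np.linalg.cholesky(V)
    logdet_v = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum(axis=1)
    Vi_y = np.linalg.solve(V, np.broadcast_to(y, (G, k))[..., None])[..., 0]
    Vi_X = np.linalg.solve(V, np.broadcast_to(X, (G, k, p)))
    XtViX = np.swapaxes(np.broadcast_to(X, (G, k, p)), 1, 2) @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    XtVi_y = X.T[None] @ Vi_y[..., None]
    beta = np.linalg.solve(XtViX, XtVi_y)
    quad = (y[None, :] * Vi_y).sum(axis=1) - (beta[..., 0] * XtVi_y[..., 0]).sum(axis=1)
    ll = -0.5 * ((k - p) * np.log(2 * np.pi) + logdet_v + logdet_x + quad)
    best = np.argmax(ll)
    return float(ll[best]), float(gp.ravel()[best]), float(gs.ravel()[best])


class TestReml:
    def test_zero_variance_limit_is_weighted_mean(self, effect_factory, yule_corr):
        effects = effect_factory(0, k=12)
        y, v, X, M_p, M_s = _arrays(effects, yule_corr, moderator=None)
        _, beta, _ = _reml_at(0.0, 0.0, y, v, X, M_p, M_s)
        w = 1.0 / v
        assert beta[0] == pytest.approx(np.sum(w * y) / np.sum(w), rel=1e-10)

    def test_optimizer_matches_grid_oracle(self, effect_factory, yule_corr):
        for seed in range(3):
            effects = effect_factory(seed, k=8, sigma2_phylo=0.1, sigma2_study=0.1)
            fit = am.fit_multilevel(effects, yule_corr, moderator=None)
            y, v, X, M_p, M_s = _arrays(effects, yule_corr, moderator=None)
            ll_grid, *_ = grid_reml_oracle(y, v, X, M_p, M_s)
            assert fit.reml_loglik >= ll_grid - 1e-3
            assert fit.reml_loglik == pytest.approx(ll_grid, abs=1e-3)

    def test_row_order_invariance(self, effect_factory, yule_corr):
        effects = effect_factory(4, k=20, sigma2_phylo=0.2, sigma2_study=0.1)
        fit1 = am.fit_multilevel(effects, yule_corr)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(effects))
        fit2 = am.fit_multilevel([effects[i] for i in perm], yule_corr)
        pd.testing.assert_series_equal(fit1.coefficients, fit2.coefficients, atol=1e-7, rtol=1e-5)
        assert fit1.sigma2_phylo == pytest.approx(fit2.sigma2_phylo, abs=1e-6)

    def test_identity_A_matches_single_component_oracle(self):
        """With A = I and singleton studies the two components collapse into
        one i.i.d. species effect; the REML optimum must match a 1-D profile."""
        labels = tuple(f"s{i}" for i in range(15))
        corr = am.PhyloCorrelation(labels, np.eye(15))
        rng = np.random.default_rng(3)
        effects = []
        for i, lab in enumerate(labels):
            v = float(rng.uniform(0.05, 0.2))
            effects.append(
                am.EffectSize(
                    g=float(rng.normal(0.3, np.sqrt(v + 0.2))), v=v,
                    species=lab, study=lab, variable="PHA", season="breeding",
                )
            )
        fit = am.fit_multilevel(effects, corr, moderator=None)
        y, v, X, M_p, M_s = _arrays(effects, corr, moderator=None)
        # brute force over the total variance on a fine 1-D grid
        best = -np.inf
        for s_tot in np.arange(0.0, 1.0, 1e-4):
            ll, _, _ = _reml_at(s_tot, 0.0, y, v, X, M_p, M_s)
            best = max(best, ll)
        assert fit.reml_loglik == pytest.approx(best, abs=1e-3)
        assert fit.sigma2_phylo + fit.sigma2_study == pytest.approx(
            np.argmax([_reml_at(s, 0.0, y, v, X, M_p, M_s)[0]
                       for s in np.arange(0.0, 1.0, 1e-3)]) * 1e-3,
            abs=5e-3,
        )

    def test_rank_deficient_moderators_rejected(self, effect_factory, yule_corr):
        effects = effect_factory(1, k=10, seasons=("breeding",))
        with pytest.raises(ValueError, match="rank-deficient"):
            am.fit_multilevel(effects, yule_corr, extra_moderators={"one": np.ones(10)},
                              moderator=None)

    def test_unknown_species_rejected(self, yule_corr):
        e = am.EffectSize(g=0.1, v=0.1, species="dodo", study="s", season="breeding")
        with pytest.raises(KeyError, match="dodo"):
            am.fit_multilevel([e] * 3, yule_corr, moderator=None)

    def test_matches_metafor(self, effect_factory, yule_corr, tmp_path):
        """Independent oracle: metafor's rma.mv on the same data."""
        effects = effect_factory(7, k=14, sigma2_phylo=0.3, sigma2_study=0.1)
        fit = am.fit_multilevel(effects, yule_corr, moderator="season")
        am.effects_to_frame(effects).to_csv(tmp_path / "effs.csv", index=False)
        yule_corr.to_frame().to_csv(tmp_path / "A.csv")
        script = textwrap.dedent(
            """
            suppressMessages(library(metafor))
            d <- read.csv(file.path("%s", "effs.csv"))
            A <- as.matrix(read.csv(file.path("%s", "A.csv"), row.names=1))
            colnames(A) <- rownames(A)
            fit <- rma.mv(g, v, mods=~factor(season)-1,
                          random=list(~1|species, ~1|study),
                          R=list(species=A), Rscale="none", data=d, method="REML")
            cat(coef(fit)[["factor(season)non-breeding"]],
                coef(fit)[["factor(season)breeding"]],
                fit$sigma2, fit$se, fit$QE, sep="\\n")
            """
            % (tmp_path, tmp_path)
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = [float(x) for x in out.stdout.strip().splitlines()]
        assert fit.coefficients["non-breeding"] == pytest.approx(vals[0], abs=1e-4)
        assert fit.coefficients["breeding"] == pytest.approx(vals[1], abs=1e-4)
        assert fit.sigma2_phylo == pytest.approx(vals[2], abs=1e-4)
        assert fit.sigma2_study == pytest.approx(vals[3], abs=1e-4)
        # metafor orders coefficients alphabetically: breeding first
        assert fit.se["breeding"] == pytest.approx(vals[4], abs=1e-4)
        assert fit.se["non-breeding"] == pytest.approx(vals[5], abs=1e-4)
        assert fit.q_resid.statistic == pytest.approx(vals[6], rel=1e-6)


class TestWaldAndQM:
    def test_wald_z_trivial_cases(self, effect_factory, yule_corr):
        fit = am.fit_multilevel(effect_factory(2, k=16), yule_corr)
        res = am.wald_z(fit, "breeding")
        se = fit.se["breeding"]
        assert res.z == pytest.approx(res.estimate / se)
        assert res.ci_low == pytest.approx(res.estimate - 1.96 * se, abs=1e-4)
        assert res.p == pytest.approx(2 * stats.norm.sf(abs(res.z)), rel=1e-12)
        with pytest.raises(KeyError):
            am.wald_z(fit, "winter")

    def test_qm_equals_z_squared_of_difference(self, effect_factory, yule_corr):
        fit = am.fit_multilevel(effect_factory(5, k=18), yule_corr)
        qm = am.omnibus_qm(fit)
        c = np.array([1.0, -1.0])
        diff = c @ fit.coefficients.values
        var = c @ fit.cov.values @ c
        assert qm.df == 1
        assert qm.qm == pytest.approx(diff**2 / var, rel=1e-10)
        assert qm.pvalue == pytest.approx(stats.chi2.sf(qm.qm, 1), rel=1e-12)

    def test_qm_requires_season_contrast(self, effect_factory, yule_corr):
        fit = am.fit_multilevel(effect_factory(6, k=10), yule_corr, moderator=None)
        with pytest.raises(ValueError):
            am.omnibus_qm(fit)


class TestHeterogeneity:
    def test_q_zero_for_identical_effects(self, yule_corr):
        sp = list(yule_corr.labels)
        effects = [
            am.EffectSize(g=0.4, v=0.1, species=sp[i], study=f"s{i}",
                          variable="PHA", season="breeding")
            for i in range(6)
        ]
        fit = am.fit_multilevel(effects, yule_corr, moderator=None)
        assert fit.q_resid.statistic == pytest.approx(0.0, abs=1e-12)
        assert fit.q_resid.df == 5

    def test_q_mean_matches_chi2_under_homogeneity(self, yule_corr):
        rng = np.random.default_rng(10)
        sp = list(yule_corr.labels)
        qs = []
        for _ in range(40):
            effects = []
            for i in range(15):
                v = float(rng.uniform(0.05, 0.3))
                effects.append(
                    am.EffectSize(g=float(rng.normal(0.2, np.sqrt(v))), v=v,
                                  species=sp[i % 10], study=f"s{i}",
                                  variable="PHA", season="breeding")
                )
            qs.append(am.fit_multilevel(effects, yule_corr, moderator=None).q_resid.statistic)
        # E[Q] = k - p = 14 under homogeneity
        assert np.mean(qs) == pytest.approx(14.0, abs=2.0)

    def test_q_inflated_under_heterogeneity(self, effect_factory, yule_corr):
        qs = [
            am.fit_multilevel(
                effect_factory(100 + r, k=15, sigma2_phylo=0.3, sigma2_study=0.3),
                yule_corr, moderator=None,
            ).q_resid.statistic
            for r in range(10)
        ]
        assert np.mean(qs) > 14.0

    def test_i2_zero_when_no_heterogeneity(self, yule_corr):
        rng = np.random.default_rng(1)
        sp = list(yule_corr.labels)
        effects = [
            am.EffectSize(g=float(rng.normal(0, 0.01)), v=0.1, species=sp[i % 10],
                          study=f"s{i}", variable="PHA", season="breeding")
            for i in range(12)
        ]
        fit = am.fit_multilevel(effects, yule_corr, moderator=None)
        assert fit.i2["total"] == pytest.approx(0.0, abs=1e-6)

    def test_i2_plug_in_arithmetic(self, effect_factory, yule_corr):
        fit = am.fit_multilevel(effect_factory(3, k=20), yule_corr, moderator=None)
        w = 1.0 / fit.v
        s2 = (fit.k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
        # force the components to the typical sampling variance
        fit.sigma2_phylo = fit.sigma2_study = s2
        i2 = am.i2_decomposition(fit)
        assert i2["phylogeny"] == pytest.approx(100.0 / 3.0, rel=1e-9)
        assert i2["study"] == pytest.approx(100.0 / 3.0, rel=1e-9)
        assert i2["total"] == pytest.approx(200.0 / 3.0, rel=1e-9)

    def test_typical_variance_degenerates_with_equal_weights(self, yule_corr):
        sp = list(yule_corr.labels)
        effects = [
            am.EffectSize(g=0.1 * i, v=0.2, species=sp[i % 10], study=f"s{i}",
                          variable="PHA", season="breeding")
            for i in range(10)
        ]
        fit = am.fit_multilevel(effects, yule_corr, moderator=None)
        w = 1.0 / fit.v
        s2 = (fit.k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
        assert s2 == pytest.approx(0.2, rel=1e-12)
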