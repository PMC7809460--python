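"""Bayesian mixed models of sex, season and their interaction, by MCMC.

Models a response (one row per species x study x season x sex cell) with
fixed effects for the intercept, season (breeding vs. the non-breeding
reference), sex (male vs. the female reference) and their interaction,
and random intercepts for study and for species, the latter with the
phylogenetic correlation ``A`` as the prior covariance structure:

    eta = X beta + Z_s u_s + Z_p u_p,   u_p ~ N(0, sigma2_p A)

Two families are supported.  *Gaussian*: the response (optionally
log-transformed, as for the H/L ratio) is modelled directly with a
conjugate Gibbs sampler.  *Binomial*: aggregated counts with totals are
modelled through a logit link with an additive latent residual
(overdispersion); the site-wise latent values are updated by a vectorised
Metropolis step inside the Gibbs sweep, and the residual variance is held
fixed (it is not separately identified from the link scale).

Random-effect variances use parameter expansion: each random term is
written ``gamma_c * u_c`` with a working scale parameter
``gamma_c ~ N(0, px_scale^2)`` sampled as an extra regression
coefficient, which implies a heavy-tailed (half-t-like) prior on the
effective standard deviation and greatly improves mixing near zero
variance.  Fixed effects get a diffuse normal prior; the Gaussian
residual variance an inverse-gamma prior.

Reporting follows common MCMC practice: posterior means, equal-tailed
95% credible intervals, pMCMC (twice the smaller tail share of the
posterior mass on either side of zero, floored at 2/N), the Gelman-Rubin
potential scale reduction factor across chains, and autocorrelation
profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo import PhyloCorrelation

__all__ = [
    "PriorSpec",
    "GlmmSpec",
    "McmcFit",
    "fit_glmm",
    "pmcmc",
    "gelman_rubin",
    "autocorrelation",
]

FIXED_LABELS = ("intercept", "season_breeding", "sex_male", "season_breeding:sex_male")
VARIANCE_LABELS = ("var_study", "var_phylogeny", "var_residual")


@dataclass(frozen=True)
class PriorSpec:
    """Prior settings for the Gibbs sampler.

    ``fixed_var``: variance of the diffuse normal prior on fixed effects.
    ``variance_nu``/``variance_v``: inverse-gamma prior IG(nu/2, nu V / 2)
    on the working variances of the random terms.  ``px_scale``: SD of the
    normal working prior on the expansion scale (25 by default, giving a
    half-t-like prior on the effective random-effect SD).  ``residual_*``:
    inverse-gamma shape/scale for the Gaussian residual variance.
    """

    fixed_var: float = 1e8
    variance_nu: float = 1.0
    variance_v: float = 1.0
    px_scale: float = 25.0
    residual_shape: float = 0.001
    residual_scale: float = 0.001


@dataclass
class GlmmSpec:
    """Specification of one MCMC mixed model."""

    response: str
    family: str = "gaussian"
    transform: str | None = None  # "log" for the H/L ratio
    priors: PriorSpec = field(default_factory=PriorSpec)
    random_terms: tuple[str, ...] = ("study", "phylogeny")
    chains: int = 3
    iterations: int = 60_000
    burnin: int = 10_000
    thin: int = 50
    seed: int = 0
    parameter_expansion: bool = True
    fix_residual: float | None = None  # binomial defaults to 1.0

    def validate(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family: {self.family!r}")
        if self.transform not in (None, "log"):
            raise ValueError(f"unknown transform: {self.transform!r}")
        if self.iterations <= self.burnin:
            raise ValueError("iterations must exceed burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.chains < 2:
            raise ValueError("need at least two chains for convergence checks")
        unknown = set(self.random_terms) - {"study", "phylogeny"}
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")


def pmcmc(draws: np.ndarray) -> float:
    """MCMC significance: twice the smaller share of draws on either side of 0.

    Floored at 2/N so a one-sided posterior never reports exactly zero.
    """
    d = np.asarray(draws, dtype=float).ravel()
    n = d.size
    if n == 0:
        raise ValueError("empty draws")
    share_pos = float(np.mean(d > 0))
    share_neg = float(np.mean(d < 0))
    return max(2.0 * min(share_pos, share_neg), 2.0 / n)


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor over chains (rows = chains).

    ``sqrt((W (n-1)/n + B/n) / W)`` with between-chain variance B and
    within-chain variance W; degenerate (zero-variance) inputs and the
    identical-chains case report exactly 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two chains")
    m, n = x.shape
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    w = float(np.mean(np.var(x, axis=1, ddof=1)))
    if w == 0.0:
        return 1.0
    b_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
    var_plus = (n - 1) / n * w + b_over_n
    return max(1.0, math.sqrt(var_plus / w))


def autocorrelation(draws: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalised autocovariance at lags 0..max_lag (lag 0 is exactly 1)."""
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the number of draws")
    xc = x - x.mean()
    acov = np.array([np.dot(xc[: n - k], xc[k:]) / n for k in range(max_lag + 1)])
    if acov[0] == 0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    return acov / acov[0]


@dataclass
class McmcFit:
    """Posterior draws per chain with summaries and convergence diagnostics."""

    draws: dict[str, np.ndarray]  # name -> (chains, n_draws)
    fixed_names: tuple[str, ...]
    variance_names: tuple[str, ...]
    spec: GlmmSpec

    def _flat(self, name: str) -> np.ndarray:
        return self.draws[name].ravel()

    @property
    def post_mean(self) -> dict[str, float]:
        return {k: float(v.mean()) for k, v in self.draws.items()}

    @property
    def ci95(self) -> dict[str, tuple[float, float]]:
        out = {}
        for k, v in self.draws.items():
            lo, hi = np.quantile(v.ravel(), [0.025, 0.975])
            out[k] = (float(lo), float(hi))
        return out

    @property
    def pmcmc_values(self) -> dict[str, float]:
        return {k: pmcmc(self._flat(k)) for k in self.fixed_names}

    @property
    def rhat(self) -> dict[str, float]:
        return {k: gelman_rubin(v) for k, v in self.draws.items()}

    def autocorr(self, name: str, max_lag: int = 20) -> np.ndarray:
        """Autocorrelation profile of one parameter (first chain)."""
        return autocorrelation(self.draws[name][0], max_lag)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, 95% CrI, pMCMC (fixed effects) and R-hat per parameter."""
        mean, ci, ps, rh = self.post_mean, self.ci95, self.pmcmc_values, self.rhat
        rows = []
        for name in (*self.fixed_names, *self.variance_names):
            rows.append(
                {
                    "term": name,
                    "post_mean": mean[name],
                    "lower": ci[name][0],
                    "upper": ci[name][1],
                    "pMCMC": ps.get(name, np.nan),
                    "rhat": rh[name],
                }
            )
        return pd.DataFrame(rows)


def _design_matrix(data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    season = (data["season"].astype(str) == "breeding").to_numpy(float)
    sex = data["sex"].astype(str).str.lower().isin(["m", "male", "males"]).to_numpy(float)
    cols = [np.ones(n)]
    labels = ["intercept"]
    if season.std() > 0:
        cols.append(season)
        labels.append("season_breeding")
    if sex.std() > 0:
        cols.append(sex)
        labels.append("sex_male")
    if season.std() > 0 and sex.std() > 0:
        cols.append(season * sex)
        labels.append("season_breeding:sex_male")
    return np.column_stack(cols), labels


def _indicator(codes: np.ndarray, q: int) -> np.ndarray:
    Z = np.zeros((len(codes), q))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _sample_mvn_from_precision(rng, M: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Draw from N(M^-1 b, M^-1) via the Cholesky factor of M."""
    L = np.linalg.cholesky(M)
    mu = np.linalg.solve(L.T, np.linalg.solve(L, b))
    z = rng.standard_normal(len(b))
    return mu + np.linalg.solve(L.T, z)


def fit_glmm(
    data: pd.DataFrame,
    spec: GlmmSpec,
    corr: PhyloCorrelation | None = None,
) -> McmcFit:
    """Run the Gibbs/Metropolis sampler for one immune variable.

    ``data`` needs columns ``species``, ``study``, ``season``, ``sex`` and,
    for the Gaussian family, a ``mean`` (or ``value``) column; for the
    binomial family integer ``count`` and ``total`` columns.  ``corr`` is
    required whenever ``"phylogeny"`` is among the random terms.
    """
    spec.validate()
    data = data.reset_index(drop=True)
    n = len(data)
    if n < 3:
        raise ValueError("need at least three data rows")

    X, labels = _design_matrix(data)
    p = X.shape[1]

    use_study = "study" in spec.random_terms
    use_phylo = "phylogeny" in spec.random_terms
    if use_phylo:
        if corr is None:
            raise ValueError("phylogeny random term requires a correlation matrix")
        species = sorted(set(data["species"].astype(str)))
        missing = set(species) - set(corr.labels)
        if missing:
            raise KeyError(f"species not in correlation matrix: {sorted(missing)}")
        A = corr.loc(species).matrix
        Ainv = np.linalg.inv(A + 1e-10 * np.eye(len(species)))
        sp_codes = data["species"].astype(str).map({s: i for i, s in enumerate(species)}).to_numpy()
        Zp = _indicator(sp_codes, len(species))
    if use_study:
        studies = sorted(set(data["study"].astype(str)))
        st_codes = data["study"].astype(str).map({s: i for i, s in enumerate(studies)}).to_numpy()
        Zs = _indicator(st_codes, len(studies))

    pri = spec.priors
    if spec.family == "binomial":
        counts = data["count"].to_numpy(float)
        totals = data["total"].to_numpy(float)
        if np.any(np.abs(counts - np.round(counts)) > 1e-9) or np.any(
            np.abs(totals - np.round(totals)) > 1e-9
        ):
            raise ValueError("binomial data must be integer counts and totals")
        if np.any(totals <= 0) or np.any(counts < 0) or np.any(counts > totals):
            raise ValueError("binomial counts must satisfy 0 <= count <= total")
        fix_residual = 1.0 if spec.fix_residual is None else float(spec.fix_residual)
    else:
        col = "mean" if "mean" in data.columns else "value"
        yobs = data[col].to_numpy(float)
        if spec.transform == "log":
            if np.any(yobs <= 0):
                raise ValueError("log transform requires positive responses")
            yobs = np.log(yobs)
        fix_residual = spec.fix_residual

    n_keep = (spec.iterations - spec.burnin) // spec.thin
    chain_seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
    store: dict[str, np.ndarray] = {
        name: np.empty((spec.chains, n_keep)) for name in labels
    }
    for name in VARIANCE_LABELS:
        store[name] = np.empty((spec.chains, n_keep))

    for c in range(spec.chains):
        rng = np.random.default_rng(chain_seeds[c])
        beta = np.zeros(p)
        us = np.zeros(len(studies)) if use_study else None
        up = np.zeros(len(species)) if use_phylo else None
        gs = gp = 1.0
        s2s = s2p = 1.0
        s2e = fix_residual if fix_residual is not None else 1.0
        if spec.family == "binomial":
            latent = np.log((counts + 0.5) / (totals - counts + 0.5))
            step = np.full(n, 1.0)
        else:
            latent = yobs

        keep = 0
        for it in range(spec.iterations):
            # --- latent Metropolis update (binomial) -------------------
            eta = X @ beta
            if use_study:
                eta = eta + gs * (Zs @ us)
            if use_phylo:
                eta = eta + gp * (Zp @ up)
            if spec.family == "binomial":
                prop = latent + step * rng.standard_normal(n)
                def _lp(l):
                    return (
                        counts * l
                        - totals * np.logaddexp(0.0, l)
                        - (l - eta) ** 2 / (2.0 * s2e)
                    )
                log_acc = _lp(prop) - _lp(latent)
                accept = np.log(rng.random(n)) < log_acc
                latent = np.where(accept, prop, latent)
                if it < spec.burnin:
                    step *= np.exp(0.1 * (accept.astype(float) - 0.44))
                    np.clip(step, 1e-2, 20.0, out=step)
                w_resp = latent
            else:
                w_resp = latent  # == yobs

            # --- joint (beta, u) given scales and variances ------------
            blocks = [X]
            prior_diag = [np.full(p, 1.0 / pri.fixed_var)]
            if use_study:
                blocks.append(gs * Zs)
                prior_diag.append(np.full(len(studies), 1.0 / s2s))
            if use_phylo:
                blocks.append(gp * Zp)
                prior_diag.append(np.zeros(len(species)))  # dense block below
            W = np.hstack(blocks)
            P = np.diag(np.concatenate(prior_diag))
            if use_phylo:
                off = p + (len(studies) if use_study else 0)
                P[off:, off:] = Ainv / s2p
            M = W.T @ W / s2e + P
            sol = _sample_mvn_from_precision(rng, M, W.T @ w_resp / s2e)
            beta = sol[:p]
            pos = p
            if use_study:
                us = sol[pos : pos + len(studies)]
                pos += len(studies)
            if use_phylo:
                up = sol[pos:]

            # --- working scales (parameter expansion) ------------------
            if spec.parameter_expansion and (use_study or use_phylo):
                gcols = [X]
                gdiag = [np.full(p, 1.0 / pri.fixed_var)]
                if use_study:
                    gcols.append((Zs @ us)[:, None])
                    gdiag.append(np.array([1.0 / pri.px_scale**2]))
                if use_phylo:
                    gcols.append((Zp @ up)[:, None])
                    gdiag.append(np.array([1.0 / pri.px_scale**2]))
                G = np.hstack(gcols)
                Mg = G.T @ G / s2e + np.diag(np.concatenate(gdiag))
                sol = _sample_mvn_from_precision(rng, Mg, G.T @ w_resp / s2e)
                beta = sol[:p]
                pos = p
                if use_study:
                    gs = sol[pos]
                    pos += 1
                if use_phylo:
                    gp = sol[pos]

            # --- variance components -----------------------------------
            a0 = pri.variance_nu / 2.0
            b0 = pri.variance_nu * pri.variance_v / 2.0
            if use_study:
                s2s = _inv_gamma(rng, a0 + len(studies) / 2.0, b0 + us @ us / 2.0)
            if use_phylo:
                s2p = _inv_gamma(rng, a0 + len(species) / 2.0, b0 + up @ (Ainv @ up) / 2.0)
            if fix_residual is None:
                eta = X @ beta
                if use_study:
                    eta = eta + gs * (Zs @ us)
                if use_phylo:
                    eta = eta + gp * (Zp @ up)
                ssr = float(np.sum((w_resp - eta) ** 2))
                s2e = _inv_gamma(rng, pri.residual_shape + n / 2.0, pri.residual_scale + ssr / 2.0)

            if it >= spec.burnin and (it - spec.burnin) % spec.thin == 0 and keep < n_keep:
                for j, name in enumerate(labels):
                    store[name][c, keep] = beta[j]
                store["var_study"][c, keep] = gs**2 * s2s if use_study else 0.0
                store["var_phylogeny"][c, keep] = gp**2 * s2p if use_phylo else 0.0
                store["var_residual"][c, keep] = s2e
                keep += 1

    return McmcFit(
        draws=store,
        fixed_names=tuple(labels),
        variance_names=VARIANCE_LABELS,
        spec=spec,
    )


def _inv_gamma(rng: np.random.Generator, shape: float, scale: float) -> float:
    g = rng.gamma(shape, 1.0 / scale)
    if g <= 0 or not np.isfinite(g):
        raise ArithmeticError("divergent variance update (overflow)")
    return 1.0 / g
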