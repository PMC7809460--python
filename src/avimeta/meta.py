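"""Multilevel random-effects meta-analysis with a phylogenetic random effect.

The model for the effect sizes is

    y ~ N(X beta, V),   V = sigma2_study Zs Zs' + sigma2_phylo Zp A Zp' + diag(v_i)

where ``A`` is the Brownian-motion correlation among species, ``Zs`` and
``Zp`` map effects to studies and species, and ``v_i`` are the known
sampling variances.  Variance components are estimated by REML with a
bounded quasi-Newton optimiser on the log-variance scale (three starts,
objective tolerance 1e-8); components that hit the zero boundary are
reported as exactly zero.  The fixed effects are the GLS solution at the
optimum with covariance ``(X' V^-1 X)^-1``.

Season enters as a cell-means moderator (one mean per season, no
intercept) so each season's sex bias is directly testable against zero;
the overall (no-moderator) model is fitted separately.

The test battery mirrors standard meta-analytic reporting: Wald Z tests
with normal 95% CIs per coefficient, the omnibus QM chi-squared on the
contrasts distinguishing seasons, Cochran's Q for residual heterogeneity
(computed from the weighted fixed-effects-only fit), and a multilevel I2
decomposition (phylogeny / study / total) based on the Higgins-Thompson
typical sampling variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .effects import SEASONS, EffectSize
from .phylo import PhyloCorrelation

__all__ = [
    "MetaFit",
    "fit_multilevel",
    "wald_z",
    "omnibus_qm",
    "cochran_q",
    "i2_decomposition",
    "WaldZ",
    "QMTest",
    "HetTest",
]

_LOG_BOUNDS = (math.log(1e-10), math.log(1e3))
_ZERO_SNAP = 1e-7


class HetTest(NamedTuple):
    statistic: float
    df: int
    pvalue: float


class QMTest(NamedTuple):
    qm: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class WaldZ:
    estimate: float
    ci_low: float
    ci_high: float
    z: float
    p: float


@dataclass
class MetaFit:
    """A fitted multilevel meta-model."""

    coefficients: pd.Series
    cov: pd.DataFrame
    sigma2_phylo: float
    sigma2_study: float
    k: int
    p: int
    reml_loglik: float
    moderator: str | None
    q_resid: HetTest = field(default=None)  # filled by fit_multilevel
    i2: dict = field(default_factory=dict)
    # design internals, used by the diagnostics module
    y: np.ndarray = field(default=None, repr=False)
    v: np.ndarray = field(default=None, repr=False)
    X: np.ndarray = field(default=None, repr=False)
    species: np.ndarray = field(default=None, repr=False)
    studies: np.ndarray = field(default=None, repr=False)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.values)), index=self.coefficients.index)


def _as_arrays(effects: Sequence[EffectSize]):
    effects = list(effects)
    y = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    species = np.array([e.species for e in effects], dtype=object)
    studies = np.array([e.study for e in effects], dtype=object)
    seasons = np.array([e.season for e in effects], dtype=object)
    return y, v, species, studies, seasons


def _design(seasons: np.ndarray, moderator: str | None, extra: dict | None):
    k = len(seasons)
    if moderator is None:
        X = np.ones((k, 1))
        labels = ["overall"]
    elif moderator == "season":
        levels = [s for s in SEASONS if s in set(seasons)]
        if not levels:
            levels = sorted(set(seasons))
        X = np.column_stack([(seasons == lev).astype(float) for lev in levels])
        labels = list(levels)
    else:
        raise ValueError(f"unknown moderator: {moderator!r}")
    if extra:
        for name, col in extra.items():
            X = np.column_stack([X, np.asarray(col, dtype=float)])
            labels.append(name)
    return X, labels


def _reml_loglik(par: np.ndarray, y, v, X, M_p, M_s) -> float:
    """Restricted log-likelihood at (sigma2_phylo, sigma2_study) = exp(par)."""
    s_p, s_s = np.exp(par)
    return _reml_at(s_p, s_s, y, v, X, M_p, M_s)[0]


def _reml_at(s_p, s_s, y, v, X, M_p, M_s):
    k, p = X.shape
    V = np.diag(v) + s_p * M_p + s_s * M_s
    try:
        cho = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    logdet_v = 2.0 * np.log(np.diag(cho[0])).sum()
    Vi_y = cho_solve(cho, y)
    Vi_X = cho_solve(cho, X)
    XtViX = X.T @ Vi_X
    try:
        cho_x = cho_factor(XtViX, lower=True)
    except np.linalg.LinAlgError:
        raise ValueError("rank-deficient moderators") from None
    logdet_x = 2.0 * np.log(np.diag(cho_x[0])).sum()
    beta = cho_solve(cho_x, X.T @ Vi_y)
    quad = y @ Vi_y - beta @ (X.T @ Vi_y)
    ll = -0.5 * ((k - p) * math.log(2.0 * math.pi) + logdet_v + logdet_x + quad)
    cov = cho_solve(cho_x, np.eye(p))
    return ll, beta, cov


def fit_multilevel(
    effects: Sequence[EffectSize],
    corr: PhyloCorrelation,
    moderator: str | None = "season",
    extra_moderators: dict | None = None,
) -> MetaFit:
    """REML fit of the multilevel (phylogeny + study) meta-model.

    ``moderator`` is ``"season"`` for the cell-means by-season model or
    ``None`` for the overall (intercept-only) model.  ``extra_moderators``
    maps label -> column and is used e.g. by the Egger regression to
    append the standard errors as a continuous moderator.
    """
    y, v, species, studies, seasons = _as_arrays(effects)
    k = len(y)
    missing = sorted(set(species) - set(corr.labels))
    if missing:
        raise KeyError(f"species not in correlation matrix: {missing}")
    X, labels = _design(seasons, moderator, extra_moderators)
    p = X.shape[1]
    if k <= p:
        raise ValueError("need more effects than fixed parameters")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient moderators")

    M_p = corr.expand(species)  # k x k phylogenetic correlation between effects
    M_s = (studies[:, None] == studies[None, :]).astype(float)

    # Three starts for the bounded quasi-Newton search on log variances:
    # a moment-based start and two fixed brackets.
    s0 = max((np.var(y, ddof=1) - v.mean()) / 2.0, 1e-3) if k > 1 else 1e-3
    starts = [(s0, s0), (0.01, 0.01), (0.25, 0.25)]
    best = None
    for st in starts:
        res = optimize.minimize(
            lambda par: -_reml_loglik(par, y, v, X, M_p, M_s),
            x0=np.log(st),
            method="L-BFGS-B",
            bounds=[_LOG_BOUNDS, _LOG_BOUNDS],
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    s_p, s_s = np.exp(best.x)
    # Components at the boundary are reported as exactly zero.
    if s_p < _ZERO_SNAP:
        s_p = 0.0
    if s_s < _ZERO_SNAP:
        s_s = 0.0
    ll, beta, cov = _reml_at(s_p, s_s, y, v, X, M_p, M_s)

    fit = MetaFit(
        coefficients=pd.Series(beta, index=labels),
        cov=pd.DataFrame(cov, index=labels, columns=labels),
        sigma2_phylo=float(s_p),
        sigma2_study=float(s_s),
        k=k,
        p=p,
        reml_loglik=float(ll),
        moderator=moderator,
        y=y,
        v=v,
        X=X,
        species=species,
        studies=studies,
    )
    fit.q_resid = cochran_q(fit)
    fit.i2 = i2_decomposition(fit)
    return fit


def wald_z(fit: MetaFit, which: str) -> WaldZ:
    """Wald Z test of one coefficient against zero, with a normal 95% CI."""
    if which not in fit.coefficients.index:
        raise KeyError(f"unknown coefficient label: {which!r}")
    est = float(fit.coefficients[which])
    se = float(fit.se[which])
    z = est / se if se > 0 else math.inf * np.sign(est) if est else 0.0
    pval = 2.0 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    half = 1.959963984540054 * se
    return WaldZ(estimate=est, ci_low=est - half, ci_high=est + half, z=z, p=pval)


def omnibus_qm(fit: MetaFit, contrasts: np.ndarray | None = None) -> QMTest:
    """Omnibus Wald-type chi-squared test on the moderator block.

    By default the contrasts are the successive differences between the
    season means (a single between-season contrast for the two-season
    model), so QM tests whether the sex bias differs by season.
    """
    labels = list(fit.coefficients.index)
    if contrasts is None:
        season_idx = [i for i, lab in enumerate(labels) if lab in SEASONS]
        if len(season_idx) < 2:
            raise ValueError("no season contrast available in this fit")
        C = np.zeros((len(season_idx) - 1, len(labels)))
        for r in range(len(season_idx) - 1):
            C[r, season_idx[r]] = 1.0
            C[r, season_idx[r + 1]] = -1.0
    else:
        C = np.atleast_2d(np.asarray(contrasts, dtype=float))
        if C.shape[1] != len(labels):
            raise ValueError("contrast matrix has wrong width")
        if C.shape[0] == 0:
            raise ValueError("empty moderator block")
    cb = C @ fit.coefficients.values
    cov_m = C @ fit.cov.values @ C.T
    try:
        qm = float(cb @ np.linalg.solve(cov_m, cb))
    except np.linalg.LinAlgError:
        raise ValueError("singular moderator covariance") from None
    df = C.shape[0]
    return QMTest(qm=qm, df=df, pvalue=float(stats.chi2.sf(qm, df)))


def cochran_q(fit: MetaFit) -> HetTest:
    """Cochran's Q for residual heterogeneity beyond sampling error.

    Uses the weighted fixed-effects-only projection (weights 1/v_i) with
    the same moderator design; Q is referred to chi-squared with k - p
    degrees of freedom.
    """
    y, v, X = fit.y, fit.v, fit.X
    k, p = X.shape
    if k <= p:
        raise ValueError("need more effects than fixed parameters")
    w = 1.0 / v
    XtWX = X.T @ (w[:, None] * X)
    beta_fe = np.linalg.solve(XtWX, X.T @ (w * y))
    resid = y - X @ beta_fe
    q = float(np.sum(w * resid**2))
    df = k - p
    return HetTest(statistic=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def i2_decomposition(fit: MetaFit) -> dict[str, float]:
    """Multilevel I2 (%) for the phylogeny and study components.

    ``I2_c = 100 sigma2_c / (sigma2_phylo + sigma2_study + s2_typical)``
    with the Higgins-Thompson typical sampling variance
    ``s2 = (k - 1) sum(w) / (sum(w)^2 - sum(w^2))``, ``w_i = 1/v_i``;
    the total is the sum of the two components.
    """
    if fit.k < 2:
        raise ValueError("need at least two effects")
    w = 1.0 / fit.v
    s2_typ = (fit.k - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
    denom = fit.sigma2_phylo + fit.sigma2_study + s2_typ
    i2_p = float(100.0 * fit.sigma2_phylo / denom)
    i2_s = float(100.0 * fit.sigma2_study / denom)
    return {"phylogeny": i2_p, "study": i2_s, "total": i2_p + i2_s}
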