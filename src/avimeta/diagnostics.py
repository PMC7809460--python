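"""Publication-bias and influence diagnostics for the meta-analysis.

Funnel-plot asymmetry is tested with the Egger regression in its
moderator form: the multilevel model is refitted with the effect-size
standard errors appended as a continuous moderator, and asymmetry is the
Wald test of that coefficient (flagged at p < 0.10).  The classical
precision-weighted regression is exposed as an option.

Influence screening follows the leave-one-out logic for weighted
fixed-effects projections: externally standardised deleted residuals and
hat values have closed forms there, which keeps the screen deterministic
and fast.  An effect is flagged when |residual| > 3, or |residual| > 2
together with leverage above twice the average (2 p / k); the model is
then refitted without the flagged effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .effects import EffectSize
from .meta import MetaFit, fit_multilevel, wald_z
from .phylo import PhyloCorrelation

__all__ = ["EggerResult", "InfluenceResult", "egger_test", "funnel_data", "flag_influential"]


@dataclass(frozen=True)
class EggerResult:
    estimate: float
    se: float
    z: float
    p: float
    biased: bool
    fit: MetaFit


@dataclass
class InfluenceResult:
    flags: np.ndarray
    residuals: np.ndarray
    leverage: np.ndarray
    refit: MetaFit


def egger_test(
    effects: list[EffectSize],
    corr: PhyloCorrelation,
    moderator: str | None = None,
    alpha: float = 0.10,
    form: str = "moderator",
) -> EggerResult:
    """Egger funnel-asymmetry test within the multilevel model.

    ``form="moderator"`` (default) appends se_i to the model's moderators
    and tests its coefficient; ``form="precision"`` runs the classical
    weighted regression of the standardised effects on precision, where
    the *intercept* is the asymmetry statistic.  The two parameterisations
    test the same association.
    """
    effects = list(effects)
    if len(effects) < 3:
        raise ValueError("need at least three effects to test asymmetry")
    se = np.array([e.se for e in effects])
    if np.ptp(se) < 1e-12:
        raise ValueError("asymmetry untestable: standard errors are constant")

    if form == "moderator":
        fit = fit_multilevel(effects, corr, moderator=moderator, extra_moderators={"se": se})
        res = wald_z(fit, "se")
        est, se_coef, z, p = res.estimate, fit.se["se"], res.z, res.p
    elif form == "precision":
        # g_i / se_i = b0 + b1 / se_i + error: b0 is the Egger intercept.
        y = np.array([e.g for e in effects]) / se
        x = 1.0 / se
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = len(y) - 2
        s2 = resid @ resid / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        est, se_coef = float(beta[0]), float(np.sqrt(cov[0, 0]))
        z = est / se_coef
        p = 2.0 * stats.norm.sf(abs(z))
        fit = None
    else:
        raise ValueError(f"unknown Egger form: {form!r}")
    return EggerResult(
        estimate=float(est), se=float(se_coef), z=float(z), p=float(p),
        biased=bool(p < alpha), fit=fit,
    )


def funnel_data(effects: list[EffectSize], fit: MetaFit) -> pd.DataFrame:
    """Plot-ready funnel pairs: columns ``residual`` (y - X beta) then ``se``."""
    y = np.array([e.g for e in effects])
    resid = y - fit.X @ fit.coefficients.values
    return pd.DataFrame({"residual": resid, "se": np.array([e.se for e in effects])})


def flag_influential(
    effects: list[EffectSize],
    corr: PhyloCorrelation,
    moderator: str | None = None,
    resid_cut: float = 3.0,
    resid_cut_leverage: float = 2.0,
) -> InfluenceResult:
    """Leave-one-out influence screen with refit excluding flagged effects.

    Residuals and hat values come from the weighted fixed-effects
    projection (weights 1/v_i) of the same moderator design; the deleted
    residual standardises to ``e_i sqrt(w_i) / sqrt(1 - h_ii)``.  The
    thresholds are configurable; the defaults flag |t| > 3 outright and
    |t| > 2 when the hat value exceeds twice the mean leverage p/k.
    """
    effects = list(effects)
    k = len(effects)
    if k < 5:
        raise ValueError("too few effects for LOO diagnostics (need >= 5)")
    y = np.array([e.g for e in effects])
    v = np.array([e.v for e in effects])
    seasons = np.array([e.season for e in effects], dtype=object)

    from .meta import _design  # same design construction as the model fits

    X, _ = _design(seasons, moderator, None)
    p = X.shape[1]
    w = 1.0 / v
    XtWX_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    beta = XtWX_inv @ (X.T @ (w * y))
    resid = y - X @ beta
    hat = np.einsum("ij,jk,ik->i", X, XtWX_inv, X) * w
    hat = np.clip(hat, 0.0, 1.0 - 1e-12)
    t = resid * np.sqrt(w) / np.sqrt(1.0 - hat)
    flags = (np.abs(t) > resid_cut) | (
        (np.abs(t) > resid_cut_leverage) & (hat > 2.0 * p / k)
    )
    kept = [e for e, f in zip(effects, flags) if not f]
    refit = fit_multilevel(kept, corr, moderator=moderator)
    return InfluenceResult(flags=flags, residuals=t, leverage=hat, refit=refit)
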