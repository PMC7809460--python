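"""Standardised effect sizes for male-versus-female comparisons.

Per-sex summary statistics (sample size, arithmetic mean, and a dispersion
estimate reported as an SD, an SE, or a 95% confidence interval) are
converted into Hedges' *g* standardised mean differences with sampling
variances.  The sign convention throughout the package is male minus
female: positive *g* indicates a male-biased immune measure, negative *g*
a female bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VARIABLES",
    "SEASONS",
    "GroupStats",
    "EffectSize",
    "sd_from_se",
    "sd_from_ci",
    "hedges_g",
    "counts_to_proportions",
    "hl_ratio",
    "build_effect_table",
    "effects_to_frame",
]

log = logging.getLogger(__name__)

#: The nine supported immune variables: four white-blood-cell proportions,
#: the heterophil/lymphocyte ratio, and four immune-response assays
#: (phytohaemagglutinin skin test, bacteria-killing ability, haemolysis,
#: haemagglutination).
VARIABLES = (
    "heterophils",
    "lymphocytes",
    "macrophages",
    "eosinophils",
    "H/L",
    "PHA",
    "BKA",
    "HL",
    "HA",
)

SEASONS = ("non-breeding", "breeding")

_MALE_LABELS = {"m", "male", "males"}
_FEMALE_LABELS = {"f", "female", "females"}


def sd_from_se(se: float, n: int) -> float:
    """Recover a standard deviation from a standard error: ``SD = SE * sqrt(n)``."""
    se = float(se)
    if se <= 0:
        raise ValueError("standard error must be positive")
    if n < 1:
        raise ValueError("sample size must be >= 1")
    return se * math.sqrt(n)


def sd_from_ci(lower: float, upper: float, n: int) -> float:
    """Recover a standard deviation from a two-sided 95% confidence interval.

    ``SD = sqrt(n) * (upper - lower) / (2 * delta)`` where ``delta`` is the
    two-sided 95% quantile of the t distribution with ``n - 1`` degrees of
    freedom (i.e. ``t_{0.975, n-1}``, which tends to 1.96 for large n).

    Zero-width or inverted intervals are rejected rather than imputed.
    """
    if n < 2:
        raise ValueError("sample size must be >= 2 (t quantile undefined at df 0)")
    if not upper > lower:
        raise ValueError("confidence interval must have upper > lower")
    delta = stats.t.ppf(0.975, n - 1)
    return math.sqrt(n) * (upper - lower) / (2.0 * delta)


@dataclass(frozen=True)
class GroupStats:
    """Summary statistics for one sex within a species/study/variable/season cell."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group sample size must be >= 2")
        if not self.sd > 0:
            raise ValueError("group SD must be positive")

    @classmethod
    def from_se(cls, n: int, mean: float, se: float) -> "GroupStats":
        return cls(n=n, mean=mean, sd=sd_from_se(se, n))

    @classmethod
    def from_ci(cls, n: int, mean: float, lower: float, upper: float) -> "GroupStats":
        return cls(n=n, mean=mean, sd=sd_from_ci(lower, upper, n))


@dataclass(frozen=True)
class EffectSize:
    """Hedges' *g* (male minus female) with its sampling variance and provenance."""

    g: float
    v: float
    species: str | None = None
    study: str | None = None
    variable: str | None = None
    season: str | None = None

    def __post_init__(self) -> None:
        if not self.v > 0:
            raise ValueError("sampling variance must be positive")

    @property
    def se(self) -> float:
        return math.sqrt(self.v)


def hedges_g(male: GroupStats, female: GroupStats, **labels: str | None) -> EffectSize:
    """Hedges' *g* for a male-versus-female contrast.

    Computes the standardised mean difference
    ``d = (mean_M - mean_F) / s_pooled`` with the degrees-of-freedom-weighted
    pooled SD, applies the small-sample correction
    ``J = 1 - 3 / (4 df - 1)`` with ``df = n_M + n_F - 2``, and returns
    ``g = J d`` together with its large-sample sampling variance
    ``v = J^2 [ (n_M + n_F) / (n_M n_F) + d^2 / (2 (n_M + n_F)) ]``.
    """
    n_m, n_f = male.n, female.n
    df = n_m + n_f - 2
    if df < 1:
        raise ValueError("pooled degrees of freedom must be >= 1")
    s2_pooled = ((n_m - 1) * male.sd**2 + (n_f - 1) * female.sd**2) / df
    if s2_pooled <= 0:
        raise ValueError("no within-group variance")
    d = (male.mean - female.mean) / math.sqrt(s2_pooled)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    ntot = n_m + n_f
    v = j**2 * (ntot / (n_m * n_f) + d**2 / (2.0 * ntot))
    return EffectSize(g=g, v=v, **labels)


def counts_to_proportions(counts: Sequence[float], total: float | None = None) -> np.ndarray:
    """Convert leukocyte counts per cell type into proportions of the total.

    ``total`` defaults to the sum of the counts; when supplied it must equal
    that sum (the proportions always sum to one).
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("cell counts must be non-negative")
    s = c.sum()
    if total is None:
        total = s
    if total <= 0:
        raise ValueError("total leukocyte count must be positive")
    if not math.isclose(s, float(total), rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("cell counts do not sum to the stated total")
    return c / float(total)


def hl_ratio(heterophils: float, lymphocytes: float) -> float:
    """Heterophil/lymphocyte ratio computed on the raw counts."""
    if lymphocytes == 0:
        raise ValueError("lymphocyte count is zero; H/L ratio undefined")
    return heterophils / lymphocytes


def _norm_sex(value: str) -> str | None:
    s = str(value).strip().lower()
    if s in _MALE_LABELS:
        return "male"
    if s in _FEMALE_LABELS:
        return "female"
    return None


def _row_group_stats(row: pd.Series) -> GroupStats:
    kind = str(row["dispersion"]).strip().lower()
    n = int(row["n"])
    mean = float(row["mean"])
    if kind == "sd":
        return GroupStats(n=n, mean=mean, sd=float(row["sd"]))
    if kind == "se":
        return GroupStats.from_se(n=n, mean=mean, se=float(row["se"]))
    if kind in ("ci95", "ci"):
        return GroupStats.from_ci(
            n=n, mean=mean, lower=float(row["ci_lower"]), upper=float(row["ci_upper"])
        )
    raise ValueError(f"unknown dispersion kind: {row['dispersion']!r}")


@dataclass
class BuildResult:
    """Outcome of :func:`build_effect_table`: the effects plus an exclusion log."""

    effects: list[EffectSize]
    excluded: pd.DataFrame

    def __iter__(self):
        return iter(self.effects)

    def __len__(self) -> int:
        return len(self.effects)


_CELL_KEY = ["species", "study", "variable", "season"]


def build_effect_table(study_table: pd.DataFrame) -> BuildResult:
    """Turn a per-sex study table into one Hedges' *g* per data cell.

    A *cell* is a species x study x variable x season combination; it
    yields an effect size only when both a male and a female row are
    present (single-sex cells are excluded with a logged reason, mirroring
    the inclusion criterion that both sexes must be reported).  Duplicated
    rows for the same cell and sex are an error.
    """
    required = set(_CELL_KEY + ["sex", "n", "mean", "dispersion"])
    missing = required - set(study_table.columns)
    if missing:
        raise ValueError(f"study table is missing columns: {sorted(missing)}")

    effects: list[EffectSize] = []
    excluded: list[dict] = []
    for key, cell in study_table.groupby(_CELL_KEY, sort=True):
        species, study, variable, season = (str(x) for x in key)
        by_sex: dict[str, pd.Series] = {}
        for _, row in cell.iterrows():
            sex = _norm_sex(row["sex"])
            if sex is None:
                raise ValueError(f"unrecognised sex label {row['sex']!r} in cell {key}")
            if sex in by_sex:
                raise ValueError(f"duplicated {sex} row for cell {key}")
            by_sex[sex] = row
        if len(by_sex) < 2:
            reason = f"single-sex cell ({next(iter(by_sex))} only)"
            log.info("excluding %s: %s", key, reason)
            excluded.append(
                dict(zip(_CELL_KEY, (species, study, variable, season))) | {"reason": reason}
            )
            continue
        effects.append(
            hedges_g(
                _row_group_stats(by_sex["male"]),
                _row_group_stats(by_sex["female"]),
                species=species,
                study=study,
                variable=variable,
                season=season,
            )
        )
    excl = pd.DataFrame(excluded, columns=_CELL_KEY + ["reason"])
    return BuildResult(effects=effects, excluded=excl)


def effects_to_frame(effects: Iterable[EffectSize]) -> pd.DataFrame:
    """Tabulate effect sizes (one row per effect, stable column order)."""
    rows = [
        {
            "species": e.species,
            "study": e.study,
            "variable": e.variable,
            "season": e.season,
            "g": e.g,
            "v": e.v,
            "se": e.se,
        }
        for e in effects
    ]
    return pd.DataFrame(rows, columns=["species", "study", "variable", "season", "g", "v", "se"])
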