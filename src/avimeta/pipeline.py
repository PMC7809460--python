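"""End-to-end orchestration: data -> effect sizes -> meta-models -> GLMMs.

``run_analysis`` reproduces the full analysis chain for a study table and
a phylogeny (a single tree or a sample to take a majority-rule consensus
of): per immune variable it fits the overall and by-season multilevel
meta-models, computes the omnibus season test, Cochran's Q and the I2
decomposition, runs the Egger asymmetry test and the influence screen
with refit, and then fits the MCMC mixed models (full data and the
both-season species subset) for the eligible variables.  Outputs are
three delimited report tables shaped like conventional meta-analysis
reporting plus a machine-readable run manifest.

The haemolysis (HL) and haemagglutination (HA) assays only carry
breeding-season data and are excluded from the season-moderated models
and the GLMMs, as is standard when one moderator level is unobserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .diagnostics import egger_test, flag_influential, funnel_data
from .effects import SEASONS, VARIABLES, build_effect_table, effects_to_frame
from .glmm import GlmmSpec, fit_glmm
from .meta import fit_multilevel, omnibus_qm, wald_z
from .phylo import (
    PhyloCorrelation,
    TreeSample,
    majority_consensus,
    read_tree_sample,
    resolve_polytomies,
    tree_to_correlation,
)
from .simulate import SimConfig, simulate_dataset

__all__ = ["AnalysisConfig", "ReportBundle", "load_dataset", "season_subset", "run_analysis"]

log = logging.getLogger(__name__)

#: Variables excluded from season-moderated models and GLMMs because only
#: breeding-season estimates exist.
SEASON_EXCLUDED = ("HL", "HA")

#: Family and transform per GLMM-eligible variable.
GLMM_FAMILIES = {
    "heterophils": ("binomial", None),
    "lymphocytes": ("binomial", None),
    "macrophages": ("binomial", None),
    "eosinophils": ("binomial", None),
    "BKA": ("binomial", None),
    "H/L": ("gaussian", "log"),
    "PHA": ("gaussian", None),
}

REQUIRED_COLUMNS = ("species", "study", "variable", "season", "sex", "n", "mean", "dispersion")
_NUMERIC_COLUMNS = ("n", "mean", "sd", "se", "ci_lower", "ci_upper", "count", "total")


def load_dataset(path: str | Path, schema: tuple[str, ...] = REQUIRED_COLUMNS):
    """Read and validate a study table; returns (table, exclusion log).

    Rows flagged as captive or experimentally manipulated (truthy values
    in optional ``captive`` / ``manipulated`` columns) are excluded with a
    reason, mirroring the free-living/unmanipulated inclusion criteria.
    Malformed numbers are a hard error naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=None, engine="python")
    missing = set(schema) - set(table.columns)
    if missing:
        raise ValueError(f"dataset is missing required columns: {sorted(missing)}")
    for col in _NUMERIC_COLUMNS:
        if col in table.columns:
            try:
                table[col] = pd.to_numeric(table[col])
            except (ValueError, TypeError) as exc:
                bad = table.index[pd.to_numeric(table[col], errors="coerce").isna()
                                  & table[col].notna()].tolist()
                raise ValueError(f"column {col!r} has malformed numbers in rows {bad}") from exc

    excluded = []
    keep = np.ones(len(table), dtype=bool)
    for flag, reason in (("captive", "captive birds"), ("manipulated", "experimental manipulation")):
        if flag in table.columns:
            mask = table[flag].fillna(0).astype(bool).to_numpy()
            for i in table.index[mask]:
                excluded.append({"row": int(i), "reason": reason})
            keep &= ~mask
    excl = pd.DataFrame(excluded, columns=["row", "reason"])
    if len(excl):
        log.info("excluded %d rows during loading", len(excl))
    return table[keep].reset_index(drop=True), excl


def season_subset(study_table: pd.DataFrame) -> pd.DataFrame:
    """Restrict to species that have data in both seasons."""
    if "season" not in study_table.columns:
        raise ValueError("season column required")
    seasons_per_species = study_table.groupby("species")["season"].agg(lambda s: frozenset(s))
    both = {sp for sp, s in seasons_per_species.items() if len(s & set(SEASONS)) == 2}
    out = study_table[study_table["species"].isin(both)].reset_index(drop=True)
    if out.empty:
        log.warning("season subset is empty: no species has data in both seasons")
    return out


@dataclass
class AnalysisConfig:
    """Inputs and knobs for one full analysis run."""

    dataset: str | None = None  # CSV path; None -> simulate
    tree: str | None = None  # Newick path (single or one tree per line)
    simulate: SimConfig | None = None
    seed: int = 0
    consensus_threshold: float = 0.5
    polytomy_epsilon: float = 1e-8
    run_glmms: bool = True
    chains: int = 3
    iterations: int = 6000
    burnin: int = 1000
    thin: int = 5


@dataclass
class ReportBundle:
    """Analysis outputs: shaped report tables, details, and a run manifest."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    details: dict
    manifest: dict
    effects: pd.DataFrame
    excluded: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table1.to_csv(outdir / "table1_sex_bias.csv", index=False)
        self.table2.to_csv(outdir / "table2_season_omnibus.csv", index=False)
        self.table3.to_csv(outdir / "table3_glmm.csv", index=False)
        self.effects.to_csv(outdir / "effect_sizes.csv", index=False)
        self.excluded.to_csv(outdir / "excluded_cells.csv", index=False)
        for var, d in self.details.items():
            if "funnel" in d:
                safe = var.replace("/", "_")
                d["funnel"].to_csv(outdir / f"funnel_{safe}.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)


def _variable_correlation(
    sample: TreeSample | None,
    tree: dendropy.Tree | None,
    species: list[str],
    config: AnalysisConfig,
) -> PhyloCorrelation:
    """Per-variable correlation: consensus over the pruned sample, or a pruned tree."""
    if sample is not None and len(sample) > 1:
        pruned = []
        for t in sample.trees:
            tc = t.clone(depth=1)
            tc.retain_taxa_with_labels(species)
            pruned.append(tc)
        cons = majority_consensus(TreeSample(trees=pruned), threshold=config.consensus_threshold)
        cons = resolve_polytomies(cons, epsilon=config.polytomy_epsilon, seed=config.seed)
        return tree_to_correlation(cons)
    return tree_to_correlation(tree).loc(sorted(species))


def _wald_cols(res) -> dict:
    return {
        "estimate": res.estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "z": res.z,
        "p": res.p,
    }


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full chain and emit report tables and a manifest."""
    # --- inputs --------------------------------------------------------
    sample = None
    tree = None
    if config.dataset is not None:
        table, load_excluded = load_dataset(config.dataset)
        if config.tree is None:
            raise ValueError("a tree file is required with an external dataset")
        sample = read_tree_sample(config.tree)
        if len(sample) == 1:
            tree = resolve_polytomies(
                sample.trees[0], epsilon=config.polytomy_epsilon, seed=config.seed
            )
            sample = None
    else:
        sim = config.simulate or SimConfig(seed=config.seed)
        dataset = simulate_dataset(sim)
        table, load_excluded = dataset.study_table, pd.DataFrame(columns=["row", "reason"])
        tree = dataset.tree

    built = build_effect_table(table)
    effects_frame = effects_to_frame(built.effects)
    variables = [v for v in VARIABLES if v in set(effects_frame["variable"])]

    details: dict = {}
    t1_rows, t2_rows, t3_rows = [], [], []

    # --- per-variable meta-analysis ------------------------------------
    for var in variables:
        effs = [e for e in built.effects if e.variable == var]
        species = sorted({e.species for e in effs})
        if len(effs) < 3 or len(species) < 2:
            log.warning("skipping %s: too few effects", var)
            continue
        corr = _variable_correlation(sample, tree, species, config)
        seasons_present = [s for s in SEASONS if s in {e.season for e in effs}]

        overall = fit_multilevel(effs, corr, moderator=None)
        row = {
            "variable": var,
            "k": overall.k,
            "n_species": len(species),
            "I2_phylogeny": overall.i2["phylogeny"],
            "I2_study": overall.i2["study"],
            "I2_total": overall.i2["total"],
            "Q": overall.q_resid.statistic,
            "Q_df": overall.q_resid.df,
            "Q_p": overall.q_resid.pvalue,
        }
        row.update({f"overall_{k}": v for k, v in _wald_cols(wald_z(overall, "overall")).items()})

        by_season = None
        if len(seasons_present) == 2:
            by_season = fit_multilevel(effs, corr, moderator="season")
            for season in SEASONS:
                res = wald_z(by_season, season)
                row.update({f"{season}_{k}": v for k, v in _wald_cols(res).items()})
        else:
            only = fit_multilevel(effs, corr, moderator="season")
            res = wald_z(only, seasons_present[0])
            row.update({f"{seasons_present[0]}_{k}": v for k, v in _wald_cols(res).items()})
            for season in set(SEASONS) - set(seasons_present):
                for k in ("estimate", "ci_low", "ci_high", "z", "p"):
                    row[f"{season}_{k}"] = np.nan
        t1_rows.append(row)

        if by_season is not None and var not in SEASON_EXCLUDED:
            qm = omnibus_qm(by_season)
            t2_rows.append(
                {"variable": var, "QM": qm.qm, "df": qm.df, "p": qm.pvalue}
            )

        det: dict = {"overall": overall, "by_season": by_season}
        try:
            egger = egger_test(effs, corr)
            det["egger"] = egger
        except ValueError as exc:
            log.warning("Egger test unavailable for %s: %s", var, exc)
            det["egger"] = None
        det["funnel"] = funnel_data(effs, overall)
        try:
            det["influence"] = flag_influential(effs, corr)
        except ValueError as exc:
            log.warning("influence screen unavailable for %s: %s", var, exc)
            det["influence"] = None
        details[var] = det

    # --- GLMMs ----------------------------------------------------------
    if config.run_glmms:
        subset = season_subset(table)
        for var in variables:
            if var not in GLMM_FAMILIES:
                continue
            family, transform = GLMM_FAMILIES[var]
            for label, data in (("full", table), ("both-season subset", subset)):
                rows = data[data["variable"] == var].reset_index(drop=True)
                if len(rows) < 8 or rows["season"].nunique() < 2:
                    continue
                rows = _prepare_glmm_rows(rows, family)
                species = sorted(set(rows["species"]))
                corr = _variable_correlation(sample, tree, species, config)
                spec = GlmmSpec(
                    response=var,
                    family=family,
                    transform=transform,
                    chains=config.chains,
                    iterations=config.iterations,
                    burnin=config.burnin,
                    thin=config.thin,
                    seed=config.seed,
                )
                fit = fit_glmm(rows, spec, corr)
                summ = fit.summary()
                summ.insert(0, "dataset", label)
                summ.insert(0, "variable", var)
                t3_rows.append(summ)
                details.setdefault(var, {})[f"glmm_{label}"] = fit

    table1 = pd.DataFrame(t1_rows)
    table2 = pd.DataFrame(t2_rows, columns=["variable", "QM", "df", "p"])
    table3 = (
        pd.concat(t3_rows, ignore_index=True)
        if t3_rows
        else pd.DataFrame(columns=["variable", "dataset", "term", "post_mean", "lower", "upper", "pMCMC", "rhat"])
    )

    sim_cfg = None
    if config.dataset is None:
        sim_cfg = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config.simulate or SimConfig(seed=config.seed)).items()}
    manifest = {
        "package": "avimeta",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "simulate"},
        "simulate": sim_cfg,
        "n_effects": int(len(effects_frame)),
        "variables": variables,
        "versions": _library_versions(),
    }
    return ReportBundle(
        table1=table1,
        table2=table2,
        table3=table3,
        details=details,
        manifest=manifest,
        effects=effects_frame,
        excluded=pd.concat(
            [built.excluded.assign(stage="effects"),
             load_excluded.assign(stage="loading")],
            ignore_index=True,
        ),
    )


def _prepare_glmm_rows(rows: pd.DataFrame, family: str) -> pd.DataFrame:
    """Ensure binomial rows carry counts; fall back to group n as denominator."""
    rows = rows.copy()
    if family == "binomial":
        if "count" not in rows.columns or rows["count"].isna().any():
            log.warning(
                "no leukocyte counts available; using group n as binomial denominator"
            )
            rows["total"] = rows["n"].astype(float)
            rows["count"] = np.rint(rows["mean"].clip(0, 1) * rows["n"]).astype(float)
        rows["count"] = np.rint(rows["count"]).astype(float)
        rows["total"] = np.rint(rows["total"]).astype(float)
    return rows


def _library_versions() -> dict[str, str]:
    import dendropy as _dendropy
    import numpy as _np
    import pandas as _pd
    import scipy as _scipy

    return {
        "numpy": _np.__version__,
        "scipy": _scipy.__version__,
        "pandas": _pd.__version__,
        "dendropy": _dendropy.__version__,
    }
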