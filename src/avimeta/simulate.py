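"""Synthetic study-level immunology datasets with known ground truth.

The generator emulates the structure of a comparative dataset on sex
differences in avian immune measures: roughly 41 wild bird species from
about 24 families measured in about 24 studies, nine immune variables
(four white-blood-cell proportions, the H/L ratio, PHA, BKA, haemolysis
and haemagglutination), two seasons, phylogenetically correlated species
effects, study effects, and per-sex group summaries (n, mean, SD) plus
aggregated leukocyte counts for binomial modelling.  All effects that
generate the male-female contrast are known, so every downstream stage
(effect sizes, REML meta-analysis, MCMC mixed models) can be tested by
parameter recovery.

Measurement scales are arbitrary but internally consistent; no attempt is
made to match real avian leukocyte reference ranges.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .effects import SEASONS, VARIABLES
from .phylo import tree_to_correlation, write_tree

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_dataset",
    "CELL_TYPES",
    "GAUSSIAN_VARIABLES",
    "COUNT_VARIABLES",
]

#: Leukocyte cell types used for the multinomial white-blood-cell panel.
CELL_TYPES = ("heterophils", "lymphocytes", "macrophages", "eosinophils", "other")

#: Baseline expected proportions of the five cell types (softmax scale).
_BASE_WBC_PROPS = np.array([0.45, 0.40, 0.06, 0.05, 0.04])

#: Variables generated on a continuous (Gaussian) measurement scale, where
#: the configured sex bias is exactly the true Hedges' g.
GAUSSIAN_VARIABLES = ("PHA", "HL", "HA")

#: Variables generated from counts; the configured sex bias acts on the
#: logit scale (log odds for BKA, per-cell-type log odds for the WBC panel).
COUNT_VARIABLES = ("heterophils", "lymphocytes", "macrophages", "eosinophils", "BKA")

#: Variables only observed during the breeding season (mirrors the data
#: situation for the haemolysis and haemagglutination assays).
BREEDING_ONLY = ("HL", "HA")

_WBC_PANEL = ("heterophils", "lymphocytes", "macrophages", "eosinophils", "H/L")

STUDY_TABLE_COLUMNS = (
    "species",
    "family",
    "study",
    "variable",
    "season",
    "sex",
    "n",
    "mean",
    "sd",
    "dispersion",
    "count",
    "total",
)


@dataclass
class SimConfig:
    """Conditions for one simulated comparative dataset.

    ``sex_bias_by_season`` maps variable -> {season -> bias}; biases are in
    Hedges' g units for Gaussian-scale variables and in logit units for
    count-type variables.  ``sigma2_phylo`` and ``sigma2_study`` are the
    variances of the phylogenetically correlated species effects and the
    i.i.d. study effects on the male-female contrast (same scale as the
    bias).  Group sizes are Poisson around ``mean_group_n`` (floored at 2).
    """

    n_species: int = 41
    n_families: int = 24
    n_studies: int = 24
    seasons: tuple[str, ...] = SEASONS
    variables: tuple[str, ...] = VARIABLES
    cells_per_variable: int = 30
    sex_bias_by_season: dict = field(default_factory=dict)
    sigma2_phylo: float = 0.2
    sigma2_study: float = 0.2
    mean_group_n: int = 15
    total_wbc_count: int = 100
    bka_trials: int = 100
    baseline_mean: float = 10.0
    group_sd_scale: float = 1.0
    group_sd_log_sigma: float = 0.2
    overdispersion_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.mean_group_n < 2:
            raise ValueError("mean_group_n must be >= 2")
        if self.sigma2_phylo < 0 or self.sigma2_study < 0:
            raise ValueError("variance components must be >= 0")
        unknown = set(self.variables) - set(VARIABLES)
        if unknown:
            raise ValueError(f"unsupported immune variables: {sorted(unknown)}")
        unknown_seasons = set(self.seasons) - set(SEASONS)
        if unknown_seasons:
            raise ValueError(f"unsupported seasons: {sorted(unknown_seasons)}")
        for var, per_season in self.sex_bias_by_season.items():
            if var not in VARIABLES:
                raise ValueError(f"sex bias given for unsupported variable {var!r}")
            for season in per_season:
                if season not in SEASONS:
                    raise ValueError(f"sex bias given for unsupported season {season!r}")

    def bias(self, variable: str, season: str) -> float:
        return float(self.sex_bias_by_season.get(variable, {}).get(season, 0.0))


@dataclass
class SimulatedDataset:
    """A simulated study table plus the tree and parameters that made it."""

    study_table: pd.DataFrame
    true_params: dict
    tree: dendropy.Tree

    def write(self, outdir: str | Path) -> None:
        """Write study_table.csv, tree.nwk and true_params.yaml."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.study_table.to_csv(outdir / "study_table.csv", index=False)
        write_tree(self.tree, str(outdir / "tree.nwk"))
        with open(outdir / "true_params.yaml", "w") as fh:
            yaml.safe_dump(self.true_params, fh, sort_keys=True)


def simulate_tree(n_species: int, seed: int | None = None) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) ultrametric tree scaled to depth one.

    Tip labels are ``sp001``, ``sp002``, ... and are unique; the same seed
    always yields the same tree.
    """
    if n_species < 2:
        raise ValueError("degenerate tree: need at least two species")
    if n_species == 2:
        tree = dendropy.Tree.get(data="(sp001:1.0,sp002:1.0);", schema="newick")
        tree.is_rooted = True
        return tree
    from dendropy.simulate import treesim

    rng = random.Random(None if seed is None else int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
    )
    tree.is_rooted = True
    tree.seed_node.edge.length = None
    # The simulation stops at the n-th speciation, which leaves zero-length
    # pendant edges; extend every tip edge by one extra exponential waiting
    # time (rate n * birth_rate) so sister tips are never perfectly
    # correlated, then rescale.
    extra = rng.expovariate(n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    depth = 0.0
    node = next(tree.leaf_node_iter())
    while node.parent_node is not None:
        depth += node.edge.length or 0.0
        node = node.parent_node
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    for i, leaf in enumerate(sorted(tree.leaf_node_iter(), key=lambda x: x.taxon.label)):
        leaf.taxon.label = f"sp{i + 1:03d}"
    return tree


def _assign_families(species: list[str], n_families: int) -> dict[str, str]:
    """Chunk the species list into contiguous groups used as family labels."""
    n_families = max(1, min(n_families, len(species)))
    bounds = np.linspace(0, len(species), n_families + 1).round().astype(int)
    fams: dict[str, str] = {}
    for f in range(n_families):
        for sp in species[bounds[f] : bounds[f + 1]]:
            fams[sp] = f"fam{f + 1:02d}"
    return fams


def _draw_cells(rng: np.random.Generator, species, studies, seasons, k: int):
    """Sample k distinct (species, study, season) cells."""
    grid = [(sp, st, se) for sp in species for st in studies for se in seasons]
    k = min(k, len(grid))
    idx = rng.choice(len(grid), size=k, replace=False)
    return [grid[i] for i in sorted(idx)]


def _group_n(rng: np.random.Generator, mean_n: int) -> int:
    return max(2, int(rng.poisson(mean_n)))


def simulate_dataset(config: SimConfig, tree: dendropy.Tree | None = None) -> SimulatedDataset:
    """Simulate a per-sex study table under known sex-bias effects.

    The latent male-female contrast for a cell of variable ``v`` in season
    ``s`` is ``theta = bias(v, s) + a_species + b_study`` with species
    effects drawn from N(0, sigma2_phylo * A) (A the Brownian correlation
    of the tree) and study effects i.i.d. N(0, sigma2_study).  The same
    species/study effects (drawn separately per variable) are also added
    to the *level* of the trait for both sexes, so mixed models of the raw
    data have non-trivial random intercepts to recover.

    Gaussian-scale variables record sample means and SDs of simulated
    individuals; WBC variables are multinomial counts over cell types
    converted to per-individual proportions (with the H/L ratio taken from
    the raw heterophil and lymphocyte counts); BKA is binomial.  Counts
    are aggregated per cell and sex into ``count``/``total`` columns.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_tree, ss_effects, ss_cells, ss_noise = root.spawn(4)

    if tree is None:
        tree_seed = int(ss_tree.generate_state(1)[0] % (2**31))
        tree = simulate_tree(config.n_species, seed=tree_seed)
    species = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    corr = tree_to_correlation(tree)
    missing = set(species) - set(corr.labels)
    if missing:
        raise ValueError(f"species missing from tree: {sorted(missing)}")
    A = corr.loc(species).matrix
    L = np.linalg.cholesky(A + 1e-10 * np.eye(len(species)))

    studies = [f"study{i + 1:02d}" for i in range(config.n_studies)]
    families = _assign_families(species, config.n_families)

    rng_eff = np.random.default_rng(ss_effects)
    rng_cells = np.random.default_rng(ss_cells)
    rng = np.random.default_rng(ss_noise)

    # Per-variable species effects (phylogenetically correlated) and study
    # effects, separately for the contrast (male - female) and the level.
    contrast_sp: dict[str, dict[str, float]] = {}
    contrast_st: dict[str, dict[str, float]] = {}
    level_sp: dict[str, dict[str, float]] = {}
    level_st: dict[str, dict[str, float]] = {}
    for var in VARIABLES:
        a = math.sqrt(config.sigma2_phylo) * (L @ rng_eff.standard_normal(len(species)))
        b = math.sqrt(config.sigma2_study) * rng_eff.standard_normal(len(studies))
        la = math.sqrt(config.sigma2_phylo) * (L @ rng_eff.standard_normal(len(species)))
        lb = math.sqrt(config.sigma2_study) * rng_eff.standard_normal(len(studies))
        contrast_sp[var] = dict(zip(species, a))
        contrast_st[var] = dict(zip(studies, b))
        level_sp[var] = dict(zip(species, la))
        level_st[var] = dict(zip(studies, lb))

    def theta(var: str, sp: str, st: str, season: str) -> float:
        return config.bias(var, season) + contrast_sp[var][sp] + contrast_st[var][st]

    def level(var: str, sp: str, st: str) -> float:
        return level_sp[var][sp] + level_st[var][st]

    rows: list[dict] = []

    def add_row(sp, st, var, season, sex, n, mean, sd, count=np.nan, total=np.nan):
        rows.append(
            {
                "species": sp,
                "family": families[sp],
                "study": st,
                "variable": var,
                "season": season,
                "sex": sex,
                "n": int(n),
                "mean": float(mean),
                "sd": float(max(sd, 1e-6)),
                "dispersion": "sd",
                "count": count,
                "total": total,
            }
        )

    requested = set(config.variables)

    # --- Gaussian-scale variables -------------------------------------
    for var in GAUSSIAN_VARIABLES:
        if var not in requested:
            continue
        seasons = ("breeding",) if var in BREEDING_ONLY else config.seasons
        cells = _draw_cells(rng_cells, species, studies, seasons, config.cells_per_variable)
        for sp, st, season in cells:
            sig = max(
                rng.lognormal(math.log(config.group_sd_scale), config.group_sd_log_sigma),
                1e-6,
            )
            mu_f = config.baseline_mean + level(var, sp, st) * sig
            mu_m = mu_f + theta(var, sp, st, season) * sig
            for sex, mu in (("female", mu_f), ("male", mu_m)):
                n = _group_n(rng, config.mean_group_n)
                x = rng.normal(mu, sig, size=n)
                add_row(sp, st, var, season, sex, n, x.mean(), x.std(ddof=1))

    # --- BKA: binomial proportion killed ------------------------------
    if "BKA" in requested:
        cells = _draw_cells(rng_cells, species, studies, config.seasons, config.cells_per_variable)
        for sp, st, season in cells:
            base = level("BKA", sp, st)  # logit of the female kill probability
            for sex in ("female", "male"):
                eta0 = base + (theta("BKA", sp, st, season) if sex == "male" else 0.0)
                n = _group_n(rng, config.mean_group_n)
                eta = eta0 + rng.normal(0.0, config.overdispersion_sd, size=n)
                killed = rng.binomial(config.bka_trials, _expit(eta))
                props = killed / config.bka_trials
                add_row(
                    sp, st, "BKA", season, sex, n, props.mean(), props.std(ddof=1),
                    count=float(killed.sum()), total=float(n * config.bka_trials),
                )

    # --- WBC panel: multinomial counts over cell types -----------------
    wbc_requested = [v for v in _WBC_PANEL if v in requested]
    if wbc_requested:
        base_logits = np.log(_BASE_WBC_PROPS)
        cells = _draw_cells(rng_cells, species, studies, config.seasons, config.cells_per_variable)
        for sp, st, season in cells:
            for sex in ("female", "male"):
                logits = base_logits.copy()
                for j, cell_type in enumerate(CELL_TYPES[:4]):
                    logits[j] += level(cell_type, sp, st)
                    if sex == "male":
                        logits[j] += theta(cell_type, sp, st, season)
                n = _group_n(rng, config.mean_group_n)
                noise = rng.normal(0.0, config.overdispersion_sd, size=(n, len(CELL_TYPES)))
                p = _softmax(logits[None, :] + noise)
                counts = np.vstack(
                    [rng.multinomial(config.total_wbc_count, p[i]) for i in range(n)]
                )
                props = counts / config.total_wbc_count
                for j, cell_type in enumerate(CELL_TYPES[:4]):
                    if cell_type not in wbc_requested:
                        continue
                    add_row(
                        sp, st, cell_type, season, sex, n,
                        props[:, j].mean(), props[:, j].std(ddof=1),
                        count=float(counts[:, j].sum()),
                        total=float(n * config.total_wbc_count),
                    )
                if "H/L" in wbc_requested:
                    ratio = counts[:, 0] / np.maximum(counts[:, 1], 1)
                    add_row(sp, st, "H/L", season, sex, n, ratio.mean(), ratio.std(ddof=1))

    table = pd.DataFrame(rows, columns=list(STUDY_TABLE_COLUMNS))
    table = table.sort_values(
        ["variable", "species", "study", "season", "sex"], kind="mergesort"
    ).reset_index(drop=True)

    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
    }
    true_params = {
        "config": cfg_dict,
        "species": species,
        "studies": studies,
        "contrast_species_effects": {v: {k: float(x) for k, x in d.items()} for v, d in contrast_sp.items()},
        "contrast_study_effects": {v: {k: float(x) for k, x in d.items()} for v, d in contrast_st.items()},
    }
    return SimulatedDataset(study_table=table, true_params=true_params, tree=tree)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)
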