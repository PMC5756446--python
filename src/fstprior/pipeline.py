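"""End-to-end experiment orchestration.

One replicate = simulate a population, score G3 tails with F_ST, preselect
SNP panels at the configured quantiles, fit the regression models on a
random G3 training set, predict GEBVs for a random G4 validation set, and
evaluate accuracy and QTL tagging. A scenario grid crosses effect
distributions, F_ST quantiles and the comparison models (BayesB / BayesC
over a pi grid); all cells of one replicate share the same simulated data,
so method comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .evaluate import genomic_accuracy, phenotype_accuracy, tag_qtl
from .fst import fst_scores, select_by_quantile
from .gwr import WholeGenomeRegressor
from .popsim import SimConfig, SimResult, run_simulation

__all__ = ["ScenarioGrid", "run_replicate", "run_experiment", "percentage_differences"]


@dataclass
class ScenarioGrid:
    """The experiment grid and sampling sizes.

    Defaults follow the study layout: F_ST quantiles 97.5/99/99.5 %,
    BayesB and BayesC with prior exclusion probabilities
    {0.90, 0.95, 0.98, 0.99}, five replicates, and an all-SNP baseline fit
    of the proposed model.
    """

    quantiles: tuple = (0.975, 0.99, 0.995)
    models: tuple = ("fst_preselect", "bayesB", "bayesC")
    pi_zeros: tuple = (0.90, 0.95, 0.98, 0.99)
    effect_dists: tuple = ("gamma",)
    n_replicates: int = 5
    n_train: int = 10_000
    n_valid: int = 5_000
    fst_group_size: int | None = 1_500
    tail: float = 0.05
    include_all_snp: bool = True
    chain_length: int = 3_000
    burn_in: int = 500
    thin: int = 5
    master_seed: int = 0
    tag_threshold: float = 0.7

    def validate(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not self.models:
            raise ValueError("empty model grid")
        for q in self.quantiles:
            if not 0.0 < q < 1.0:
                raise ValueError("quantiles must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _training_split(sim: SimResult, grid: ScenarioGrid, rng: np.random.Generator):
    pop = sim.population
    g_train = min(3, sim.config.n_select_generations)
    g_valid = sim.config.n_select_generations
    g3 = pop.ids_of_generation(g_train)
    g4 = pop.ids_of_generation(g_valid)
    n_train = min(grid.n_train, g3.size)
    n_valid = min(grid.n_valid, g4.size)
    train = np.sort(rng.choice(g3, size=n_train, replace=False))
    valid = np.sort(rng.choice(g4, size=n_valid, replace=False))
    return g3, train, valid


def run_replicate(
    sim: SimResult, grid: ScenarioGrid, seed: int, replicate: int = 0
) -> list[dict]:
    """Analyze one simulated data set over every grid cell.

    Returns one dict per cell with accuracy, tagging and bookkeeping
    columns. ``seed`` drives the training/validation draw and the chains.
    """
    grid.validate()
    rng = np.random.default_rng(seed)
    pop, trait, genome = sim.population, sim.trait, sim.genome
    g3, train, valid = _training_split(sim, grid, rng)

    X3_all = pop.dosages(sim.marker_panel, g3).astype(float)
    X_train = pop.dosages(sim.marker_panel, train).astype(float)
    X_valid = pop.dosages(sim.marker_panel, valid).astype(float)
    Q_train = pop.dosages(trait.qtl_locus_index, train).astype(float)
    y3 = trait.phenotype[g3]
    y_train = trait.phenotype[train]
    y_valid = trait.phenotype[valid]
    tbv_valid = trait.tbv[valid]

    group = grid.fst_group_size
    if group is not None and group > int(2 * grid.tail * g3.size):
        group = None  # fall back to quantile tails when the population is small
    scores, split, p1, p2 = fst_scores(X3_all, y3, grid.tail, 1.0 - grid.tail, group)

    chain = dict(chain_length=grid.chain_length, burn_in=grid.burn_in, thin=grid.thin,
                 scale_g=sim.config.sigma2_g, scale_e=sim.config.sigma2_e)
    rows: list[dict] = []

    def evaluate_fit(est, design_cols, label, param):
        gebv = est.predict_gebv(X_valid[:, design_cols])
        tags = tag_qtl(Q_train, X_train[:, design_cols][:, _tag_subset(est, design_cols)],
                       trait.qtl_effects, grid.tag_threshold)
        rows.append({
            "replicate": replicate,
            "effect_dist": sim.config.qtl_effect_dist,
            "model": label,
            "param": param,
            "n_selected": int(_tag_subset(est, design_cols).sum()),
            "n_tagged_qtl": tags["n_tagged"],
            "gv_explained_pct": tags["gv_explained_pct"],
            "acc_g": genomic_accuracy(tbv_valid, gebv),
            "acc_p": phenotype_accuracy(gebv, y_valid, est.mu_hat_),
        })

    def _tag_subset(est, design_cols):
        """Which design SNPs count as 'selected' for tagging."""
        m = len(design_cols)
        if est.model == "fst_preselect":
            return np.ones(m, dtype=bool)
        k = max(1, int(round((1.0 - est.pi_zero) * m)))
        cut = np.argsort(est.include_prob_)[::-1][:k]
        mask = np.zeros(m, dtype=bool)
        mask[cut] = True
        return mask

    child = np.random.SeedSequence(seed).spawn(1 + len(grid.quantiles) + 2 * len(grid.pi_zeros))
    chain_seeds = iter(int(c.generate_state(1)[0] % (2**31 - 1)) for c in child)

    if "fst_preselect" in grid.models:
        if grid.include_all_snp:
            est = WholeGenomeRegressor(model="fst_preselect", random_state=next(chain_seeds), **chain)
            est.fit(X_train, y_train)
            evaluate_fit(est, np.arange(X_train.shape[1]), "fst_preselect", "all_snp")
        for q in grid.quantiles:
            res = select_by_quantile(scores, q)
            cols = res.selected
            est = WholeGenomeRegressor(model="fst_preselect", random_state=next(chain_seeds), **chain)
            est.fit(X_train[:, cols], y_train)
            evaluate_fit(est, cols, "fst_preselect", f"q{q}")
    for model in ("bayesB", "bayesC"):
        if model not in grid.models:
            continue
        for pz in grid.pi_zeros:
            est = WholeGenomeRegressor(model=model, pi_zero=pz,
                                       random_state=next(chain_seeds), **chain)
            est.fit(X_train, y_train)
            evaluate_fit(est, np.arange(X_train.shape[1]), model, f"pi{pz}")
    return rows


def run_experiment(grid: ScenarioGrid, base_config: SimConfig) -> pd.DataFrame:
    """Full grid x replicate experiment; returns one row per cell."""
    grid.validate()
    base_config.validate()
    ss = np.random.SeedSequence(grid.master_seed)
    all_rows: list[dict] = []
    for dist in grid.effect_dists:
        for rep in range(grid.n_replicates):
            sim_seed, ana_seed = (
                int(s.generate_state(1)[0] % (2**31 - 1))
                for s in ss.spawn(2)
            )
            cfg = SimConfig(**{**base_config.to_dict(), "qtl_effect_dist": dist, "seed": sim_seed})
            sim = run_simulation(cfg)
            try:
                all_rows.extend(run_replicate(sim, grid, ana_seed, replicate=rep))
            except Exception as exc:  # a failed cell aborts only its replicate
                all_rows.append({
                    "replicate": rep, "effect_dist": dist, "model": "ERROR",
                    "param": repr(exc), "n_selected": 0, "n_tagged_qtl": 0,
                    "gv_explained_pct": float("nan"),
                    "acc_g": float("nan"), "acc_p": float("nan"),
                })
    return pd.DataFrame(all_rows)


def aggregate(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error over replicates per grid cell."""
    num = ["n_selected", "n_tagged_qtl", "gv_explained_pct", "acc_g", "acc_p"]
    g = results[results["model"] != "ERROR"].groupby(
        ["effect_dist", "model", "param"], sort=False
    )
    agg = g[num].agg(["mean", "sem"])
    agg.columns = [f"{a}_{b}" for a, b in agg.columns]
    agg["n_replicates"] = g.size()
    return agg.reset_index()


def percentage_differences(results: pd.DataFrame) -> pd.DataFrame:
    """Best-cell comparison of BayesB/BayesC against the proposed method.

    Positive values mean the competitor is better; the study's convention is
    100 * (other - proposed) / proposed on the best accuracy per method.
    """
    agg = aggregate(results)
    out = []
    for dist, sub in agg.groupby("effect_dist"):
        prop = sub[(sub["model"] == "fst_preselect") & (sub["param"] != "all_snp")]
        if prop.empty:
            continue
        best_prop_g = prop["acc_g_mean"].max()
        best_prop_p = prop["acc_p_mean"].max()
        for model in ("bayesB", "bayesC"):
            other = sub[sub["model"] == model]
            if other.empty:
                continue
            out.append({
                "effect_dist": dist,
                "model": model,
                "diff_acc_g_pct": 100.0 * (other["acc_g_mean"].max() - best_prop_g) / best_prop_g,
                "diff_acc_p_pct": 100.0 * (other["acc_p_mean"].max() - best_prop_p) / best_prop_p,
            })
    return pd.DataFrame(out)
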