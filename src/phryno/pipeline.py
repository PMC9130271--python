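"""End-to-end orchestration: regime inference, map-averaged OU fits,
energetics, regressions, and convergence/covariation tests, with per-stage
logging and a reproducibility manifest.

The full analysis runs from an :class:`AnalysisConfig`; a one-command
synthetic demo wires the generator's defaults straight into the pipeline.
Canonical settings are 500 stochastic maps, 500 bootstrap replicates and
10^6 MCMC generations; the ``desk`` profile scales these to (100, 200,
2x10^5) so a complete run fits comfortably on a laptop.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import coevolution, ecophys, mk, ou, simulate, stats
from .regimes import write_simmap
from .tree import PhyloTree, read_tree

logger = logging.getLogger("phryno")

__all__ = ["AnalysisConfig", "run_full", "robustness_over_trees", "run_synthetic_demo"]

THERMAL_TRAITS = ("Tb", "Tpref", "CTmin", "CTmax")
LOG10_TRAITS = ("log10_SVL", "log10_offspring_mass", "log10_offspring_size",
                "log10_clutch_size")


@dataclass
class AnalysisConfig:
    out_dir: str = "phryno_out"
    tree_path: str | None = None               # None -> synthetic demo
    traits_path: str | None = None
    obs_path: str | None = None
    seed: int = 0
    n_maps: int = 500
    n_boot: int = 500
    mcmc_generations: int = 1_000_000
    mcmc_thin: int = 100
    mcmc_burnin: int = 200_000
    mk_model: str = "ER"                       # regime painting model
    ou_models: tuple = ("BM1", "OU1", "OUM")
    ou_traits: tuple = THERMAL_TRAITS + ("B", "Pr")
    parity_column: str = "parity"
    derived_state: str = "viviparous"
    climate_columns: tuple = ("bio1", "bio10", "bio11")
    stages: tuple = ("mk", "maps", "ou", "ecophys", "pgls", "anova",
                     "threshold", "wheatsheaf", "slouch")
    synth: simulate.SynthConfig | None = None

    @classmethod
    def desk(cls, **kw) -> "AnalysisConfig":
        """Laptop-scale profile: fewer maps/bootstraps/generations."""
        kw.setdefault("n_maps", 100)
        kw.setdefault("n_boot", 200)
        kw.setdefault("mcmc_generations", 200_000)
        kw.setdefault("mcmc_burnin", 40_000)
        return cls(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_inputs(cfg: AnalysisConfig):
    if cfg.tree_path is None:
        synth = cfg.synth or simulate.SynthConfig(seed=cfg.seed)
        ds = simulate.generate_study_dataset(synth)
        return ds.tree, ds.traits, ds.observations, {"synthetic": True,
                                                     "synth_seed": synth.seed}
    tree = read_tree(cfg.tree_path)
    traits = pd.read_csv(cfg.traits_path, index_col="species")
    obs = pd.read_csv(cfg.obs_path) if cfg.obs_path else None
    prov = {"synthetic": False,
            "tree_sha256": _sha256(Path(cfg.tree_path)),
            "traits_sha256": _sha256(Path(cfg.traits_path))}
    return tree, traits, obs, prov


def run_full(cfg: AnalysisConfig) -> dict:
    """Execute every configured stage; write tidy CSVs, a JSON summary and a
    run manifest into ``cfg.out_dir``. Returns the in-memory report."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    tree, traits, obs, provenance = _load_inputs(cfg)
    report["provenance"] = provenance
    parity = traits[cfg.parity_column].dropna()
    keep = [l for l in tree.tip_labels if l in set(parity.index)]
    if len(keep) < tree.n_tips:
        tree = tree.prune_to(keep)
    rng = np.random.default_rng(cfg.seed)

    def stage(name):
        enabled = name in cfg.stages
        if enabled:
            logger.info("stage %s", name)
        return enabled

    def record(name, started, **extra):
        report["stages"][name] = {"wall_s": round(time.time() - started, 3), **extra}

    mapset = None
    try:
        if stage("mk"):
            ts = time.time()
            cmp_df = mk.compare_mk(tree, parity)
            cmp_df.to_csv(out / "mk_model_comparison.csv")
            record("mk", ts, table=str(out / "mk_model_comparison.csv"))
            report["mk_weights"] = cmp_df["weight"].to_dict()

        if stage("maps"):
            ts = time.time()
            fit = mk.fit_mk(tree, parity, cfg.mk_model)
            mapset = mk.stochastic_maps(tree, parity, fit, cfg.n_maps,
                                        int(rng.integers(2 ** 31)))
            origins = mk.count_origins(mapset, cfg.derived_state)
            write_simmap(mapset.maps, out / "parity_maps.simmap.nwk")
            record("maps", ts, n_maps=cfg.n_maps)
            report["origins"] = origins.summary().to_dict()

        if stage("ou") and mapset is not None:
            ts = time.time()
            all_rows = []
            summaries = {}
            for trait in cfg.ou_traits:
                if trait not in traits:
                    continue
                col = traits[trait]
                res = ou.fit_over_maps(mapset, col, cfg.ou_models, trait_name=trait)
                rec = res.records.copy()
                rec.insert(0, "trait", trait)
                all_rows.append(rec)
                summ = res.theta_summary("OUM")
                summaries[trait] = {
                    "theta_mean": summ["mean"].to_dict(),
                    "best_model_freq": res.model_support().to_dict(),
                    "n_excluded": res.n_excluded,
                }
            if all_rows:
                pd.concat(all_rows).to_csv(out / "ou_fits.csv", index=False)
            record("ou", ts)
            report["ou"] = summaries

        if stage("ecophys"):
            ts = time.time()
            energetics = ecophys.species_energetics(traits, obs)
            energetics.to_csv(out / "energetics.csv")
            if "E" in energetics:
                report["E_mean_by_parity"] = (
                    energetics.groupby(cfg.parity_column)["E"].mean().to_dict())
            record("ecophys", ts)

        if stage("pgls"):
            ts = time.time()
            pgls_out = {}
            if {"log10_clutch_size", "log10_SVL"} <= set(traits.columns):
                r = stats.pgls(tree, traits, "log10_clutch_size", "log10_SVL")
                pgls_out["clutch_vs_svl"] = {"slope": r.slope,
                                             "intercept": r.intercept,
                                             "p": float(r.pvalues.iloc[-1]),
                                             "n": r.n}
            if {"Tb", "bio1", cfg.parity_column} <= set(traits.columns):
                by = stats.pgls(tree, traits, "Tb", "bio1", by=cfg.parity_column)
                pgls_out["tb_vs_bio1_by_parity"] = {
                    g: {"slope": f.slope, "p": float(f.pvalues.iloc[-1]), "n": f.n}
                    for g, f in by.items()}
            record("pgls", ts)
            report["pgls"] = pgls_out

        if stage("anova"):
            ts = time.time()
            energetics = ecophys.species_energetics(traits, obs)
            if "E" in energetics:
                res = stats.phyl_anova(tree, parity, energetics["E"],
                                       n_sim=min(cfg.n_boot, 500),
                                       seed=int(rng.integers(2 ** 31)))
                report["phyl_anova_E"] = {"F": res.F, "p": res.pvalue}
            record("anova", ts)

        if stage("threshold"):
            ts = time.time()
            thr = {}
            for col in cfg.climate_columns:
                if col not in traits:
                    continue
                chain = coevolution.threshold_mcmc(
                    tree, parity, traits[col], cfg.mcmc_generations,
                    cfg.mcmc_thin, cfg.mcmc_burnin,
                    seed=int(rng.integers(2 ** 31)))
                lo, hi = chain.r_interval()
                thr[col] = {"r_mean": chain.r_mean, "r_2.5%": lo, "r_97.5%": hi,
                            "ess": chain.ess_r, "low_ess": chain.low_ess}
            record("threshold", ts)
            report["threshold"] = thr

        if stage("wheatsheaf"):
            ts = time.time()
            focal = parity[parity == cfg.derived_state].index.tolist()
            ws = {}
            for trait in THERMAL_TRAITS:
                if trait not in traits:
                    continue
                try:
                    res = coevolution.wheatsheaf(tree, traits[[trait]], focal,
                                                 n_boot=cfg.n_boot,
                                                 seed=int(rng.integers(2 ** 31)))
                except ValueError:
                    continue
                ws[trait] = {"w": res.w, "p": res.pvalue}
            record("wheatsheaf", ts)
            report["wheatsheaf"] = ws

        if stage("slouch"):
            ts = time.time()
            sl = {}
            for trait in THERMAL_TRAITS:
                if trait not in traits or "bio1" not in traits:
                    continue
                fit = stats.slouch_fit(tree, traits[trait], traits["bio1"],
                                       n_grid=20)
                sl[trait] = {"t_half": fit.best_t_half,
                             "alpha": fit.best_alpha,
                             "evolutionary_slope": fit.evolutionary_slope,
                             "optimal_slope": fit.optimal_slope}
            record("slouch", ts)
            report["slouch"] = sl
    except Exception as exc:
        report["failed_stage"] = str(exc)
        (out / "summary.json").write_text(json.dumps(report, indent=2, default=str))
        raise

    report["wall_s_total"] = round(time.time() - t0, 3)
    (out / "summary.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def robustness_over_trees(cfg: AnalysisConfig, trees: list, traits: pd.DataFrame,
                          trait: str, maps_per_tree: int = 1) -> pd.DataFrame:
    """Repeat mapping + OU fitting across a posterior tree sample.

    Draws ``maps_per_tree`` stochastic maps on each tree and fits the
    configured OU models, returning one summary row per tree for comparison
    against the consensus-tree run.
    """
    if len(trees) < 2:
        raise ValueError("need >= 2 trees")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for i, tree in enumerate(trees):
        parity = traits[cfg.parity_column].dropna()
        keep = [l for l in tree.tip_labels if l in set(parity.index)]
        sub = tree.prune_to(keep) if len(keep) < tree.n_tips else tree
        fit = mk.fit_mk(sub, parity, cfg.mk_model)
        mapset = mk.stochastic_maps(sub, parity, fit, maps_per_tree,
                                    int(rng.integers(2 ** 31)))
        res = ou.fit_over_maps(mapset, traits[trait], cfg.ou_models)
        summ = res.theta_summary("OUM")["mean"]
        row = {"tree": i, "best_model": res.best_model.mode().iloc[0]}
        for reg, v in summ.items():
            row[f"theta_{reg}"] = v
        rows.append(row)
    return pd.DataFrame(rows).set_index("tree")


def run_synthetic_demo(out_dir: str, seed: int = 0, n_maps: int = 100,
                       **kw) -> dict:
    """One-command demo on generator defaults at desk scale."""
    cfg = AnalysisConfig.desk(out_dir=out_dir, seed=seed, n_maps=n_maps, **kw)
    return run_full(cfg)
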