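"""Full-pipeline orchestration: filter -> stats -> outlier scan -> GEA ->
combine -> classify, from a single configuration, with per-stage TSV outputs
and a structured run report."""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import combine as cmb
from . import gea as gea_mod
from . import io_formats as io
from . import outlier_scan as scan_mod
from . import popgen_stats as stats_mod
from . import synthetic_data as sim_mod

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and settings for one pipeline run.

    Either ``sim`` (a SimConfig) or the three input paths must be provided.
    A single global seed fans out to per-stage seeds by fixed offsets so each
    stage is independently reproducible.
    """

    outdir: str = "adaptscan_out"
    seed: int = 0
    # inputs: simulated or on-disk
    sim: sim_mod.SimConfig | None = None
    vcf_path: str | None = None
    popmap_path: str | None = None
    env_path: str | None = None
    # stage settings
    filters: io.FilterConfig = field(default_factory=io.FilterConfig)
    k: int | None = None           # None -> scree-drop choice
    max_k: int = 20
    r2_max: float = 0.7
    env_priority: list | None = None
    n_perm: int = 999
    combine_cfg: cmb.CombineConfig = field(default_factory=cmb.CombineConfig)
    broad_sense_anchor: str | None = "latitude"
    # external method adapters (second method of each track)
    external_gso_path: str | None = None
    external_gea_path: str | None = None


def _stage_seed(seed: int, offset: int) -> int:
    return (seed * 1009 + offset) % (2**31 - 1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in order; returns the run report (also written as
    JSON to the output directory).  Stage failures propagate with the stage
    name; outputs of completed stages are left intact."""
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {
        "seed": cfg.seed,
        "thresholds": {
            "alpha": cfg.combine_cfg.alpha,
            "random_hit_max": cfg.combine_cfg.random_hit_max,
            "n_random": cfg.combine_cfg.n_random,
            "r2_max": cfg.r2_max,
            "maf_min": cfg.filters.maf_min,
            "n_perm": cfg.n_perm,
        },
        "stages": {},
    }

    def _run(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- inputs -----------------------------------------------------------
    def load():
        if cfg.sim is not None:
            sim_cfg = cfg.sim
            g, pm, env, truth = sim_mod.simulate(sim_cfg)
            truth.to_json(os.path.join(cfg.outdir, "truth.json"))
            return g, pm, env
        if not (cfg.vcf_path and cfg.popmap_path and cfg.env_path):
            raise ValueError("need either a SimConfig or vcf/popmap/env paths")
        return (
            io.read_vcf(cfg.vcf_path),
            io.read_popmap(cfg.popmap_path),
            io.read_env_table(cfg.env_path),
        )

    g, pm, env = _run("load", load)
    report["stages"]["load"] = {"n_individuals": g.n_individuals, "n_loci": g.n_loci}

    # --- filter -----------------------------------------------------------
    def filt():
        fc = cfg.filters
        fc = io.FilterConfig(
            fc.maf_min, fc.indiv_missing_max, fc.locus_missing_max,
            fc.one_snp_per_tag, _stage_seed(cfg.seed, 1),
        )
        g2, rep = io.apply_filters(g, pm, fc)
        g2, miss_rep = io.drop_population_missing_loci(g2, pm)
        return g2, rep, miss_rep

    g, filt_rep, miss_rep = _run("filter", filt)
    pm = pm.subset(g.individual_ids)
    report["stages"]["filter"] = {
        "individuals_removed": filt_rep.individuals_removed_missing,
        "loci_removed_missing": filt_rep.loci_removed_missing,
        "loci_removed_tag_thinning": filt_rep.loci_removed_tag_thinning,
        "loci_removed_maf": filt_rep.loci_removed_maf,
        "loci_removed_population_missing": miss_rep,
        "n_loci_out": g.n_loci,
    }

    # --- stats ------------------------------------------------------------
    def run_stats():
        div = stats_mod.diversity(g, pm)
        scores, ev = stats_mod.pca(g, n_axes=min(10, g.n_individuals - 1))
        pca_df = pd.DataFrame(
            scores, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
        )
        pca_df.insert(0, "individual", g.individual_ids)
        io.write_results(pca_df, os.path.join(cfg.outdir, "pca_scores.tsv"))
        return div, ev

    div, ev = _run("stats", run_stats)
    report["stages"]["stats"] = {
        "ho": div.ho, "hs": div.hs, "ht": div.ht, "fst": div.fst, "fis": div.fis,
        "pca_explained": [float(x) for x in ev[:5]],
    }

    # --- outlier scan (GSO) ----------------------------------------------
    def run_scan():
        k = cfg.k
        if k is None:
            k, _scree = scan_mod.choose_k(g, max_k=min(cfg.max_k, g.n_individuals - 1))
        table, gif = scan_mod.pcadapt_scan(g, k, seed=_stage_seed(cfg.seed, 2))
        io.write_results(table, os.path.join(cfg.outdir, "gso_scan.tsv"))
        if cfg.external_gso_path:
            other = scan_mod.ingest_external_scan(
                cfg.external_gso_path, "external", g.locus_ids
            )
        else:
            other = table  # single-method track: combination degenerates to q
        cand = cmb.classify_gso(table, other, cfg.combine_cfg)
        suspect = scan_mod.flag_suspect_outliers(
            g, pm, cand[cand["significant"]], ho_max=0.5
        )
        io.write_results(cand, os.path.join(cfg.outdir, "gso_candidates.tsv"))
        return table, gif, cand, suspect

    gso_table, gif, gso_cand, suspect = _run("scan", run_scan)
    report["stages"]["scan"] = {
        "k": gif.k,
        "lambda": gif.lam,
        "n_significant": int(gso_cand["significant"].sum()),
        "n_union": int(gso_cand["in_union"].sum()),
        "n_intersection": int(gso_cand["in_intersection"].sum()),
        "n_high_het_flagged": len(suspect.flagged_high_het),
        "n_population_missing_removed": len(suspect.removed_missing),
    }

    # --- GEA --------------------------------------------------------------
    def run_gea():
        env2, dropped = gea_mod.preprocess_env(
            env, r2_max=cfg.r2_max, priority=cfg.env_priority
        )
        # the constrained model needs df: cap predictors at n_populations - 2,
        # keeping the head of the priority order
        max_vars = len(env2) - 2
        if max_vars < 1:
            raise ValueError("need >=3 populations for the GEA stage")
        if env2.shape[1] > max_vars:
            dropped = dropped + list(env2.columns[max_vars:])
            env2 = env2.iloc[:, :max_vars]
        g_imp = gea_mod.impute_modal(g, pm)
        f_obs, p_full = gea_mod.rda_full_model_test(
            g_imp, env2, pm, n_perm=cfg.n_perm, seed=_stage_seed(cfg.seed, 3)
        )
        real = gea_mod.rda_associations(g_imp, env2, pm)
        io.write_results(real, os.path.join(cfg.outdir, "gea_rda.tsv"))
        if cfg.external_gea_path:
            other = gea_mod.ingest_external_gea(
                cfg.external_gea_path, "external", variables=list(env2.columns)
            )
        else:
            other = real
        real_combined = cmb.combine_gea_tables(real, other)
        ran_env = gea_mod.make_random_env(
            env2.index, count=cfg.combine_cfg.n_random,
            seed=_stage_seed(cfg.seed, 4),
        )
        ran = gea_mod.univariate_associations(g_imp, ran_env, pm)
        ran_combined = cmb.combine_gea_tables(ran, ran)
        hits = cmb.random_hit_counts(ran_combined, cfg.combine_cfg)
        cand, summary = cmb.classify_gea(real_combined, hits, cfg.combine_cfg)
        io.write_results(cand, os.path.join(cfg.outdir, "gea_candidates.tsv"))
        io.write_results(summary, os.path.join(cfg.outdir, "gea_summary.tsv"))
        broad = None
        anchor = cfg.broad_sense_anchor
        if anchor and anchor in env2.columns:
            broad = gea_mod.broad_sense_combine(real_combined.rename(
                columns={"q_combined": "q_value"}), anchor, env2, r2_min=cfg.r2_max)
            io.write_results(
                broad, os.path.join(cfg.outdir, "gea_broad_sense.tsv")
            )
        return env2, dropped, f_obs, p_full, cand, summary, broad

    env2, dropped, f_obs, p_full, gea_cand, gea_summary, broad = _run("gea", run_gea)
    n_high = int((gea_cand["class"] == cmb.HIGH_CONFIDENCE).sum())
    report["stages"]["gea"] = {
        "variables_kept": list(env2.columns),
        "variables_dropped": list(dropped),
        "full_model_F": f_obs,
        "full_model_p": p_full,
        "n_significant_pairs": int((gea_cand["q_combined"] < cfg.combine_cfg.alpha).sum()),
        "n_high_confidence_pairs": n_high,
        "n_high_confidence_loci": int(
            gea_cand.loc[gea_cand["class"] == cmb.HIGH_CONFIDENCE, "locus_id"].nunique()
        ),
    }

    with open(os.path.join(cfg.outdir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    return report
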