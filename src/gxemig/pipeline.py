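"""End-to-end orchestration: simulate → QC → scans → clump → relevance → power.

Configuration is one nested mapping (YAML on disk); a single global seed is
fanned out to every stochastic stage through a seed sequence, so a rerun
with the same configuration is reproducible.  Each stage writes its
artifact under the output directory and appends to a consolidated report
(JSON + Markdown) whose sections mirror the analysis outputs: replicated
main-effect SNPs, replicated interaction SNPs after clumping, relevance
posteriors (overall and stratified by depression), and the predictive
ladder with its AIC confirmation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from gxemig import association, bayes_relevance, clumping, predictive_power, qc
from gxemig.genio import write_assoc
from gxemig.synthetic_cohort import (
    BlockSpec, CohortConfig, EffectSpec, default_blocks, simulate_genotypes,
    simulate_phenotypes, write_cohort,
)

log = logging.getLogger("gxemig")


def default_config(seed: int = 0) -> dict:
    """Desk-scale configuration: ~1000 SNPs, two cohorts totalling 1815
    individuals, three simulated main-effect SNPs and three interaction
    SNPs, reduced MCMC chains."""
    return {
        "seed": seed,
        "cohort": {},                     # CohortConfig overrides
        "blocks": None,                   # None -> default_blocks()
        # Effect sizes sit at the upper end of what candidate-SNP studies
        # of this size report (main-effect OR ~1.6, interaction OR ~3), so
        # the two-subsample replication rule has realistic power at n=1815.
        "effects": [
            {"snp_id": "snp00060", "beta_main": 0.45},       # large block
            {"snp_id": "snp00150", "beta_main": -0.5},       # gene-sized block
            {"snp_id": "snp00185", "beta_interaction": 1.1},  # chr4 block
            {"snp_id": "snp00200", "beta_interaction": 1.1},  # chr10 block
            {"snp_id": "snp00240", "beta_interaction": 1.1},  # background
        ],
        "qc": {},                         # QcThresholds overrides
        "n_pcs_assoc": 10,
        "clump_r2": 0.6,
        "mcmc": {"burn_in": 5000, "n_steps": 25000, "n_chains": 4},
        "classifier": {},
        "cv": {"k": 10, "n_repeats": 10},
        "max_relevance_snps": 8,
    }


def _load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError("pipeline config must be a mapping")
    merged = default_config()
    merged.update(cfg)
    return merged


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage; returns the consolidated report dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "pipeline.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    report: dict[str, Any] = {"config": {k: v for k, v in config.items()}}
    try:
        seed = int(config.get("seed", 0))
        ss = np.random.SeedSequence(seed)
        stage_seeds = ss.spawn(4)

        # --- simulate ---------------------------------------------------
        cohort_cfg = CohortConfig(**{**config.get("cohort", {}),
                                     "seed": _seed_int(stage_seeds[0])})
        blocks = (default_blocks() if config.get("blocks") is None
                  else [BlockSpec(**b) for b in config["blocks"]])
        effects = [EffectSpec(**e) for e in config.get("effects", [])]
        G = simulate_genotypes(blocks, cohort_cfg)
        pheno = simulate_phenotypes(G, effects, cohort_cfg)
        write_cohort(G, pheno, out / "cohort")
        log.info("simulated %d individuals x %d SNPs",
                 G.n_individuals, G.n_snps)

        # --- QC ----------------------------------------------------------
        thresholds = qc.QcThresholds(**config.get("qc", {}))
        G_qc, pheno_qc, qc_report = qc.run_qc(G, pheno, thresholds)
        (out / "qc_report.json").write_text(qc_report.to_json())
        log.info("QC: %d SNPs, %d individuals remain",
                 G_qc.n_snps, G_qc.n_individuals)
        report["qc"] = qc_report.steps

        # --- association scans -------------------------------------------
        n_pcs = int(config.get("n_pcs_assoc", 10))
        main_recs = association.run_main_scan(G_qc, pheno_qc, n_pcs=n_pcs)
        int_recs = association.run_interaction_scan(G_qc, pheno_qc, n_pcs=n_pcs)
        write_assoc(main_recs, out / "assoc_main.tsv")
        write_assoc(int_recs, out / "assoc_interaction.tsv")

        main_rep = association.apply_replication_criterion(main_recs)
        int_rep = association.apply_replication_criterion(int_recs)
        main_hits = [r for r in main_rep if r.passed]
        int_hits = [r for r in int_rep if r.passed]
        tbl1 = association.replication_table(main_hits, n_tests=G_qc.n_snps)
        tbl2_raw = association.replication_table(int_hits, n_tests=G_qc.n_snps)
        tbl1.to_csv(out / "replicated_main.tsv", sep="\t", index=False)
        log.info("replicated: %d main, %d interaction SNPs",
                 len(main_hits), len(int_hits))

        dep_check = association.depression_outcome_check(
            G_qc, pheno_qc,
            [r.snp_id for r in main_hits + int_hits], n_pcs=n_pcs)
        report["depression_outcome_flags"] = (
            dep_check.loc[dep_check["flagged"], "snp_id"].tolist()
            if len(dep_check) else [])

        # --- clumping -----------------------------------------------------
        r2 = float(config.get("clump_r2", 0.6))
        def clump_hits(hits):
            recs = [h.records["TOTAL"] for h in hits]
            return clumping.clump(G_qc, recs, r2_threshold=r2) if recs else []
        main_clumps = clump_hits(main_hits)
        int_clumps = clump_hits(int_hits)
        clumping.clump_table(int_clumps).to_csv(
            out / "clumps_interaction.tsv", sep="\t", index=False)
        main_index = [c.index_snp for c in main_clumps]
        int_index = [c.index_snp for c in int_clumps]
        tbl2 = tbl2_raw[tbl2_raw["snp_id"].isin(int_index)]
        tbl2.to_csv(out / "replicated_interaction_clumped.tsv",
                    sep="\t", index=False)
        report["table_main_effects"] = tbl1.to_dict(orient="records")
        report["table_interaction_clumped"] = tbl2.to_dict(orient="records")

        # --- Bayesian relevance -------------------------------------------
        cap = int(config.get("max_relevance_snps", 8))
        mcmc_cfg = bayes_relevance.McmcConfig(
            **{**config.get("mcmc", {}), "seed": _seed_int(stage_seeds[1])})
        rel_main: dict[str, float] = {}
        if main_index:
            ds = bayes_relevance.DiscreteDataset.from_cohort(
                G_qc, pheno_qc, main_index[:cap])
            post = bayes_relevance.relevance_posterior(
                bayes_relevance.structure_mcmc(ds, mcmc_cfg, "MIGR"))
            rel_main = {s: post.pooled[s] for s in main_index[:cap]}
        rel_strat: dict[str, Any] = {}
        if int_index:
            ds = bayes_relevance.DiscreteDataset.from_cohort(
                G_qc, pheno_qc, int_index[:cap])
            strat = bayes_relevance.stratified_relevance(
                ds, "MIGR", "DEPR", mcmc_cfg)
            rel_strat = {
                "non_depressed": {s: strat["strata"][0].pooled[s]
                                  for s in int_index[:cap]},
                "depressed": {s: strat["strata"][1].pooled[s]
                              for s in int_index[:cap]},
                "difference": {s: strat["difference"][s]
                               for s in int_index[:cap]},
            }
        report["relevance_main"] = rel_main
        report["relevance_stratified"] = rel_strat
        (out / "relevance.json").write_text(json.dumps(
            {"main": rel_main, "stratified": rel_strat,
             "mcmc": {"burn_in": mcmc_cfg.burn_in,
                      "n_steps": mcmc_cfg.n_steps,
                      "n_chains": mcmc_cfg.n_chains,
                      "seed": mcmc_cfg.seed}}, indent=2))
        log.info("relevance analysis done (%d main, %d interaction SNPs)",
                 len(rel_main), len(int_index[:cap]))

        # --- predictive power ---------------------------------------------
        clf_spec = predictive_power.ClassifierSpec(
            **{**config.get("classifier", {}),
               "seed": _seed_int(stage_seeds[2])})
        cv = predictive_power.CvScheme(
            **{**config.get("cv", {}), "seed": _seed_int(stage_seeds[3])})
        power = predictive_power.run_ladder(
            G_qc, pheno_qc, main_index[:cap], int_index[:cap], clf_spec, cv)
        ladder_tbl = power.table()
        aic_tbl = predictive_power.logistic_ladder_aic(
            G_qc, pheno_qc, main_index[:cap], int_index[:cap])
        report["table_predictive_power"] = ladder_tbl.to_dict(orient="records")
        report["table_aic"] = aic_tbl.drop(columns=["term_p"]).to_dict(
            orient="records")
        log.info("predictive ladder done")

        # --- consolidated report ------------------------------------------
        (out / "report.json").write_text(
            json.dumps(report, indent=2, default=str))
        (out / "report.md").write_text(_render_markdown(report))
        return report
    except Exception:
        (out / "report_partial.json").write_text(
            json.dumps(report, indent=2, default=str))
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _render_markdown(report: dict) -> str:
    def df_md(records):
        if not records:
            return "_none_\n"
        return pd.DataFrame(records).to_markdown(index=False,
                                                 floatfmt=".4g") + "\n"
    parts = [
        "# Pipeline report\n",
        "## Replicated main-effect SNPs\n",
        df_md(report.get("table_main_effects", [])),
        "## Replicated interaction SNPs (clumped)\n",
        df_md(report.get("table_interaction_clumped", [])),
        "## Relevance posteriors (main effects)\n",
        json.dumps(report.get("relevance_main", {}), indent=2) + "\n",
        "## Relevance posteriors stratified by depression\n",
        json.dumps(report.get("relevance_stratified", {}), indent=2) + "\n",
        "## Predictive ladder\n",
        df_md(report.get("table_predictive_power", [])),
        "## Logistic ladder (AIC)\n",
        df_md(report.get("table_aic", [])),
    ]
    return "\n".join(parts)


def run_pipeline_from_file(config_path: str | Path, out_dir: str | Path) -> dict:
    return run_pipeline(_load_config(config_path), out_dir)
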