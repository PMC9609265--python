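"""End-to-end orchestration: simulate or load -> depth filter -> agglomerate
-> clr -> diversity -> community tests -> stability selection -> risk
prediction, with every stage's output written as tidy TSV plus a JSON run
manifest (parameter echo and seeds) sufficient to reproduce the run.

Defaults reproduce the study's analysis settings: 6000-read sample filter,
rarefaction at depth 2468 with 100 iterations, 500 x 10-fold elastic-net
Cox with mixing 0.5, the >=25% / q<0.20 selection rule, 5000 permutations
for community and added-discrimination tests, and 1000 bootstraps for the
AUC confidence bands.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition, community, selection, synthetic, tables_io, tdroc

log = logging.getLogger("microsurv")

DEFAULT_CONFIG = {
    "seed": 0,
    "output_dir": "microsurv_out",
    "cohort": {},                 # CohortSpec overrides (synthetic mode)
    "min_reads": 6000,
    "ranks": ["class", "order", "genus"],
    "pseudocount": 0.5,
    "rarefaction_depth": 2468,
    "rarefaction_iterations": 100,
    "endpoints": ["RFS", "DFS", "OS"],
    "selection_tissue": "normal",
    "R": 500,
    "K": 10,
    "alpha": 0.5,
    "min_fraction": 0.25,
    "q_threshold": 0.20,
    "t_grid": [12, 24, 36, 48, 60],
    "n_boot": 1000,
    "n_perm": 5000,
    "risk_endpoint": "RFS",
    "risk_rank": "order",
    "max_risk_features": 4,
}


def load_config(path) -> dict:
    import yaml
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg.update(user)
    return cfg


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", encoding="utf-8",
              float_format="%.10g")


def run_pipeline(config: dict) -> dict:
    """Execute all stages; returns a dict of in-memory results and writes
    one TSV per stage plus ``manifest.json`` under ``output_dir``."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    cfg.update(config or {})
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sub = np.random.SeedSequence(seed).spawn(6)
    stage_seed = [int(s.generate_state(1)[0] % (2 ** 31)) for s in sub]
    results: dict = {}

    def _stage(name):
        log.info("stage=%s", name)

    try:
        _stage("simulate")
        spec = synthetic.CohortSpec(seed=stage_seed[0], **cfg["cohort"])
        cohort = synthetic.simulate_cohort(spec)
        results["cohort"] = cohort
        tables_io.write_feature_table(cohort.table, out / "feature_table.tsv")
        tables_io.write_survival_records(cohort.records, out / "survival.tsv")
        cohort.covariates.table.to_csv(out / "covariates.tsv", sep="\t",
                                       na_rep="NA")
        cohort.metadata.table.to_csv(out / "metadata.tsv", sep="\t", na_rep="NA")
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    try:
        _stage("filter")
        table = tables_io.filter_low_depth(cohort.table, int(cfg["min_reads"]))
        log.info("filter kept %d/%d samples", len(table.sample_ids),
                 len(cohort.table.sample_ids))
    except Exception as e:
        raise RuntimeError(f"stage 'filter' failed: {e}") from e

    meta = tables_io.SampleMetadata(
        cohort.metadata.table.loc[table.sample_ids])

    try:
        _stage("diversity")
        alpha = composition.rarefied_alpha(
            table, int(cfg["rarefaction_depth"]),
            int(cfg["rarefaction_iterations"]), seed=stage_seed[1])
        results["alpha"] = alpha
        _write(alpha.table, out / "alpha_diversity.tsv")
        dmat = composition.jsd_matrix(table)
        results["jsd"] = dmat
        _write(dmat.values, out / "jsd.tsv")
        pc = composition.pcoa(dmat, k=2)
        _write(pc.coordinates, out / "pcoa.tsv")
    except Exception as e:
        raise RuntimeError(f"stage 'diversity' failed: {e}") from e

    try:
        _stage("community-tests")
        tissue = meta.table["tissue_type"]
        perma = community.permanova(dmat, tissue, strata=meta.table["patient_id"],
                                    n_perm=int(cfg["n_perm"]), seed=stage_seed[2])
        pairs = meta.pairs()
        pdt = community.paired_distance_test(dmat, pairs,
                                             n_perm=int(cfg["n_perm"]),
                                             seed=stage_seed[2])
        results["permanova"], results["paired_distance"] = perma, pdt
        feature_tests = []
        for rank in cfg["ranks"]:
            agg = composition.agglomerate(table, rank, drop_unclassified=True)
            clr = composition.clr_transform(agg, float(cfg["pseudocount"]), rank)
            ft = community.paired_feature_tests(clr, clr, pairs, rank)
            feature_tests.append(ft.reset_index())
        res_ft = pd.concat(feature_tests, ignore_index=True)
        results["feature_tests"] = res_ft
        _write(res_ft, out / "paired_feature_tests.tsv")
        pd.DataFrame([{
            "test": "permanova_tissue", "statistic": perma.pseudo_f,
            "R2": perma.r_squared, "p": perma.p_value,
        }, {
            "test": "paired_distance", "statistic": pdt.observed_mean,
            "R2": np.nan, "p": pdt.p_value,
        }]).to_csv(out / "community_tests.tsv", sep="\t", index=False,
                   na_rep="NA")
    except Exception as e:
        raise RuntimeError(f"stage 'community-tests' failed: {e}") from e

    try:
        _stage("selection")
        design = cohort.covariates.design_matrix()
        tissue_ids = meta.samples_of(cfg["selection_tissue"]).index
        sel_table = table.subset_samples(
            [s for s in table.sample_ids if s in set(tissue_ids)])
        pid_of = meta.table["patient_id"]
        selections = {}
        for ep in cfg["endpoints"]:
            surv = tables_io.endpoint_frame(cohort.records, ep)
            for rank in cfg["ranks"]:
                agg = composition.agglomerate(sel_table, rank,
                                              drop_unclassified=True)
                clr = composition.clr_transform(
                    agg, float(cfg["pseudocount"]), rank).values
                clr.index = pid_of.loc[clr.index]
                common = clr.index.intersection(surv.index)
                stab = selection.stability_select(
                    surv.loc[common], clr.loc[common], design.loc[common],
                    R=int(cfg["R"]), K=int(cfg["K"]), alpha=float(cfg["alpha"]),
                    seed=stage_seed[3])
                stab = selection.attach_adjusted_cox(
                    stab, surv.loc[common], clr.loc[common], design.loc[common])
                frame = stab.frame()
                frame["selected"] = frame.index.isin(selection.select_features(
                    stab, float(cfg["min_fraction"]), float(cfg["q_threshold"])))
                selections[(ep, rank)] = (stab, frame)
                _write(frame, out / f"selection_{ep}_{rank}.tsv")
        results["selections"] = selections
    except Exception as e:
        raise RuntimeError(f"stage 'selection' failed: {e}") from e

    try:
        _stage("predict-auc")
        ep = cfg["risk_endpoint"]
        rank = cfg["risk_rank"]
        surv = tables_io.endpoint_frame(cohort.records, ep)
        stab, frame = selections[(ep, rank)]
        chosen = list(frame.index[frame["selected"]])
        if not chosen:  # fall back to the most stable features
            chosen = list(stab.counts.sort_values(ascending=False)
                          .index[:2])
        chosen = chosen[:int(cfg["max_risk_features"])]
        agg = composition.agglomerate(sel_table, rank, drop_unclassified=True)
        clr = composition.clr_transform(agg, float(cfg["pseudocount"])).values
        clr.index = pid_of.loc[clr.index]
        micro_block = clr[chosen]
        gene_block = selection.log2_gene_matrix(cohort.genes)
        gene_cols = list(cohort.truth.signal_genes) or list(gene_block.columns[:4])
        data = tdroc.RiskData.from_frames(surv, design, micro_block,
                                          gene_block[gene_cols])
        td = tdroc.run_td_auc(data, tuple(float(t) for t in cfg["t_grid"]),
                              n_boot=int(cfg["n_boot"]),
                              n_perm=int(cfg["n_perm"]), seed=stage_seed[4])
        results["tdauc"] = td
        rows = []
        for model in td.auc.index:
            for t in td.t_grid:
                rows.append({"model": model, "time": t,
                             "auc": td.auc.loc[model, t],
                             "ci_lower": td.ci_lower.loc[model, t],
                             "ci_upper": td.ci_upper.loc[model, t]})
        for comp_name in td.delta_auc.index:
            for t in td.t_grid:
                rows.append({"model": comp_name, "time": t,
                             "auc": td.delta_auc.loc[comp_name, t],
                             "perm_p": td.perm_p.loc[comp_name, t]})
        pd.DataFrame(rows).to_csv(out / "td_auc.tsv", sep="\t", index=False,
                                  na_rep="NA", float_format="%.10g")
    except Exception as e:
        raise RuntimeError(f"stage 'predict-auc' failed: {e}") from e

    manifest = {"config": cfg, "seed": seed, "stage_seeds": stage_seed,
                "n_samples": len(table.sample_ids),
                "n_patients": len(cohort.records)}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
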