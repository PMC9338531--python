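"""End-to-end convenience workflows tying the modules together.

These are the same steps the command-line interface exposes; keeping them
here lets scripts and tests run the full analysis without shelling out.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import (biomarker_funnel, concordance, diffexp, omics_io,
               signature_trend, splicing_landscape)
from .cohort_synth import GroundTruth
from .omics_io import PairedCohort
from .splicing_landscape import SpliceEventTable

__all__ = ["prepare_cohort", "load_cohort_dir", "full_analysis"]


def prepare_cohort(cohort: PairedCohort, max_missing_frac: float = 0.2,
                   k_neighbors: int = 10,
                   low_abundance: bool = False) -> PairedCohort:
    """Standard preprocessing: optional low-abundance filters, protein
    missingness filter + KNN imputation, re-pairing of the layers."""
    prot, mrna = cohort.protein, cohort.mrna
    if low_abundance:
        prot = omics_io.filter_low_abundance(prot)
        mrna = omics_io.filter_low_abundance(mrna)
    prot = omics_io.filter_and_impute(prot, max_missing_frac, k_neighbors)
    return omics_io.build_paired_cohort(prot, mrna, cohort.meta)


def load_cohort_dir(dir_path, prepare: bool = True,
                    max_missing_frac: float = 0.2, k_neighbors: int = 10
                    ) -> tuple[PairedCohort, SpliceEventTable, GroundTruth | None]:
    """Read a cohort directory written by ``write_cohort`` (or hand-built
    with the same file names)."""
    d = Path(dir_path)
    protein = omics_io.read_matrix(d / "protein.tsv", "protein")
    mrna = omics_io.read_matrix(d / "mrna.tsv", "mrna")
    meta = omics_io.read_metadata(d / "metadata.tsv")
    cohort = omics_io.build_paired_cohort(protein, mrna, meta)
    if prepare:
        cohort = prepare_cohort(cohort, max_missing_frac, k_neighbors)
    tumor = [s for s in meta.samples if meta.table.loc[s, "group"] == "tumor"]
    control = [s for s in meta.samples if meta.table.loc[s, "group"] != "tumor"]
    fragments = []
    for t in omics_io.ASE_TYPES:
        path = d / f"{t}.MATS.JC.txt"
        if path.exists():
            fragments.append(omics_io.read_rmats_table(path, t, tumor, control))
    table = None
    if fragments:
        table = SpliceEventTable.concat(fragments, meta.arm)
    truth = None
    tpath = d / "ground_truth.json"
    if tpath.exists():
        truth = GroundTruth.from_json(tpath.read_text())
    return cohort, table, truth


def full_analysis(cohort: PairedCohort, table: SpliceEventTable,
                  truth: GroundTruth | None = None, seed: int = 0,
                  n_lasso_iterations: int = 200,
                  sf_genes=None, include_funnel: bool = True) -> dict:
    """Run every stage on one cohort and collect the headline numbers.

    Returns a flat dict of scalar results (medians, counts, test statistics)
    suitable for reporting; heavier per-stage tables are recomputed on
    demand by the individual modules.
    """
    cohort = prepare_cohort(cohort)
    results: dict[str, float] = {}

    # per-sample concordance, scope-specific pair universes
    prof_t = concordance.compute_concordance(cohort, "tumor")
    prof_c = concordance.compute_concordance(cohort, "control")
    profiles = pd.concat([prof_t, prof_c])
    results["n_pairs_tumor_scope"] = prof_t.attrs["n_pairs_universe"]
    results["n_pairs_control_scope"] = prof_c.attrs["n_pairs_universe"]
    results["median_rho_tumor"] = float(prof_t["rho"].median())
    results["median_rho_control"] = float(prof_c["rho"].median())
    results["median_rho_difference"] = (results["median_rho_tumor"]
                                        - results["median_rho_control"])
    grouping = (profiles["arm"] == "tumor").map({True: "tumor", False: "control"})
    results["rho_group_p"] = concordance.compare_groups(profiles, grouping).p_value

    mki67 = cohort.meta.table["mki67_protein"]
    results["mki67_rho_r_tumor"] = concordance.correlate_with(prof_t, mki67).estimate

    surv = concordance.concordance_survival(prof_t, cohort.meta, "DRFS")
    results["drfs_logrank_p"] = surv.logrank.p_value
    results["drfs_cox_beta"] = surv.cox.estimate
    # log-hazard per SD of concordance (raw rho units are tiny)
    results["drfs_cox_beta_per_sd"] = surv.cox.estimate * float(prof_t["rho"].std())

    # cross-layer differential expression
    is_tumor = (cohort.meta.arm == "tumor").to_numpy()
    de_p = diffexp.run_de(cohort.protein.values, is_tumor, "protein")
    de_m = diffexp.run_de(cohort.mrna.values, is_tumor, "mrna")
    _, counts = diffexp.classify_concordance(de_p, de_m)
    results["n_shared_pairs"] = int(len(cohort.genes))
    results["n_co_up"] = counts.co_up
    results["n_co_down"] = counts.co_down
    results["n_discordant"] = counts.discordant

    # trend signature
    arms = cohort.meta.arm
    patterns = signature_trend.call_trend_patterns(cohort.protein.values, arms)
    clusters = signature_trend.cluster_hvgs(cohort.protein.values, arms, seed=seed)
    _, cls_counts = signature_trend.build_signature(patterns, clusters)
    for cls in signature_trend.SIGNATURE_CLASSES:
        results[f"n_{cls.lower().replace('-', '_')}"] = int(cls_counts[cls])

    # splicing landscape
    calls = splicing_landscape.call_aase(table)
    summary = splicing_landscape.landscape_summary(calls)
    results["n_aase"] = summary.n_aase
    results["n_aase_genes"] = summary.n_genes
    results["n_single_type_genes"] = summary.n_single_type_genes
    prog = splicing_landscape.progression_aase(calls, table, cohort.meta, "PFS")
    results["n_progression_aase"] = int(prog["significant"].sum()) if len(prog) else 0
    if sf_genes is None and truth is not None:
        sf_genes = truth.sf_genes
    if sf_genes:
        rank = splicing_landscape.sf_correlation_ranking(
            sf_genes, cohort.protein.values, table, calls, prog)
        results["n_recurrent_sfs"] = len(rank.recurrent_sfs)
        if truth is not None and truth.active_sfs:
            sf = truth.active_sfs[0]
            if sf in rank.ranking_all.index:
                results["regulator_rank_all"] = int(rank.ranking_all.loc[sf, "rank"])
                results["regulator_strong_count"] = int(
                    rank.ranking_all.loc[sf, "strong_count"])
            if rank.ranking_progression is not None and \
                    sf in rank.ranking_progression.index:
                results["regulator_rank_progression"] = int(
                    rank.ranking_progression.loc[sf, "rank"])

    # biomarker funnel
    if not include_funnel:
        return results
    references = []
    if truth is not None:
        references = sorted(g for g, p in truth.pattern_genes.items()
                            if p == "up_up" and g in cohort.genes)[:2]
    report = biomarker_funnel.run_funnel(cohort.protein.values, is_tumor,
                                         reference_markers=references,
                                         n_iterations=n_lasso_iterations,
                                         seed=seed)
    results["n_funnel_de"] = len(report.stage1_de)
    results["n_funnel_logistic"] = len(report.stage1_logistic)
    results["n_funnel_overlap"] = len(report.stage2_overlap)
    results["n_lasso_selected"] = len(report.lasso_selected)
    results["n_final_markers"] = len(report.final_markers)
    if truth is not None:
        results["marker_recovered"] = float(
            report.final_markers == [truth.marker_gene])
        if truth.marker_gene in report.auc_table.index:
            results["marker_auc"] = float(
                report.auc_table.loc[truth.marker_gene, "auc"])
        for i, ref in enumerate(references, 1):
            results[f"reference_{i}_auc"] = float(report.auc_table.loc[ref, "auc"])
    return results
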