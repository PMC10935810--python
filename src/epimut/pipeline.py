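"""End-to-end orchestration: simulate → qc → call → stats → expression → clinical.

``run_pipeline`` executes the stages in dependency order against a YAML
config, writes every stage's outputs as TSV/JSON into an artifact directory
and records a run manifest (config snapshot, seed, input digests, per-stage
row counts, tool version). Re-running with an unchanged config and seed is a
no-op unless forced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, io
from .annotation import build_promoter_map, summarize_probe_coverage
from .calling import (call_epimutations, call_healthy_test, promoter_beta,
                      tissue_baseline)
from .clinical import cox_univariate, drug_sensitivity_assoc, km_estimate, \
    logrank_test, quartile_groups
from .cohort_stats import classify_frequency, oedr, prevalence_summary, top_epimutated
from .expression import compare_expression, methylation_expression_correlation, \
    partition_by_methylation
from .qc import filter_probes
from .simulate import SimConfig, simulate_clinical, simulate_cohort, simulate_expression

logger = logging.getLogger(__name__)


def _config_hash(config: dict, seed: int | None) -> str:
    payload = json.dumps({"config": config, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def make_sim_config(params: dict | None, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a (possibly partial) mapping of overrides."""
    params = dict(params or {})
    if seed is not None:
        params["seed"] = int(seed)
    field_names = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(params) - field_names
    if unknown:
        raise ValueError(f"unknown simulate parameters: {sorted(unknown)}")
    return SimConfig(**params)


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None, force: bool = False) -> Path:
    """Run the full pipeline; returns the artifact directory.

    The config maps stage names to parameters. With a ``simulate`` section
    (possibly empty) the inputs are generated; otherwise an ``inputs`` section
    must give paths to beta / sheet / annotation files.
    """
    if not isinstance(config, dict):
        config = io.read_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = _config_hash(config, seed)
    if manifest_path.exists() and not force:
        previous = io.read_manifest(manifest_path)
        if previous.get("config_hash") == chash:
            logger.info("unchanged config and seed; skipping (use force to rerun)")
            return out

    manifest: dict = {"tool": "epimut", "version": __version__, "seed": seed,
                      "config": config, "config_hash": chash,
                      "input_digests": {}, "row_counts": {}}
    counts = manifest["row_counts"]

    # --- inputs ------------------------------------------------------------
    truth = None
    if "simulate" in config or "inputs" not in config:
        sim_config = make_sim_config(config.get("simulate"), seed)
        logger.info("stage simulate: seed %s", sim_config.seed)
        beta, sheet, annotation, truth = simulate_cohort(sim_config)
        expr = simulate_expression(truth, sim_config)
        survival, drugs = simulate_clinical(truth, sim_config)
        detection_p = truth.detection_p
        blocklist_cr = truth.blocklist_cross_reactive
        blocklist_snp = truth.blocklist_snp
        io.write_matrix(beta, out / "beta.tsv", kind="beta")
        io.write_cohort_sheet(sheet, out / "cohort_sheet.tsv")
        io.write_annotation(annotation, out / "annotation.tsv")
        io.write_matrix(expr, out / "expression.tsv", kind="expression")
        io.write_survival(survival, out / "survival.tsv")
        io.write_drug_response(drugs, out / "drug_response.tsv")
        io.write_calls(truth.planted_calls.rename(columns={"sample": "sample"}),
                       out / "truth_planted_calls.tsv")
        gene_list = truth.gene_effects["gene"].tolist()
    else:
        paths = config["inputs"]
        for key, p in paths.items():
            manifest["input_digests"][key] = io.file_digest(p)
        beta = io.read_matrix(paths["beta"], kind="beta")
        sheet = io.read_cohort_sheet(paths["sheet"])
        annotation = io.read_annotation(paths["annotation"])
        detection_p = (io.read_matrix(paths["detection_p"], kind="detection_p")
                       if "detection_p" in paths else None)
        blocklist_cr = io.read_blocklist(paths["blocklist_cross_reactive"]) \
            if "blocklist_cross_reactive" in paths else None
        blocklist_snp = io.read_blocklist(paths["blocklist_snp"]) \
            if "blocklist_snp" in paths else None
        expr = io.read_matrix(paths["expression"], kind="expression") \
            if "expression" in paths else None
        survival = io.read_survival(paths["survival"]) if "survival" in paths else None
        drugs = io.read_drug_response(paths["drug_response"]) \
            if "drug_response" in paths else None
        gene_list = (io.read_gene_list(paths["gene_list"]) if "gene_list" in paths
                     else sorted(set(annotation["gene"]) - {""}))
    counts["samples"] = len(sheet)
    counts["probes_in"] = len(beta)

    # --- qc ---------------------------------------------------------------
    qc_params = config.get("qc", {})
    filtered, report = filter_probes(
        beta, detection_p=detection_p,
        blocklist_cross_reactive=blocklist_cr, blocklist_snp=blocklist_snp,
        annotation=annotation,
        fail_fraction=float(qc_params.get("fail_fraction", 0.05)),
        skip_sex=bool(qc_params.get("skip_sex", False)))
    io.write_matrix(filtered, out / "beta_filtered.tsv", kind="beta")
    qc_dict = {k: getattr(report, k) for k in (
        "n_probes_in", "n_failed_detection", "n_cross_reactive", "n_snp_adjacent",
        "n_sex_chromosome", "n_no_annotation", "n_probes_out", "n_cells_masked",
        "skipped_rules")}
    (out / "qc_report.json").write_text(json.dumps(qc_dict, indent=2) + "\n")
    counts["probes_out"] = report.n_probes_out
    logger.info("stage qc: %d -> %d probes", report.n_probes_in, report.n_probes_out)

    # --- calling ------------------------------------------------------------
    pmap = build_promoter_map(annotation, gene_list)
    coverage = summarize_probe_coverage(pmap, annotation)
    (out / "coverage_summary.json").write_text(
        json.dumps(coverage.as_dict(), indent=2) + "\n")
    pm = promoter_beta(filtered, pmap)
    baseline = tissue_baseline(pm, sheet)
    calls = call_epimutations(pm, baseline, sheet)
    healthy = call_healthy_test(pm, baseline, sheet)
    io.write_calls(calls.calls, out / "calls.tsv")
    io.write_calls(healthy.calls, out / "healthy_test_calls.tsv")
    counts["calls"] = len(calls)
    counts["healthy_test_calls"] = len(healthy)
    logger.info("stage call: %d cancer calls, %d healthy-test calls",
                len(calls), len(healthy))

    # --- cohort statistics ---------------------------------------------------
    n_cancer = int((sheet["role"] == "cancer").sum())
    if len(calls.calls):
        oedr_table = oedr(calls.calls, sheet)
        oedr_table.to_csv(out / "oedr.tsv", sep="\t", index=False,
                          float_format=io.FLOAT_FORMAT)
        prev = prevalence_summary(calls.calls, sheet)
        prev.per_tissue.to_csv(out / "prevalence_per_tissue.tsv", sep="\t",
                               index=False, float_format=io.FLOAT_FORMAT)
        freq = classify_frequency(calls.calls, n_cancer)
        freq.to_csv(out / "frequency_classes.tsv", sep="\t", index=False,
                    float_format=io.FLOAT_FORMAT)
        top = top_epimutated(calls.calls, sheet,
                             k=int(config.get("stats", {}).get("top_k", 10)))
        top.to_csv(out / "top_epimutated.tsv", sep="\t", index=False,
                   float_format=io.FLOAT_FORMAT)
        summary = {"n_calls": len(calls), "median_calls_per_sample": prev.median_calls,
                   "carrier_fraction": prev.carrier_fraction}
        (out / "prevalence_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    else:
        logger.warning("stage stats: no calls; distribution statistics skipped")
        (out / "oedr.tsv").write_text("no calls\n")
    counts["genes_called"] = int(calls.calls["gene"].nunique()) if len(calls.calls) else 0

    # --- expression integration ---------------------------------------------
    if expr is not None and len(calls.calls):
        genes = config.get("expression", {}).get("genes")
        if not genes:
            genes = (calls.calls.groupby("gene")["sample"].nunique()
                     .sort_values(ascending=False).head(7).index.tolist())
        rows = []
        for gene in genes:
            part = partition_by_methylation(pm, baseline, sheet, gene,
                                            expr_samples=list(expr.columns))
            if not part.testable or len(part.hyper) < 2 or len(part.other) < 2:
                rows.append((gene, len(part.hyper), len(part.other),
                             float("nan"), float("nan"), 0, "untestable"))
                continue
            cmp_res = compare_expression(expr, part.hyper, part.other, gene)
            rows.append((gene, cmp_res.n_hyper, cmp_res.n_other, cmp_res.statistic,
                         cmp_res.p, cmp_res.direction, cmp_res.method))
        pd.DataFrame(rows, columns=["gene", "n_hyper", "n_other", "statistic",
                                    "p", "direction", "method"]).to_csv(
            out / "expression_comparison.tsv", sep="\t", index=False,
            float_format=io.FLOAT_FORMAT)
        counts["expression_tests"] = len(rows)

    # --- clinical -------------------------------------------------------------
    clinical_cfg = config.get("clinical", {})
    if survival is not None and expr is not None:
        gene = clinical_cfg.get("gene") or (truth.clinical_gene if truth is not None
                                            else None)
        tissue = clinical_cfg.get("tissue", "pancreas")
        if gene is not None and gene in expr.index:
            surv = survival.set_index("sample_id")
            eligible = [s for s in surv.index if s in expr.columns]
            sheet_idx = sheet.set_index("sample_id")
            eligible = [s for s in eligible
                        if sheet_idx.loc[s, "tissue"] == tissue] or eligible
            result: dict = {"gene": gene, "tissue": tissue, "n": len(eligible)}
            if len(eligible) >= 8:
                labels = quartile_groups(expr.loc[gene, eligible])
                keep = labels[labels != "excluded"].index
                records = surv.loc[keep, ["time", "event"]].reset_index(drop=True)
                group = (labels[keep] == "low").astype(int).reset_index(drop=True)
                km_estimate(surv.loc[keep].reset_index()).to_csv(
                    out / "km_curve.tsv", sep="\t", index=False,
                    float_format=io.FLOAT_FORMAT)
                try:
                    chi2, p = logrank_test(records, group)
                    result["logrank_chi2"], result["logrank_p"] = chi2, p
                except ValueError as err:
                    result["logrank_error"] = str(err)
                try:
                    cox = cox_univariate(records, group)
                    result.update({"cox_hr": cox.hr, "cox_ci_low": cox.ci_low,
                                   "cox_ci_high": cox.ci_high, "cox_p": cox.p})
                except (ValueError, RuntimeError) as err:
                    result["cox_error"] = str(err)
            else:
                result["error"] = "cohort too small for quartile split"
            (out / "survival_analysis.json").write_text(
                json.dumps(result, indent=2) + "\n")
    if drugs is not None:
        gene = clinical_cfg.get("drug_gene") or (truth.drug_gene if truth is not None
                                                 else None)
        compounds = clinical_cfg.get("compounds") or sorted(drugs["compound"].unique())
        if gene is not None and gene in pm.beta.index:
            try:
                assoc = drug_sensitivity_assoc(pm, drugs, gene, compounds)
                (out / "drug_association.json").write_text(json.dumps({
                    "gene": assoc.gene, "compounds": list(assoc.compounds),
                    "n_pairs": assoc.n_pairs, "rho": assoc.rho, "rho_p": assoc.rho_p,
                    "slope": assoc.slope, "slope_p": assoc.slope_p,
                    "flagged": assoc.flagged}, indent=2) + "\n")
            except ValueError as err:
                logger.warning("drug association skipped: %s", err)

    io.write_manifest(manifest, manifest_path)
    logger.info("pipeline complete: %s", out)
    return out
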