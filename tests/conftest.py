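import numpy as np
import pandas as pd
import pytest

import epimut as em
from epimut.simulate import SimTruth


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size synthetic cohort at the default study conditions (seed 1)."""
    config = em.SimConfig(seed=1)
    beta, sheet, annotation, truth = em.simulate_cohort(config)
    return {"config": config, "beta": beta, "sheet": sheet,
            "annotation": annotation, "truth": truth}


@pytest.fixture(scope="session")
def called_cohort(default_cohort):
    """QC'd, aggregated and called version of the default cohort."""
    d = default_cohort
    filtered, report = em.filter_probes(
        d["beta"], detection_p=d["truth"].detection_p,
        blocklist_cross_reactive=d["truth"].blocklist_cross_reactive,
        blocklist_snp=d["truth"].blocklist_snp, annotation=d["annotation"])
    pmap = em.build_promoter_map(d["annotation"],
                                 d["truth"].gene_effects["gene"].tolist())
    pm = em.promoter_beta(filtered, pmap)
    baseline = em.tissue_baseline(pm, d["sheet"])
    calls = em.call_epimutations(pm, baseline, d["sheet"])
    healthy = em.call_healthy_test(pm, baseline, d["sheet"])
    return {**d, "filtered": filtered, "qc_report": report, "pmap": pmap,
            "pm": pm, "baseline": baseline, "calls": calls, "healthy": healthy}


def small_config(seed=0, **overrides):
    """A fast five-tissue cohort for unit tests."""
    counts = {t: {"primary": 12, "cell_line": 6, "organoid": 2,
                  "baseline_control": 4, "test_control": 3}
              for t in em.simulate.TISSUES}
    defaults = dict(counts=counts, n_genes=60, n_sex_probes=20,
                    n_cross_reactive=10, n_snp_adjacent=10, n_failed_probes=3,
                    seed=seed)
    defaults.update(overrides)
    return em.SimConfig(**defaults)


@pytest.fixture()
def small_cohort():
    config = small_config(seed=7)
    beta, sheet, annotation, truth = em.simulate_cohort(config)
    return {"config": config, "beta": beta, "sheet": sheet,
            "annotation": annotation, "truth": truth}


def minimal_truth(sheet: pd.DataFrame, planted: pd.DataFrame,
                  genes: list[str], inverted: list[str] | None = None,
                  survival_group: pd.Series | None = None,
                  config: em.SimConfig | None = None) -> SimTruth:
    """Hand-built SimTruth for targeted generator tests."""
    inverted = inverted or []
    config = config or em.SimConfig()
    if survival_group is None:
        mask = (sheet["role"] == "cancer") & (sheet["cell_model"] == "primary")
        survival_group = pd.Series("high", index=sheet.loc[mask, "sample_id"].to_numpy())
    gene_effects = pd.DataFrame({
        "gene": genes,
        "weight": 1.0,
        "n_planted_cancer": 0,
        "silencing_factor": config.expression_silencing_factor,
        "inverted": [g in inverted for g in genes],
    })
    return SimTruth(
        planted_calls=planted, gene_effects=gene_effects,
        survival_group=survival_group, drug_gene=genes[0], clinical_gene=genes[0],
        inverted_genes=inverted,
        drug_gene_beta=pd.Series(dtype=float),
        baseline_means=pd.DataFrame(index=genes),
        blocklist_cross_reactive=set(), blocklist_snp=set(),
        detection_p=pd.DataFrame(), sheet=sheet, config=config)


def toy_annotation() -> pd.DataFrame:
    """Six probes over three genes; GENEC has only a non-promoter probe."""
    return pd.DataFrame({
        "probe_id": ["cg01", "cg02", "cg03", "cg04", "cg05", "cg06"],
        "chrom": ["1", "1", "2", "2", "3", "X"],
        "pos": [100, 300, 500, 700, 900, 1100],
        "strand": ["+", "+", "-", "-", "+", "+"],
        "gene": ["GENEA", "GENEA", "GENEB", "GENEB", "GENEC", "GENEA"],
        "region_class": ["TSS200", "TSS1500", "UTR5", "EXON1", "OTHER", "TSS200"],
        "cpg_island": [True, False, True, False, False, True],
    })
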