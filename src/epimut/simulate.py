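"""Synthetic multi-tissue methylation cohorts with known planted truth.

Emulates the structure of a pan-cancer promoter-methylation study: five
tissues, three cancer cell models (primary tumour, cancer cell line,
organoid), a per-tissue healthy baseline cohort and an independent healthy
test cohort. Promoter methylation is beta-distributed on [0,1]; selected
(sample, gene) pairs are "epimutated" — every promoter probe of that gene is
drawn from a hypermethylated beta distribution — and the planted truth is
returned so downstream callers can be scored. Matched expression (silenced in
carriers, with a configurable positively-coupled exception), exponential
survival with an expression-group hazard ratio, and IC50 z-scores correlated
with promoter methylation complete the cohort.

Everything is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtri as _norm_ppf
from scipy.stats import rankdata as stats_rankdata

TISSUES = ("colorectum", "oesophagus", "lung", "pancreas", "stomach")
CELL_MODELS = ("primary", "cell_line", "organoid")
ROLES = ("cancer", "baseline_control", "test_control")

# per-tissue sample counts: primary, cell_line, organoid, baseline_control, test_control
DEFAULT_COUNTS: dict[str, dict[str, int]] = {
    "colorectum": {"primary": 95, "cell_line": 49, "organoid": 11,
                   "baseline_control": 10, "test_control": 16},
    "oesophagus": {"primary": 92, "cell_line": 35, "organoid": 4,
                   "baseline_control": 8, "test_control": 8},
    "lung":       {"primary": 94, "cell_line": 61, "organoid": 1,
                   "baseline_control": 10, "test_control": 16},
    "pancreas":   {"primary": 97, "cell_line": 31, "organoid": 7,
                   "baseline_control": 4, "test_control": 5},
    "stomach":    {"primary": 98, "cell_line": 28, "organoid": 2,
                   "baseline_control": 10, "test_control": 2},
}

# per-tissue per-gene planting probabilities (scaled by per-gene weights);
# chosen so the expected tissue over/under-representation (log2 OEDR) spans
# roughly -1.3 .. +0.6 with lung under- and stomach over-represented.
DEFAULT_EPIMUTATION_RATE: dict[str, float] = {
    "colorectum": 0.010,
    "oesophagus": 0.010,
    "lung": 0.0035,
    "pancreas": 0.006,
    "stomach": 0.015,
}

REGION_CLASS_PROBS = {"TSS1500": 0.30, "TSS200": 0.21, "UTR5": 0.29,
                      "EXON1": 0.13, "OTHER": 0.07}


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort. Defaults give the multi-tissue
    case/control design described in the module docstring."""

    tissues: tuple[str, ...] = TISSUES
    counts: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {t: dict(c) for t, c in DEFAULT_COUNTS.items()})
    n_genes: int = 523
    probes_per_gene_lambda: float = 10.0  # probes/gene = 1 + Poisson(lambda); median 11

    beta_background_mean: float = 0.10
    beta_background_concentration: float = 50.0
    beta_hyper_mean: float = 0.85
    beta_hyper_concentration: float = 50.0
    tissue_offset_sd: float = 0.02  # per-(tissue, gene) baseline shift

    epimutation_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EPIMUTATION_RATE))
    gene_weight_shape: float = 3.0  # Gamma shape of per-gene planting weights (mean 1)
    healthy_test_rate: float = 0.005
    healthy_test_tissues: tuple[str, ...] = ("oesophagus", "pancreas")

    missing_rate: float = 0.01
    detection_fail_cell_rate: float = 0.002
    n_failed_probes: int = 15
    failed_probe_fail_fraction: float = 0.10
    n_sex_probes: int = 150
    n_cross_reactive: int = 80
    n_snp_adjacent: int = 80

    expression_silencing_factor: float = 0.15
    n_inverted_genes: int = 1
    expression_fraction: float = 0.8
    expression_log_mean: float = 3.0
    expression_gene_log_sd: float = 1.0
    expression_sample_log_sd: float = 0.5

    survival_base_rate: float = 0.001  # events per day for the high-expression group
    survival_hr_low_expression: float = 2.0
    censoring_rate: float = 0.0005

    drug_rho: float = 0.3
    drug_tissue: str = "pancreas"
    drug_compounds: tuple[str, ...] = ("AZ960", "JAK_inh_A", "JAK_inh_B", "ruxolitinib")
    drug_pathway: str = "JAK/STAT"

    seed: int = 0

    def validate(self) -> None:
        for name in ("healthy_test_rate", "missing_rate",
                     "detection_fail_cell_rate", "expression_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for t, r in self.epimutation_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"epimutation_rate[{t}] must be in [0, 1], got {r}")
        for name in ("beta_background_mean", "beta_hyper_mean"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        for t in self.tissues:
            if t not in self.counts:
                raise ValueError(f"no sample counts for tissue {t!r}")
            for role in ("primary", "baseline_control", "test_control"):
                if self.counts[t].get(role, 0) < 1:
                    raise ValueError(
                        f"tissue {t!r} needs >= 1 sample in role {role!r}")


@dataclass
class SimTruth:
    """Planted ground truth and generator-internal state for scoring."""

    planted_calls: pd.DataFrame          # sample, gene, tissue, role, cell_model, healthy_leak
    gene_effects: pd.DataFrame           # gene, weight, silencing_factor, inverted
    survival_group: pd.Series            # primary-tumour sample -> {"low", "high"}
    drug_gene: str
    clinical_gene: str
    inverted_genes: list[str]
    drug_gene_beta: pd.Series            # realized promoter mean in drug-tissue cell lines
    baseline_means: pd.DataFrame         # gene x tissue generating background means
    blocklist_cross_reactive: set[str]
    blocklist_snp: set[str]
    detection_p: pd.DataFrame
    sheet: pd.DataFrame
    config: SimConfig

    def planted_pairs(self, cancer_only: bool = True) -> set[tuple[str, str]]:
        df = self.planted_calls
        if cancer_only:
            df = df[df["role"] == "cancer"]
        return set(zip(df["sample"], df["gene"]))


def _beta_params(mean: np.ndarray, concentration: np.ndarray):
    return mean * concentration, (1.0 - mean) * concentration


def _make_samples(config: SimConfig) -> pd.DataFrame:
    rows = []
    for tissue in config.tissues:
        counts = config.counts[tissue]
        short = tissue[:3]
        for model in CELL_MODELS:
            for i in range(int(counts.get(model, 0))):
                rows.append((f"{short}_{model}_{i + 1:03d}", tissue, "cancer", model))
        for i in range(int(counts["baseline_control"])):
            rows.append((f"{short}_ctrl_{i + 1:03d}", tissue, "baseline_control", "primary"))
        for i in range(int(counts["test_control"])):
            rows.append((f"{short}_test_{i + 1:03d}", tissue, "test_control", "primary"))
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "role", "cell_model"])


def simulate_cohort(config: SimConfig | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate (beta matrix, cohort sheet, probe annotation, truth).

    The beta matrix is probes x samples with values in [0,1] and NaN for
    missing cells. Planted (sample, gene) pairs have every probe of the gene
    drawn from the hypermethylated distribution. Decoy probes (sex
    chromosomes, cross-reactive, SNP-adjacent) and detection-p failures are
    included so QC filtering has real work to do.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    sheet = _make_samples(config)
    genes = np.array([f"GENE{i + 1:04d}" for i in range(config.n_genes)])

    # per-gene planting weights (mean 1) give heterogeneous recurrence
    weights = rng.gamma(config.gene_weight_shape, 1.0 / config.gene_weight_shape,
                        size=config.n_genes)

    # --- annotation -------------------------------------------------------
    probes_per_gene = 1 + rng.poisson(config.probes_per_gene_lambda, size=config.n_genes)
    gene_idx_of_probe = np.repeat(np.arange(config.n_genes), probes_per_gene)
    n_real = gene_idx_of_probe.size
    chrom = rng.integers(1, 23, size=config.n_genes).astype(str)
    tss = rng.integers(1_000_000, 50_000_000, size=config.n_genes)
    strand = rng.choice(["+", "-"], size=config.n_genes)
    classes = rng.choice(list(REGION_CLASS_PROBS), size=n_real,
                         p=list(REGION_CLASS_PROBS.values()))
    offsets = rng.integers(-1500, 1500, size=n_real)

    ann = pd.DataFrame({
        "probe_id": [f"cg{i:08d}" for i in range(n_real)],
        "chrom": chrom[gene_idx_of_probe],
        "pos": tss[gene_idx_of_probe] + offsets,
        "strand": strand[gene_idx_of_probe],
        "gene": genes[gene_idx_of_probe],
        "region_class": classes,
        "cpg_island": rng.random(n_real) < 0.52,
    })

    # decoys: cross-reactive / SNP-adjacent probes attached to real genes
    # (noisy signal, must be filtered), sex-chromosome probes unassigned.
    n_cr, n_snp, n_sex = config.n_cross_reactive, config.n_snp_adjacent, config.n_sex_probes
    n_decoy = n_cr + n_snp + n_sex
    decoy_ids = [f"cg9{i:07d}" for i in range(n_decoy)]
    decoy_gene_idx = rng.integers(0, config.n_genes, size=n_cr + n_snp)
    decoy = pd.DataFrame({
        "probe_id": decoy_ids,
        "chrom": np.concatenate([chrom[decoy_gene_idx],
                                 rng.choice(["X", "Y"], size=n_sex)]),
        "pos": rng.integers(1_000_000, 50_000_000, size=n_decoy),
        "strand": rng.choice(["+", "-"], size=n_decoy),
        "gene": np.concatenate([genes[decoy_gene_idx], np.repeat("", n_sex)]),
        "region_class": np.concatenate([
            rng.choice(["TSS1500", "TSS200", "UTR5", "EXON1"], size=n_cr + n_snp),
            np.repeat("OTHER", n_sex)]),
        "cpg_island": rng.random(n_decoy) < 0.52,
    })
    blocklist_cr = set(decoy_ids[:n_cr])
    blocklist_snp = set(decoy_ids[n_cr:n_cr + n_snp])
    annotation = pd.concat([ann, decoy], ignore_index=True)

    # --- planted epimutations --------------------------------------------
    n_samples = len(sheet)
    tissue_of = sheet["tissue"].to_numpy()
    role_of = sheet["role"].to_numpy()
    rate_of_sample = np.array([
        config.epimutation_rate[t] if r == "cancer"
        else (config.healthy_test_rate
              if r == "test_control" and t in config.healthy_test_tissues
              else 0.0)
        for t, r in zip(tissue_of, role_of)])
    # healthy-test leaks are planted uniformly across genes; cancer planting
    # is scaled by per-gene weights.
    p_plant = np.where(
        (role_of == "cancer")[None, :],
        np.clip(weights[:, None] * rate_of_sample[None, :], 0.0, 0.9),
        rate_of_sample[None, :])
    planted = rng.random((config.n_genes, n_samples)) < p_plant  # genes x samples

    gi, si = np.nonzero(planted)
    planted_calls = pd.DataFrame({
        "sample": sheet["sample_id"].to_numpy()[si],
        "gene": genes[gi],
        "tissue": tissue_of[si],
        "role": role_of[si],
        "cell_model": sheet["cell_model"].to_numpy()[si],
        "healthy_leak": role_of[si] == "test_control",
    }).sort_values(["sample", "gene"], ignore_index=True)

    # --- beta values ------------------------------------------------------
    tissue_index = {t: i for i, t in enumerate(config.tissues)}
    t_of_sample = np.array([tissue_index[t] for t in tissue_of])
    baseline_means = np.clip(
        config.beta_background_mean
        + rng.normal(0.0, config.tissue_offset_sd, size=(config.n_genes, len(config.tissues))),
        0.02, 0.30)

    mean_gs = baseline_means[:, t_of_sample]                       # genes x samples
    mean_gs = np.where(planted, config.beta_hyper_mean, mean_gs)
    conc_gs = np.where(planted, config.beta_hyper_concentration,
                       config.beta_background_concentration)

    mean_ps = mean_gs[gene_idx_of_probe, :]                        # real probes x samples
    conc_ps = conc_gs[gene_idx_of_probe, :]
    # decoy probes: uninformative noisy signal around 0.5
    decoy_mean = np.full((n_decoy, n_samples), 0.5)
    decoy_conc = np.full((n_decoy, n_samples), 4.0)
    mean_all = np.vstack([mean_ps, decoy_mean])
    conc_all = np.vstack([conc_ps, decoy_conc])

    a, b = _beta_params(mean_all, conc_all)
    beta = rng.beta(a, b)

    # missingness and detection-p artifacts
    beta[rng.random(beta.shape) < config.missing_rate] = np.nan
    detection_p = rng.uniform(0.0, 0.005, size=beta.shape)
    fail_cells = rng.random(beta.shape) < config.detection_fail_cell_rate
    detection_p[fail_cells] = rng.uniform(0.011, 0.5, size=int(fail_cells.sum()))
    # a handful of probes fail in enough samples to be removed outright
    failed_probes = rng.choice(n_real, size=min(config.n_failed_probes, n_real),
                               replace=False)
    for p in failed_probes:
        fail_in = rng.random(n_samples) < config.failed_probe_fail_fraction
        detection_p[p, fail_in] = rng.uniform(0.011, 0.5, size=int(fail_in.sum()))

    probe_ids = annotation["probe_id"].to_numpy()
    sample_ids = sheet["sample_id"].to_numpy()
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=sample_ids)
    beta_df.index.name = "probe_id"
    detection_df = pd.DataFrame(detection_p, index=probe_ids, columns=sample_ids)
    detection_df.index.name = "probe_id"

    # --- per-gene effects and focal genes ---------------------------------
    cancer_planted = planted[:, role_of == "cancer"]
    carriers = cancer_planted.sum(axis=1)
    order = np.lexsort((genes, -carriers))  # most carriers first, ties by symbol
    clinical_gene = str(genes[order[0]])
    inverted_genes = [str(genes[i]) for i in order[1:1 + config.n_inverted_genes]]
    gene_effects = pd.DataFrame({
        "gene": genes,
        "weight": weights,
        "n_planted_cancer": carriers,
        "silencing_factor": config.expression_silencing_factor,
        "inverted": np.isin(genes, inverted_genes),
    })

    # realized promoter mean of the focal (clinical) gene in drug-tissue cell
    # lines, used later to generate correlated IC50 z-scores
    drug_gene = clinical_gene
    drug_mask = (sheet["tissue"] == config.drug_tissue) & (sheet["cell_model"] == "cell_line") \
        & (sheet["role"] == "cancer")
    drug_samples = sheet.loc[drug_mask, "sample_id"].to_numpy()
    g_idx = int(np.nonzero(genes == drug_gene)[0][0])
    probe_rows = np.nonzero(gene_idx_of_probe == g_idx)[0]
    drug_beta = pd.Series(
        np.nanmean(beta[np.ix_(probe_rows, np.nonzero(drug_mask.to_numpy())[0])], axis=0),
        index=drug_samples, name="promoter_beta")

    primary_mask = (sheet["cell_model"] == "primary") & (sheet["role"] == "cancer")
    survival_group = pd.Series(index=sheet.loc[primary_mask, "sample_id"].to_numpy(),
                               dtype=object, name="survival_group")
    low = set(planted_calls.loc[(planted_calls["gene"] == clinical_gene)
                                & (planted_calls["role"] == "cancer"), "sample"])
    survival_group[:] = ["low" if s in low else "high" for s in survival_group.index]

    truth = SimTruth(
        planted_calls=planted_calls,
        gene_effects=gene_effects,
        survival_group=survival_group,
        drug_gene=drug_gene,
        clinical_gene=clinical_gene,
        inverted_genes=inverted_genes,
        drug_gene_beta=drug_beta,
        baseline_means=pd.DataFrame(baseline_means, index=genes, columns=list(config.tissues)),
        blocklist_cross_reactive=blocklist_cr,
        blocklist_snp=blocklist_snp,
        detection_p=detection_df,
        sheet=sheet,
        config=config,
    )
    return beta_df, sheet, annotation, truth


def simulate_expression(truth: SimTruth, config: SimConfig | None = None) -> pd.DataFrame:
    """Log-normal expression, silenced in epimutated carriers.

    Carriers of a planted epimutation in gene g have expression multiplied by
    the silencing factor; for "inverted" genes the factor's reciprocal is used
    (promoter methylation positively coupled to expression). Only a random
    subset of samples (``expression_fraction``) receives expression, emulating
    matched-data availability. Returns a gene x sample DataFrame with
    ``attrs["unit_tag"] = "simulated"``.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1_000_003)
    genes = truth.gene_effects["gene"].to_numpy()
    samples = truth.sheet["sample_id"].to_numpy()
    n_g, n_s = len(genes), len(samples)

    mu = rng.normal(config.expression_log_mean, config.expression_gene_log_sd, size=n_g)
    log_expr = rng.normal(mu[:, None], config.expression_sample_log_sd, size=(n_g, n_s))

    factor = np.where(truth.gene_effects["inverted"].to_numpy(),
                      1.0 / config.expression_silencing_factor,
                      config.expression_silencing_factor)
    g_pos = {g: i for i, g in enumerate(genes)}
    s_pos = {s: i for i, s in enumerate(samples)}
    for _, row in truth.planted_calls.iterrows():
        gi, si = g_pos[row["gene"]], s_pos[row["sample"]]
        log_expr[gi, si] += np.log(factor[gi])

    keep = rng.random(n_s) < config.expression_fraction
    expr = pd.DataFrame(np.exp(log_expr[:, keep]), index=genes, columns=samples[keep])
    expr.index.name = "gene"
    expr.attrs["unit_tag"] = "simulated"
    return expr


def simulate_clinical(truth: SimTruth, config: SimConfig | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(survival table, drug-response table) consistent with the truth.

    Survival: exponential event times for primary tumours, hazard multiplied
    by the configured ratio in the low-expression group, with independent
    exponential censoring. Drug response: per (cell line, compound) IC50
    z-scores built as promoter beta plus Gaussian noise whose variance is
    calibrated so the population correlation is ``drug_rho``, then
    standardized per compound.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 2_000_003)

    group = truth.survival_group
    n = len(group)
    hazard = config.survival_base_rate * np.where(
        group.to_numpy() == "low", config.survival_hr_low_expression, 1.0)
    event_t = rng.exponential(1.0 / hazard)
    censor_t = rng.exponential(1.0 / config.censoring_rate, size=n)
    survival = pd.DataFrame({
        "sample_id": group.index,
        "time": np.minimum(event_t, censor_t),
        "event": (event_t <= censor_t).astype(int),
    })

    beta = truth.drug_gene_beta
    if len(beta) == 0:
        return survival, pd.DataFrame(
            columns=["cell_line", "compound", "ic50_z", "pathway"])
    # IC50 increases monotonically with promoter methylation. Methylation is
    # near-constant with rare hypermethylated outliers, so additive noise on
    # the raw beta scale cannot hit a rank-correlation target; instead the
    # signal is the normal score of the methylation rank, and the noise
    # variance comes from the exact bivariate-normal relation
    # rho_spearman = (6/pi) asin(r/2)  <=>  r = 2 sin(pi rho / 6).
    ranks = stats_rankdata(beta.to_numpy())
    scores = _norm_ppf((ranks - 0.5) / len(beta))
    r = 2.0 * np.sin(np.pi * config.drug_rho / 6.0)
    sigma_noise = np.sqrt(max(1.0 / r**2 - 1.0, 1e-12))
    rows = []
    for compound in config.drug_compounds:
        z = scores + rng.normal(0.0, sigma_noise, size=len(beta))
        z = (z - z.mean()) / max(z.std(ddof=1), 1e-12)
        for line, zi in zip(beta.index, z):
            rows.append((line, compound, zi, config.drug_pathway))
    drugs = pd.DataFrame(rows, columns=["cell_line", "compound", "ic50_z", "pathway"])
    return survival, drugs
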