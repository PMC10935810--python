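# epimut

Promoter hypermethylation ("epimutation") discovery for methylation-array
cohorts: from probe-level beta values and promoter annotation, through probe
QC and per-promoter aggregation, to outlier calls against healthy-tissue
baselines, tissue-distribution statistics, gene-set enrichment,
methylation–expression silencing tests and clinical correlates (survival,
drug sensitivity).

The package is aimed at cancer epigenomics analysts working with
450K-style array data (or anything reducible to a probes × samples beta
matrix) who want a tested, scriptable implementation of the epimutation
workflow — plus a synthetic-cohort generator with known planted truth, so
every stage can be validated end-to-end without downloading any cohort.

## The method

DNA methylation at a CpG is summarised as a beta value
β = M / (M + U) ∈ [0, 1]. For each gene *g*, promoter probes are those in
the TSS1500/TSS200 windows (within 1500 / 200 bp upstream of the
transcription start site), the 5′UTR or the first exon. The calling unit is
the **promoter mean** β̄(g, s) over a gene's non-missing promoter probes in
sample *s*, and the per-tissue healthy baseline is the mean of β̄ over that
tissue's baseline-control samples. An **epimutation** is called when

```
Δ(g, s) = β̄(g, s) − baseline(g, tissue(s)) > τ
```

with τ = 0.66 in cancer cell lines (cellular homogeneity sharpens
outliers) and τ = 0.33 in primary tumours and organoids (mixed cell
populations dilute the signal); independent healthy *test* controls are
screened at τ = 0.33.

Cohort-level statistics include the observed epimutation distribution
ratio per tissue,

```
OEDR(t) = log2( epimutation share of t / sample share of t ),
```

zero under an even distribution and positive for over-represented tissues;
carrier-frequency classes (*rare* < 1 %, *recurrent* > 5 % of cancer
samples); 2×2 contingency enrichment (two-sided Fisher exact +
chi-squared); and hypergeometric gene-set enrichment over GMT files with
Benjamini–Hochberg correction. Downstream, expression is compared between
hypermethylated and comparison samples with a Wilcoxon rank-sum test
(exact for small groups), survival by expression quartile uses
Kaplan–Meier / log-rank / univariate Cox (Efron ties), and promoter
methylation is correlated with IC50 z-scores pooled over a compound set
(Spearman + OLS slope).

The synthetic generator (`simulate_cohort`) emulates the study design it is
meant to test: five tissues, three cancer cell models, per-tissue baseline
and test controls, ~11 promoter probes per gene, beta-distributed
methylation with planted hypermethylation (background mean 0.10 → planted
mean 0.85), decoy probes for the QC rules, carrier-silenced expression with
one positively-coupled exception, exponential survival with a
hazard-ratio-2 low-expression group, and IC50 z-scores whose population
Spearman correlation with promoter methylation is calibrated to 0.3.

## Worked example

`examples/01_simulate_and_call.py` simulates the default cohort, runs QC and
calls epimutations:

```
cohort: 794 samples, 5976 probes, 3207 planted epimutations
QC: 5976 -> 5651 probes (sex 150, cross-reactive 80, SNP 80, failed detection 15)
promoter map: 523 genes, 5397 promoter probes (median 10/gene, 53% on CpG islands)
calls: 3182 in cancer samples, 25 in healthy tests
recovery vs planted truth: sensitivity 1.000, false-call rate 0.000
```

The planted effect (Δβ ≈ 0.75) sits far above both calling margins, so the
caller recovers essentially every planted event without false calls.
`examples/02_cohort_statistics.py` then reports the tissue distribution —

```
    tissue  n_samples  sample_share  n_calls  epimutation_share  oedr_log2
colorectum        155         0.220      775              0.244      0.148
      lung        156         0.221      294              0.092     -1.260
oesophagus        131         0.186      694              0.218      0.231
  pancreas        135         0.191      412              0.129     -0.565
   stomach        128         0.182     1007              0.316      0.802

median epimutations per cancer sample: 4; 95% of samples carry at least one
```

— stomach over-represented and lung under-represented, with a median of 4
epimutations per cancer sample. `examples/03_expression_silencing.py` shows
carriers expressing less (rank-sum direction −1) for every top gene except
the inverted one, and `examples/04_survival_and_drug.py` prints the
quartile-split survival analysis and the pooled methylation–IC50
association (Spearman ρ ≈ 0.3).

A thin CLI mirrors the stages: `epimut simulate | qc | call | stats |
expression | clinical | run` (see `epimut --help`); `epimut run --config
config.yaml --out-dir run/` executes the whole pipeline and writes a
manifest with the config, seed and per-stage row counts.

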