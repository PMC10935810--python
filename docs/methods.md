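# Methods

## Calling model

The unit of analysis is the gene promoter, not the probe. Promoter probes
are the array probes annotated to a gene's TSS1500, TSS200, 5′UTR or
first-exon regions; coordinates are 1-based with closed intervals, the TSS
itself counts as upstream distance 0 (hence TSS200), and when several
windows contain a probe the precedence is TSS200 > TSS1500 > 5′UTR >
first exon — the array manifest convention of one label per probe–gene
pair. A probe annotated to several genes contributes to each gene's
promoter independently. Genes without any promoter probe are recorded as
exclusions rather than dropped, since "no data" and "no signal" must stay
distinguishable downstream.

Promoter methylation is the arithmetic mean of non-missing probe betas;
cells with zero contributing probes are missing, never zero. Baselines are
arithmetic means over the tissue's baseline-control samples and are never
pooled across tissues, because healthy methylation levels differ by tissue.
A call requires the delta over baseline to *strictly* exceed the margin:
0.66 for cancer cell lines, 0.33 for primary tumours and organoids, and
0.33 for the healthy test cohort. Strict inequality follows the
healthy-test definition ("> 0.33") and is applied uniformly; at these
margins the choice is immaterial in practice. Because both margins compare
the same delta, every 0.66-call is also a 0.33-call (threshold
monotonicity), which the tests exploit as an invariant.

## QC

Probe exclusion is the union of: detection failure (cells with detection
p > 0.01 are always masked to missing; the probe is removed outright when
the failing fraction reaches `fail_fraction`, default 5 % of samples —
masking alone handles sporadic failures, removal handles systematically bad
probes), external cross-reactive and SNP-adjacent blocklists (published
lists are inputs, not recomputed), chromosomes X/Y, and probes missing from
the annotation (reported under their own rule so upstream bookkeeping
errors surface). Per-rule counts may overlap; a probe is removed once.
Inputs are assumed to be normalized betas — background correction and
dye-bias normalization are upstream of this package's contract, as is
mislabel detection (replaced here by cohort-sheet validation).

## Cohort statistics

OEDR is reported as log2(epimutation share / sample share), oriented so
over-represented tissues are positive. Tissues with zero calls are reported
with a `zero_calls` flag and a missing log-ratio rather than −∞. Carrier
counting is by distinct samples per gene; frequency bounds are exclusive
(rare < 1 %, recurrent > 5 %). The two-sided Fisher p uses
probability-mass ordering (the common convention); the chi-squared
companion test carries no continuity correction; odds ratios use the
Haldane–Anscombe +0.5 correction when a cell is zero, flagged as such.
Gene-set enrichment is a hypergeometric upper tail over user-supplied GMT
sets intersected with the analysis universe, corrected with
Benjamini–Hochberg (no rank-based combined scores).

## Expression and clinical analyses

Expression comparisons default to the Wilcoxon rank-sum test: exact when
both groups have ≤ 10 samples, otherwise the normal approximation with tie
correction. An automatic mode routes to a two-sample t-test only when both
groups pass Shapiro–Wilk at α = 0.05, and logs the decision. Spearman p
uses exact enumeration of rank permutations when n ≤ 9 and ranks are
tie-free. Expression matrices carry a unit tag (FPKM / TPM / simulated);
cohorts with different tags are never pooled into one test. No
multiple-testing correction is applied across small, hand-picked gene
panels; BH is available for genome-wide runs.

"Top/bottom 25 % quartile" splits use group sizes of ⌊n/4⌋ with ties broken
by stable sample-id order, so the split is deterministic; a constant vector
is flagged degenerate with all samples excluded. Kaplan–Meier, log-rank and
the univariate Cox model are computed with lifelines; Cox ties use Efron's
method (lifelines' and R coxph's default, and the more accurate
approximation — with no tied event times it coincides with Breslow, which
the grid-search oracle test verifies). Confidence intervals are Wald.
Drug association pools (cell line, compound) pairs across a same-pathway
compound set by default — a per-compound mode exists — and reports Spearman
rho plus an OLS slope, requiring ≥ 5 pairs and flagging constant
methylation.

## Synthetic cohort generator

The generator emulates the multi-tissue case/control design the analysis is
built for; its defaults are the cohort conditions, chosen once:

- **Samples** — five tissues with per-tissue counts
  (primary/cell-line/organoid/baseline/test): colorectum 95/49/11/10/16,
  oesophagus 92/35/4/8/8, lung 94/61/1/10/16, pancreas 97/31/7/4/5,
  stomach 98/28/2/10/2 (705 cancer samples, 42 baseline and 47 test
  controls).
- **Probes** — 523 genes with 1 + Poisson(10) promoter probes each (median
  11); region classes drawn with probabilities TSS1500 0.30, TSS200 0.21,
  5′UTR 0.29, first exon 0.13, other 0.07; CpG-island flag at 0.52. Decoy
  probes give QC real work: 150 sex-chromosome probes, 80 cross-reactive
  and 80 SNP-adjacent probes attached to real genes with noisy
  (mean 0.5, low-concentration) signal, 15 probes failing detection in 10 %
  of samples, 0.2 % random failing cells, 1 % missing cells.
- **Methylation** — beta-distributed (respects [0, 1] and array-data
  convention): background mean 0.10, concentration 50, plus a per-(tissue,
  gene) baseline offset (SD 0.02) so baselines genuinely differ by tissue;
  planted hypermethylation mean 0.85, concentration 50, applied to *all*
  probes of the gene (the promoter is the calling unit). The planted
  Δβ ≈ 0.75 clears both calling margins.
- **Planting** — per-tissue per-gene rates {colorectum 0.010, oesophagus
  0.010, lung 0.0035, pancreas 0.006, stomach 0.015}, scaled by per-gene
  Gamma(3)-distributed weights (mean 1) for heterogeneous recurrence. The
  rates were chosen so the expected OEDR spread spans roughly −1.3 to +0.6
  with lung under- and stomach over-represented; the realized default
  cohort shows a median of 4 epimutations per cancer sample. The gene-weight
  tail is light, so very-high-recurrence genes (> 5 % carriers) are rarer
  here than in real tumour cohorts, where a few tumour suppressors dominate.
  Healthy-test leaks are planted at rate 0.005 per (sample, gene),
  restricted to oesophagus and pancreas.
- **Expression** — log-normal (per-gene log-mean ~ N(3, 1), within-gene log
  SD 0.5), multiplied by the silencing factor 0.15 in carriers; one
  "inverted" gene (the second-most planted) uses the reciprocal, giving a
  positive methylation–expression coupling. A random 80 % of samples
  receive expression, emulating matched-data availability. Units are a
  single arbitrary relative scale; the FPKM/TPM distinction is modelled
  only as a unit tag that forbids cross-cohort pooling.
- **Survival** — exponential event times for primary tumours at base rate
  0.001/day, hazard ×2 for the low-expression group (carriers of the focal
  gene, whose expression the generator silences), with independent
  exponential censoring (rate 0.0005).
- **Drug response** — IC50 z-scores for four same-pathway compounds in the
  31 pancreas cell lines. Because promoter methylation is near-constant
  with rare hypermethylated outliers, additive noise on the raw beta scale
  cannot achieve a target *rank* correlation; the generator instead adds
  Gaussian noise to the normal scores of the methylation ranks, with noise
  variance from the exact bivariate-normal identity
  ρ_spearman = (6/π)·asin(r/2). This is monotone in methylation and hits
  the configured population Spearman (0.3) regardless of the methylation
  distribution's shape.

Everything is a deterministic function of the seed; expression and clinical
tables use fixed offsets of the same seed so the three generators can be
re-run independently.

### What passing tests do and do not show

The generator produces clean, well-separated planted effects: near-perfect
caller recovery on it demonstrates correctness of the aggregation,
baseline and thresholding logic, not sensitivity on real tumours, where
cell-type admixture, copy-number artefacts, batch effects and borderline
deltas dominate the error budget. Likewise the silencing and survival
effects are generated exactly under the tested models (log-normal shifts,
proportional exponential hazards), so the power figures measured here are
upper bounds for real data.

## Numerical and design choices

- Test problem sizes: the full default cohort (794 samples × ~6,000
  probes) for caller recovery; 100-seed loops for power/recovery checks
  (Cox at n = 200, rank-sum at 20 vs 20, drug correlation at 31 lines ×
  4 compounds); exhaustive oracle sweeps for Fisher (all 2×2 tables with
  grand total ≤ 40, via symmetry-orbit representatives after verifying the
  two-sided p is invariant under transpose and row/column swaps) and for
  the rank-sum test (full enumeration up to 10 vs 10).
- The carrier-fraction recovery test compares realized per-tissue carrier
  fractions against the exact product expectation 1 − Π_g(1 − rate·w_g)
  with a band of max(3 points, 4 binomial SD), since a fixed ±3-point band
  would be ~1 SD for the lung tissue and reject a correct generator about
  a third of the time.
- Degenerate inputs: all-probe-missing promoter cells are missing, not 0;
  zero-variance vectors are flagged (correlation) or rejected
  (Shapiro–Wilk, Cox covariate); zero-call tissues are flagged; an
  all-zero 2×2 table is an error.
- Outputs are deterministic: writers sort rows and use a fixed float
  format, so two runs with the same config and seed produce byte-identical
  TSVs, and the pipeline skips re-running when the manifest's config hash
  matches (`--force` overrides).

## Known limitations

- No idat parsing, normalization (ssNoob or otherwise), probe-type
  chemistry correction, or EPIC support: inputs are normalized betas.
- No hypomethylation calling, probe-level calling or copy-number-aware
  correction.
- Cross-reactive / SNP blocklists must be supplied; they are not derived.
- Survival is univariate only (no multivariate Cox, competing risks or
  time-varying covariates).
- The gene-set enrichment is a plain hypergeometric test, not a rank-based
  combined score; results are qualitative guidance, not pathway inference.
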