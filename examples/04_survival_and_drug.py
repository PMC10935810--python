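"""Clinical correlates: survival by expression quartile and drug sensitivity.

Primary-tumour patients are split into top/bottom expression quartiles of the
focal silenced gene; overall survival is compared with Kaplan-Meier,
log-rank and a univariate Cox model (the generator gives the low-expression
group a hazard ratio of 2). IC50 z-scores of four same-pathway compounds are
pooled and correlated with promoter methylation in the 31 pancreatic cancer
cell lines (population Spearman calibrated to 0.3).
"""

import pandas as pd

import epimut as em

config = em.SimConfig(seed=1)
beta, sheet, annotation, truth = em.simulate_cohort(config)
expr = em.simulate_expression(truth, config)
survival, drugs = em.simulate_clinical(truth, config)

gene = truth.clinical_gene
surv = survival.set_index("sample_id")
eligible = [s for s in surv.index if s in expr.columns]
labels = em.quartile_groups(expr.loc[gene, eligible])
keep = labels[labels != "excluded"].index
records = surv.loc[keep, ["time", "event"]].reset_index(drop=True)
group = pd.Series((labels[keep] == "low").astype(int).to_numpy())

km = em.km_estimate(surv.loc[keep].reset_index())
chi2, p = em.logrank_test(records, group)
cox = em.cox_univariate(records, group.to_numpy(dtype=float))
print(f"survival by {gene} expression quartile "
      f"(n = {len(keep)}, {int(records['event'].sum())} events):")
print(f"  log-rank chi2 = {chi2:.2f}, p = {p:.3g}")
print(f"  Cox HR (low vs high expression) = {cox.hr:.2f} "
      f"(95% CI {cox.ci_low:.2f}-{cox.ci_high:.2f}), p = {cox.p:.3g}")
print(f"  KM curve: {len(km)} steps, S(median follow-up) = "
      f"{km['survival'].iloc[len(km) // 2]:.2f}")
# the quartile split dilutes the effect: only carriers of the epimutation are
# silenced and at elevated hazard, and they make up part of the low quartile.
# Scoring the generator's true high/low groups directly recovers the HR of 2:
true_group = truth.survival_group.reindex(surv.index).dropna()
records_all = surv.loc[true_group.index, ["time", "event"]].reset_index(drop=True)
cox_true = em.cox_univariate(records_all, (true_group == "low").astype(float).to_numpy())
print(f"  Cox HR on the generator's true low-expression group = "
      f"{cox_true.hr:.2f} (95% CI {cox_true.ci_low:.2f}-{cox_true.ci_high:.2f})")

filtered, _ = em.filter_probes(
    beta, detection_p=truth.detection_p,
    blocklist_cross_reactive=truth.blocklist_cross_reactive,
    blocklist_snp=truth.blocklist_snp, annotation=annotation)
pmap = em.build_promoter_map(annotation, [gene])
pm = em.promoter_beta(filtered, pmap)
assoc = em.drug_sensitivity_assoc(pm, drugs, gene, list(config.drug_compounds))
print(f"\ndrug sensitivity vs {gene} promoter methylation "
      f"({assoc.n_pairs} cell line x compound pairs):")
print(f"  Spearman rho = {assoc.rho:.2f} (p = {assoc.rho_p:.3g}); "
      f"OLS slope = {assoc.slope:.2f} (p = {assoc.slope_p:.3g})")
# positive rho: more methylation, higher IC50 — methylated lines are less
# sensitive to the pathway-targeting compounds.
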