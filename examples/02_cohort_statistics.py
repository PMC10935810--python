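"""Tissue distribution (OEDR), prevalence, frequency classes and enrichment.

OEDR = log2(tissue's share of epimutations / tissue's share of samples):
0 under an even distribution, positive for over-represented tissues. The
generator's per-tissue planting rates make stomach over- and lung
under-represented, echoing the pattern seen in real pan-cancer cohorts.
"""

import epimut as em

config = em.SimConfig(seed=1)
beta, sheet, annotation, truth = em.simulate_cohort(config)
filtered, _ = em.filter_probes(
    beta, detection_p=truth.detection_p,
    blocklist_cross_reactive=truth.blocklist_cross_reactive,
    blocklist_snp=truth.blocklist_snp, annotation=annotation)
pmap = em.build_promoter_map(annotation, truth.gene_effects["gene"].tolist())
pm = em.promoter_beta(filtered, pmap)
baseline = em.tissue_baseline(pm, sheet)
calls = em.call_epimutations(pm, baseline, sheet)

print(em.oedr(calls.calls, sheet).round(3).to_string(index=False))

prev = em.prevalence_summary(calls.calls, sheet)
print(f"\nmedian epimutations per cancer sample: {prev.median_calls:.0f}; "
      f"{prev.carrier_fraction:.0%} of samples carry at least one")
print("calls of the top-10% most-epimutated individuals, by tissue:")
print(prev.top_decile_attribution.round(3).to_string())

n_cancer = int((sheet["role"] == "cancer").sum())
freq = em.classify_frequency(calls.calls, n_cancer)
print("\nfrequency classes (rare < 1%, recurrent > 5% of cancer samples):")
print(freq["class"].value_counts().to_string())

print("\nten most-epimutated genes (overall carrier fraction):")
print(em.top_epimutated(calls.calls, sheet, k=10).round(3).to_string(index=False))

# hypergeometric gene-set enrichment: take the 50 most-epimutated genes as
# hits; a gene set built from the generator's highest planting weights is
# strongly enriched, an arbitrary set of symbols is not
universe = set(truth.gene_effects["gene"])
hits = set(em.top_epimutated(calls.calls, sheet, k=50)["gene"])
by_weight = truth.gene_effects.sort_values("weight", ascending=False)
gene_sets = {
    "high_planting_weight": set(by_weight["gene"].head(50)),
    "arbitrary_50": set(sorted(universe)[:50]),
}
print("\ngene-set enrichment of the 50 most-epimutated genes:")
print(em.geneset_enrichment(hits, gene_sets, universe).to_string(index=False))
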