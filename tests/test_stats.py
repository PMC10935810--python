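"""Tissue-distribution statistics, frequency classes and enrichment tests."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epimut as em


def _sheet_with_counts(counts, role="cancer"):
    rows = []
    for tissue, n in counts.items():
        for i in range(n):
            rows.append((f"{tissue}_{i}", tissue, role, "primary"))
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "role", "cell_model"])


def _calls(counts):
    rows = []
    for tissue, n in counts.items():
        for i in range(n):
            rows.append((f"{tissue}_{i % 3}", f"GENE{i:03d}", tissue))
    return pd.DataFrame(rows, columns=["sample", "gene", "tissue"])


class TestOEDR:
    def test_stomach_style_worked_example(self):
        """Shares 27% calls / 18% samples give log2 OEDR ~ 0.585."""
        sheet = _sheet_with_counts({"stomach": 18, "colorectum": 22,
                                    "oesophagus": 20, "lung": 22, "pancreas": 18})
        calls = _calls({"stomach": 27, "colorectum": 20, "oesophagus": 18,
                        "lung": 17, "pancreas": 18})
        table = em.oedr(calls, sheet).set_index("tissue")
        assert table.at["stomach", "sample_share"] == pytest.approx(0.18)
        assert table.at["stomach", "epimutation_share"] == pytest.approx(0.27)
        assert table.at["stomach", "oedr_log2"] == pytest.approx(0.584963, abs=1e-5)

    def test_even_distribution_is_zero_everywhere(self):
        sheet = _sheet_with_counts({"a": 10, "b": 10})
        calls = _calls({"a": 6, "b": 6})
        table = em.oedr(calls, sheet)
        assert np.allclose(table["oedr_log2"], 0.0)

    def test_under_represented_tissue_is_negative(self):
        """Shares 9% vs 22% give log2(9/22) ~ -1.29."""
        sheet = _sheet_with_counts({"lung": 22, "stomach": 78})
        calls = _calls({"lung": 9, "stomach": 91})
        table = em.oedr(calls, sheet).set_index("tissue")
        assert table.at["lung", "oedr_log2"] == pytest.approx(np.log2(9 / 22), abs=1e-9)
        assert table.at["lung", "oedr_log2"] == pytest.approx(-1.2895, abs=1e-3)

    def test_shares_sum_to_one_and_zero_call_tissue_flagged(self):
        sheet = _sheet_with_counts({"a": 10, "b": 10, "c": 5})
        calls = _calls({"a": 6, "b": 3})
        table = em.oedr(calls, sheet)
        assert table["sample_share"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["epimutation_share"].sum() == pytest.approx(1.0, abs=1e-9)
        c_row = table.set_index("tissue").loc["c"]
        assert c_row["zero_calls"] and np.isnan(c_row["oedr_log2"])
        assert table["n_calls"].sum() == len(calls)

    def test_no_calls_is_an_error(self):
        sheet = _sheet_with_counts({"a": 3})
        with pytest.raises(ValueError, match="no calls"):
            em.oedr(pd.DataFrame(columns=["sample", "gene", "tissue"]), sheet)


class TestPrevalence:
    def test_median_and_carrier_fraction(self):
        sheet = _sheet_with_counts({"a": 4})
        calls = pd.DataFrame({
            "sample": ["a_2"] * 4 + ["a_3"] * 8,
            "gene": [f"G{i}" for i in range(12)],
            "tissue": "a"})
        prev = em.prevalence_summary(calls, sheet)
        assert sorted(prev.per_sample) == [0, 0, 4, 8]
        assert prev.median_calls == 2.0
        assert prev.carrier_fraction == 0.5

    def test_all_zero_calls(self):
        sheet = _sheet_with_counts({"a": 5})
        calls = pd.DataFrame(columns=["sample", "gene", "tissue"])
        prev = em.prevalence_summary(calls, sheet)
        assert prev.median_calls == 0.0 and prev.carrier_fraction == 0.0

    def test_median_matches_brute_force_recount(self, called_cohort):
        calls = called_cohort["calls"].calls
        sheet = called_cohort["sheet"]
        prev = em.prevalence_summary(calls, sheet)
        # independent recount straight from the call records
        counts = {}
        for s in sheet.loc[sheet["role"] == "cancer", "sample_id"]:
            counts[s] = 0
        for s in calls["sample"]:
            counts[s] += 1
        assert prev.median_calls == float(np.median(sorted(counts.values())))
        assert prev.top_decile_attribution.sum() == pytest.approx(1.0)


class TestFrequencyClasses:
    @pytest.mark.parametrize("carriers,n,expected", [
        (3, 705, "rare"),            # 0.43%
        (40, 705, "recurrent"),      # 5.7%
        (20, 705, "intermediate"),   # 2.8%
        (7, 705, "rare"),            # 0.993%, still below the 1% bound
        (1, 100, "intermediate"),    # exactly 1% is not rare (bounds exclusive)
        (5, 100, "intermediate"),    # exactly 5% is not recurrent
    ])
    def test_boundaries(self, carriers, n, expected):
        calls = pd.DataFrame({"sample": [f"s{i}" for i in range(carriers)],
                              "gene": "G1", "tissue": "a"})
        out = em.classify_frequency(calls, n)
        assert out.iloc[0]["class"] == expected

    def test_partition_property(self, called_cohort):
        calls = called_cohort["calls"].calls
        sheet = called_cohort["sheet"]
        n_cancer = int((sheet["role"] == "cancer").sum())
        out = em.classify_frequency(calls, n_cancer)
        assert set(out["gene"]) == set(calls["gene"])
        assert out["class"].isin(["rare", "intermediate", "recurrent"]).all()
        assert not out["gene"].duplicated().any()

    def test_duplicate_calls_count_distinct_samples(self):
        calls = pd.DataFrame({"sample": ["s1", "s1"], "gene": "G1", "tissue": "a"})
        out = em.classify_frequency(calls, 100)
        assert out.iloc[0]["n_carriers"] == 1


class TestTopEpimutated:
    def test_ranking_and_tie_break(self):
        sheet = _sheet_with_counts({"a": 10})
        calls = pd.DataFrame({
            "sample": ["a_0", "a_1", "a_2", "a_3", "a_0"],
            "gene": ["GENEZ", "GENEZ", "GENEZ", "GENEB", "GENEA"],
            "tissue": "a"})
        top = em.top_epimutated(calls, sheet, k=3)
        assert list(top["gene"]) == ["GENEZ", "GENEA", "GENEB"]
        assert top["carrier_fraction"].tolist() == [0.3, 0.1, 0.1]

    def test_most_planted_gene_ranks_first(self, called_cohort):
        """The gene given the most planted carriers tops the ranking."""
        truth = called_cohort["truth"]
        best = truth.gene_effects.sort_values(
            ["n_planted_cancer", "gene"], ascending=[False, True]).iloc[0]["gene"]
        top = em.top_epimutated(called_cohort["calls"].calls,
                                called_cohort["sheet"], k=1)
        assert top.iloc[0]["gene"] == best


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive two-sided Fisher p over all tables with the same margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denominator = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = [comb(r1, k) * comb(r2, c1 - k) / denominator for k in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-12))


class TestEnrichment2x2:
    def test_flat_table(self):
        res = em.enrichment_2x2(5, 5, 5, 5)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.fisher_p == pytest.approx(1.0)

    def test_perfect_association_matches_enumeration(self):
        res = em.enrichment_2x2(10, 0, 0, 10)
        assert res.fisher_p == pytest.approx(fisher_two_sided_oracle(10, 0, 0, 10),
                                             abs=1e-12)
        assert res.haldane_corrected

    @settings(max_examples=150, deadline=None)
    @given(st.tuples(st.integers(0, 12), st.integers(0, 12),
                     st.integers(0, 12), st.integers(0, 12))
           .filter(lambda t: sum(t) > 0))
    def test_fisher_matches_oracle_property(self, cells):
        a, b, c, d = cells
        res = em.enrichment_2x2(a, b, c, d)
        assert res.fisher_p == pytest.approx(fisher_two_sided_oracle(a, b, c, d),
                                             abs=1e-10)

    def test_study_scale_carrier_table_is_extreme(self):
        """A 593/112 vs 11/36 carrier table is overwhelmingly significant."""
        res = em.enrichment_2x2(593, 112, 11, 36)
        assert res.fisher_p < 1e-10
        assert res.odds_ratio > 1

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            em.enrichment_2x2(0, 0, 0, 0)


class TestGenesetEnrichment:
    def test_exact_hit_set_is_most_enriched(self):
        universe = {f"G{i}" for i in range(50)}
        sets = {"target": {f"G{i}" for i in range(5)},
                "decoy": {f"G{i}" for i in range(20, 30)}}
        hits = {f"G{i}" for i in range(5)}
        out = em.geneset_enrichment(hits, sets, universe).set_index("set")
        assert out.at["target", "overlap"] == 5
        assert out.at["target", "p"] < out.at["decoy", "p"]
        assert out.at["decoy", "overlap"] == 0
        assert out.at["decoy", "p"] == pytest.approx(1.0)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(9)
        universe = [f"G{i}" for i in range(200)]
        gene_set = {"s": set(universe[:40])}
        pvals = []
        for _ in range(300):
            hits = set(rng.choice(universe, size=20, replace=False))
            pvals.append(em.geneset_enrichment(hits, gene_set, set(universe))
                         .iloc[0]["p"])
        # hypergeometric upper-tail p is super-uniform (discrete); check the
        # rejection rate is not inflated and the bulk is spread out
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.10
        assert np.median(pvals) > 0.2

    def test_bh_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(2)
        universe = {f"G{i}" for i in range(100)}
        sets = {f"s{j}": set(rng.choice(sorted(universe), size=15, replace=False))
                for j in range(20)}
        hits = set(rng.choice(sorted(universe), size=10, replace=False))
        out = em.geneset_enrichment(hits, sets, universe).sort_values("p")
        assert (np.diff(out["q"]) >= -1e-12).all()

    def test_empty_universe_and_stray_hits_rejected(self):
        with pytest.raises(ValueError):
            em.geneset_enrichment({"G1"}, {}, set())
        with pytest.raises(ValueError):
            em.geneset_enrichment({"NOT_THERE"}, {}, {"G1"})
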