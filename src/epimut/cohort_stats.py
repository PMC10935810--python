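"""Cohort-level epimutation statistics.

Includes the observed epimutation distribution ratio (OEDR): for each tissue,
log2 of (the tissue's share of all epimutations) / (its share of all samples).
Under an even distribution every tissue's OEDR is 0; over-represented tissues
are positive. Also: per-sample prevalence summaries, rare/recurrent frequency
classification (<1% / >5% of cancer cases), gene rankings, 2x2 contingency
enrichment (Fisher exact + chi-squared) and hypergeometric gene-set
enrichment with Benjamini–Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

RARE_MAX_FRACTION = 0.01       # exclusive: rare  <=> fraction < 1%
RECURRENT_MIN_FRACTION = 0.05  # exclusive: recurrent <=> fraction > 5%


def _cancer_samples(sheet: pd.DataFrame, role: str = "cancer") -> pd.DataFrame:
    sheet = sheet.reset_index() if "sample_id" not in sheet.columns else sheet
    return sheet[sheet["role"] == role]


def oedr(calls: pd.DataFrame, sheet: pd.DataFrame, role: str = "cancer") -> pd.DataFrame:
    """Per-tissue OEDR records.

    ``calls`` is a call table with ``tissue`` and ``sample`` columns; sample
    shares are computed over sheet rows with the given role. Tissues with zero
    calls get ``epimutation_share`` 0, a missing ``oedr_log2`` and
    ``zero_calls = True``.
    """
    if len(calls) == 0:
        raise ValueError("no calls")
    samples = _cancer_samples(sheet, role)
    unknown = set(calls["tissue"]) - set(samples["tissue"])
    if unknown:
        raise ValueError(f"calls reference tissues absent from the sheet: {sorted(unknown)}")
    n_by_tissue = samples.groupby("tissue").size()
    calls_by_tissue = calls.groupby("tissue").size().reindex(n_by_tissue.index, fill_value=0)
    total_samples = int(n_by_tissue.sum())
    total_calls = int(calls_by_tissue.sum())

    out = pd.DataFrame({
        "tissue": n_by_tissue.index,
        "n_samples": n_by_tissue.to_numpy(),
        "sample_share": n_by_tissue.to_numpy() / total_samples,
        "n_calls": calls_by_tissue.to_numpy(),
        "epimutation_share": calls_by_tissue.to_numpy() / total_calls,
    })
    with np.errstate(divide="ignore"):
        out["oedr_log2"] = np.log2(out["epimutation_share"] / out["sample_share"])
    out["zero_calls"] = out["n_calls"] == 0
    out.loc[out["zero_calls"], "oedr_log2"] = np.nan
    return out.reset_index(drop=True)


@dataclass
class PrevalenceSummary:
    per_sample: pd.Series          # call count per sample, zeros included
    median_calls: float
    carrier_fraction: float        # fraction of samples with >= 1 call
    per_tissue: pd.DataFrame       # tissue, n_samples, n_calls, median, carrier_fraction
    top_decile_attribution: pd.Series  # tissue share of calls in the top-10% samples


def prevalence_summary(calls: pd.DataFrame, sheet: pd.DataFrame,
                       role: str = "cancer") -> PrevalenceSummary:
    """Per-sample epimutation burden over every sample of the role (zeros kept)."""
    samples = _cancer_samples(sheet, role)
    counts = (calls.groupby("sample").size()
              .reindex(samples["sample_id"], fill_value=0).astype(int))
    counts.index.name = "sample_id"

    tissue_of = samples.set_index("sample_id")["tissue"]
    per_tissue = []
    for tissue, members in tissue_of.groupby(tissue_of):
        c = counts.loc[members.index]
        per_tissue.append((tissue, len(c), int(c.sum()), float(c.median()),
                           float((c > 0).mean())))
    per_tissue = pd.DataFrame(per_tissue, columns=[
        "tissue", "n_samples", "n_calls", "median_calls", "carrier_fraction"])

    # the 10% most-epimutated individuals and which tissues their calls come from
    k = max(1, math.ceil(0.10 * len(counts)))
    top = counts.sort_values(ascending=False, kind="stable").index[:k]
    top_calls = calls[calls["sample"].isin(set(top))]
    if len(top_calls):
        attribution = top_calls.groupby("tissue").size() / len(top_calls)
    else:
        attribution = pd.Series(dtype=float)
    attribution.name = "share_of_top_decile_calls"

    return PrevalenceSummary(
        per_sample=counts,
        median_calls=float(counts.median()),
        carrier_fraction=float((counts > 0).mean()),
        per_tissue=per_tissue,
        top_decile_attribution=attribution,
    )


def classify_frequency(calls: pd.DataFrame, n_cancer_samples: int) -> pd.DataFrame:
    """Rare / intermediate / recurrent classification by distinct-carrier fraction."""
    if n_cancer_samples <= 0:
        raise ValueError("n_cancer_samples must be positive")
    carriers = calls.groupby("gene")["sample"].nunique()
    fraction = carriers / n_cancer_samples
    cls = np.where(fraction < RARE_MAX_FRACTION, "rare",
                   np.where(fraction > RECURRENT_MIN_FRACTION, "recurrent", "intermediate"))
    return pd.DataFrame({
        "gene": carriers.index,
        "n_carriers": carriers.to_numpy(),
        "carrier_fraction": fraction.to_numpy(),
        "class": cls,
    }).sort_values("gene", ignore_index=True)


def top_epimutated(calls: pd.DataFrame, sheet: pd.DataFrame, k: int,
                   role: str = "cancer") -> pd.DataFrame:
    """Top-k genes by overall carrier fraction, with per-tissue fractions.

    Ties in overall fraction are broken lexicographically by gene symbol.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    samples = _cancer_samples(sheet, role)
    n_total = len(samples)
    n_by_tissue = samples.groupby("tissue").size()

    overall = calls.groupby("gene")["sample"].nunique() / n_total
    ranked = overall.sort_index().sort_values(ascending=False, kind="stable").head(k)

    per_tissue = (calls.groupby(["gene", "tissue"])["sample"].nunique()
                  .unstack(fill_value=0)
                  .reindex(columns=n_by_tissue.index, fill_value=0)
                  .div(n_by_tissue, axis=1))
    out = pd.DataFrame({"gene": ranked.index, "carrier_fraction": ranked.to_numpy()})
    out = out.join(per_tissue.reindex(ranked.index).reset_index(drop=True))
    return out


@dataclass
class Enrichment2x2:
    odds_ratio: float
    fisher_p: float
    chi2_p: float
    haldane_corrected: bool


def enrichment_2x2(a: int, b: int, c: int, d: int) -> Enrichment2x2:
    """Fisher exact (two-sided, probability-mass ordering) and chi-squared
    (no continuity correction) for the table [[a, b], [c, d]].

    The odds ratio uses the Haldane–Anscombe +0.5 correction when any cell is
    zero (flagged).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells) or any(int(x) != x for x in cells):
        raise ValueError("cells must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("all-zero table")
    table = np.array([[a, b], [c, d]])
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    haldane = 0 in cells
    if haldane:
        a_, b_, c_, d_ = (x + 0.5 for x in cells)
    else:
        a_, b_, c_, d_ = cells
    odds = (a_ * d_) / (b_ * c_)
    margins_ok = table.sum(axis=0).all() and table.sum(axis=1).all()
    if margins_ok:
        chi2_p = float(stats.chi2_contingency(table, correction=False).pvalue)
    else:
        chi2_p = float("nan")
    return Enrichment2x2(odds_ratio=float(odds), fisher_p=fisher_p,
                         chi2_p=chi2_p, haldane_corrected=haldane)


def geneset_enrichment(hit_genes: set[str], gene_sets: dict[str, set[str]],
                       universe: set[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hit_genes`` in each gene set.

    Sets are intersected with the universe; p is the upper tail
    P(overlap >= observed); q is Benjamini–Hochberg across the sets.
    """
    if not universe:
        raise ValueError("empty universe")
    extra = set(hit_genes) - set(universe)
    if extra:
        raise ValueError(f"hit genes outside the universe: {sorted(extra)[:5]}")
    M, n = len(universe), len(hit_genes)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & set(universe)
        k = len(members & set(hit_genes))
        p = float(stats.hypergeom.sf(k - 1, M, len(members), n)) if members else 1.0
        rows.append((name, len(members), k, p))
    out = pd.DataFrame(rows, columns=["set", "n_set", "overlap", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    return out
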