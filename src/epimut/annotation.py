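"""Promoter probe annotation: region-class assignment, gene→probe promoter maps
and probe-coverage summaries.

A "promoter probe" for a gene is a 450K-style array probe whose interrogated
CpG falls within 1500 bp upstream of the transcription start site (split into
the TSS200 and TSS1500 windows), inside the 5'UTR, or inside the first exon.
Genes in the analysed universe that have no promoter probe on the array are
recorded as exclusions rather than dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REGION_CLASSES = ("TSS200", "TSS1500", "UTR5", "EXON1", "OTHER")
#: region classes that make a probe "promoter-associated"
PROMOTER_CLASSES = ("TSS200", "TSS1500", "UTR5", "EXON1")

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY"}

ANNOTATION_COLUMNS = ("probe_id", "chrom", "pos", "strand", "gene",
                      "region_class", "cpg_island")


class AnnotationError(ValueError):
    """Malformed probe annotation (bad interval, unknown class, ...)."""


def assign_region_class(
    probe_pos: int,
    tss_pos: int,
    strand: str,
    utr5: tuple[int, int] | None = None,
    exon1: tuple[int, int] | None = None,
    gene: str = "",
) -> str:
    """Classify a probe position relative to a gene's transcription start site.

    Coordinates are 1-based; intervals are closed. Upstream distance is
    strand-aware: on '+' upstream coordinates are smaller than the TSS, on '-'
    larger. The TSS itself counts as upstream distance 0 and therefore TSS200.
    When several windows apply the precedence is
    TSS200 > TSS1500 > UTR5 > EXON1.

    Parameters
    ----------
    probe_pos, tss_pos:
        1-based genomic coordinates of the interrogated CpG and the TSS.
    strand:
        '+' or '-'.
    utr5, exon1:
        Optional closed (start, end) intervals of the 5'UTR and first exon.
    gene:
        Used only to make error messages identifiable.

    Returns
    -------
    str
        One of ``REGION_CLASSES``.
    """
    if strand not in ("+", "-"):
        raise AnnotationError(f"gene {gene!r}: strand must be '+' or '-', got {strand!r}")
    for name, interval in (("utr5", utr5), ("exon1", exon1)):
        if interval is not None:
            start, end = interval
            if start > end:
                raise AnnotationError(
                    f"gene {gene!r}: malformed {name} interval ({start} > {end})")
    if probe_pos < 1 or tss_pos < 1:
        raise AnnotationError(f"gene {gene!r}: coordinates must be >= 1")

    upstream = tss_pos - probe_pos if strand == "+" else probe_pos - tss_pos
    if 0 <= upstream <= 200:
        return "TSS200"
    if 201 <= upstream <= 1500:
        return "TSS1500"
    if utr5 is not None and utr5[0] <= probe_pos <= utr5[1]:
        return "UTR5"
    if exon1 is not None and exon1[0] <= probe_pos <= exon1[1]:
        return "EXON1"
    return "OTHER"


@dataclass
class PromoterMap:
    """Gene → sorted unique promoter probe ids, plus explicit exclusions."""

    genes: dict[str, list[str]]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def all_probes(self) -> list[str]:
        """Unique probe ids across all mapped genes (a probe may serve several genes)."""
        seen: set[str] = set()
        for probes in self.genes.values():
            seen.update(probes)
        return sorted(seen)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check the annotation table schema and invariants; returns the table."""
    missing = [c for c in ("probe_id", "chrom", "pos", "gene", "region_class", "cpg_island")
               if c not in annotation.columns]
    if missing:
        raise AnnotationError(f"annotation table missing columns: {missing}")
    bad = set(annotation["region_class"]) - set(REGION_CLASSES)
    if bad:
        raise AnnotationError(f"unknown region classes: {sorted(bad)}")
    if (annotation["pos"] < 1).any():
        raise AnnotationError("annotation positions must be >= 1")
    # probe_id must be unique per (probe, gene) pair; a probe may annotate to
    # several genes but not twice to the same gene.
    if annotation.duplicated(subset=["probe_id", "gene"]).any():
        # duplicates are tolerated on input but must be deduplicable
        annotation = annotation.drop_duplicates(subset=["probe_id", "gene"])
    return annotation


def build_promoter_map(annotation: pd.DataFrame, gene_list: Sequence[str]) -> PromoterMap:
    """Map each gene in ``gene_list`` to its promoter-class probes.

    Genes with no promoter-class probe in the annotation (including genes
    absent from the annotation entirely) are listed in ``excluded`` with
    reason ``"no promoter probe"``. Duplicate (probe, gene) rows are
    deduplicated so the operation is idempotent.
    """
    if len(gene_list) == 0:
        raise AnnotationError("gene_list is empty")
    annotation = validate_annotation(annotation)
    promoter = annotation[annotation["region_class"].isin(PROMOTER_CLASSES)]
    by_gene = promoter.groupby("gene")["probe_id"].agg(lambda s: sorted(set(s)))
    genes: dict[str, list[str]] = {}
    excluded: dict[str, str] = {}
    for gene in dict.fromkeys(gene_list):  # preserve order, drop duplicates
        probes = by_gene.get(gene)
        if probes:
            genes[gene] = list(probes)
        else:
            excluded[gene] = "no promoter probe"
    return PromoterMap(genes=genes, excluded=excluded)


@dataclass
class CoverageSummary:
    """Probe-coverage bookkeeping for a promoter map.

    Probe counts are over (probe, gene) assignments: a probe serving two
    genes contributes to both, so per-gene counts sum to ``n_promoter_probes``.
    """

    n_genes_with_probes: int
    n_genes_excluded: int
    n_promoter_probes: int
    n_cpg_island_probes: int
    probes_per_gene_mean: float
    probes_per_gene_median: float
    region_class_fractions: dict[str, float]

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_genes_with_probes", "n_genes_excluded", "n_promoter_probes",
            "n_cpg_island_probes", "probes_per_gene_mean", "probes_per_gene_median")}
        d["region_class_fractions"] = dict(self.region_class_fractions)
        return d


def summarize_probe_coverage(pmap: PromoterMap, annotation: pd.DataFrame) -> CoverageSummary:
    """Coverage statistics over the mapped genes (excluded genes only counted)."""
    if pmap.n_genes == 0:
        raise AnnotationError("promoter map is empty")
    annotation = validate_annotation(annotation)
    ann = annotation.set_index(["gene", "probe_id"])

    pairs = [(gene, probe) for gene, probes in pmap.genes.items() for probe in probes]
    rows = ann.loc[pairs]
    counts = np.asarray([len(probes) for probes in pmap.genes.values()])
    total = int(counts.sum())
    island = int(rows["cpg_island"].astype(bool).sum())
    class_counts = rows["region_class"].value_counts()
    fractions = {str(cls): n / total for cls, n in sorted(class_counts.items())}
    return CoverageSummary(
        n_genes_with_probes=pmap.n_genes,
        n_genes_excluded=len(pmap.excluded),
        n_promoter_probes=total,
        n_cpg_island_probes=island,
        probes_per_gene_mean=float(counts.mean()),
        probes_per_gene_median=float(np.median(counts)),
        region_class_fractions=fractions,
    )
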