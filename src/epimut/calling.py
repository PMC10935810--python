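"""Promoter-level aggregation and epimutation calling.

The calling unit is the promoter mean: the arithmetic mean of the non-missing
beta values of a gene's promoter probes in one sample. Per-tissue healthy
baselines are the mean promoter beta across that tissue's baseline-control
samples. A cancer-associated epimutation is called when the promoter mean
exceeds the baseline by strictly more than a cell-model-specific margin: 0.66
in cancer cell lines (cellular homogeneity makes outliers sharp) and 0.33 in
primary tumours and organoids (mixed cell populations dilute the signal).
Healthy-population screening applies the 0.33 margin to independent test
controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import PromoterMap

#: model-specific calling margins (absolute increase in mean promoter beta)
DEFAULT_THRESHOLDS = {"primary": 0.33, "organoid": 0.33, "cell_line": 0.66}
HEALTHY_TEST_THRESHOLD = 0.33

CALL_COLUMNS = ("sample", "gene", "tissue", "cell_model",
                "observed", "baseline", "delta", "threshold")


class CallingError(ValueError):
    pass


@dataclass
class PromoterMethylation:
    """Gene x sample promoter means plus contributing-probe counts."""

    beta: pd.DataFrame
    n_probes: pd.DataFrame


@dataclass
class BaselineTable:
    """Per-(gene, tissue) healthy baseline means and control counts."""

    mean: pd.DataFrame        # genes x tissues
    n_controls: pd.DataFrame  # genes x tissues


@dataclass
class EpimutationCallSet:
    calls: pd.DataFrame
    skipped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["tissue", "gene", "reason"]))

    def __len__(self) -> int:
        return len(self.calls)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.calls["sample"], self.calls["gene"]))


def promoter_beta(beta: pd.DataFrame, pmap: PromoterMap) -> PromoterMethylation:
    """Mean promoter beta per (gene, sample) over non-missing probes.

    Cells with zero contributing probes are missing (never 0). Probes serving
    several genes contribute to each gene's mean independently.
    """
    pairs = [(gene, probe) for gene, probes in pmap.genes.items() for probe in probes
             if probe in beta.index]
    if not pairs:
        raise CallingError("no promoter probes present in the beta matrix")
    gene_keys = pd.Index([g for g, _ in pairs], name="gene")
    rows = beta.loc[[p for _, p in pairs]]
    grouped = rows.set_index(gene_keys).groupby(level="gene", sort=True)
    means = grouped.mean()
    counts = grouped.count()
    means = means.where(counts > 0)
    return PromoterMethylation(beta=means, n_probes=counts)


def tissue_baseline(pm: PromoterMethylation, sheet: pd.DataFrame) -> BaselineTable:
    """Per-tissue baseline means over baseline-control samples.

    Raises if any tissue in the sheet has no baseline control.
    """
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    tissues = sorted(sheet["tissue"].unique())
    means, counts = {}, {}
    for tissue in tissues:
        controls = sheet.index[(sheet["tissue"] == tissue)
                               & (sheet["role"] == "baseline_control")]
        controls = [c for c in controls if c in pm.beta.columns]
        if not controls:
            raise CallingError(f"tissue {tissue!r} has no baseline control samples")
        sub = pm.beta[controls]
        means[tissue] = sub.mean(axis=1)
        counts[tissue] = sub.count(axis=1)
    return BaselineTable(mean=pd.DataFrame(means), n_controls=pd.DataFrame(counts))


def _call(pm: PromoterMethylation, baseline: BaselineTable, sheet: pd.DataFrame,
          role: str, thresholds: dict[str, float] | float,
          out_model: str | None = None) -> EpimutationCallSet:
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    samples = [s for s in pm.beta.columns if s in sheet.index
               and sheet.loc[s, "role"] == role]
    records = []
    skipped: dict[tuple[str, str], str] = {}
    for sample in samples:
        tissue = sheet.loc[sample, "tissue"]
        model = sheet.loc[sample, "cell_model"]
        if pd.isna(tissue) or tissue not in baseline.mean.columns:
            raise CallingError(f"sample {sample!r} has unknown tissue {tissue!r}")
        if isinstance(thresholds, dict):
            if model not in thresholds:
                raise CallingError(f"sample {sample!r} has unknown cell model {model!r}")
            thr = thresholds[model]
        else:
            thr = float(thresholds)
        base = baseline.mean[tissue]
        observed = pm.beta[sample]
        delta = observed - base
        missing_base = base.isna() & observed.notna()
        for gene in pm.beta.index[missing_base]:
            skipped[(tissue, gene)] = "no baseline"
        hits = delta.index[(delta > thr).fillna(False)]
        for gene in hits:
            records.append((sample, gene, tissue, out_model or model,
                            float(observed[gene]), float(base[gene]),
                            float(delta[gene]), thr))
    calls = (pd.DataFrame(records, columns=CALL_COLUMNS)
             .drop_duplicates(subset=["sample", "gene"])
             .sort_values(["sample", "gene"], ignore_index=True))
    skipped_df = pd.DataFrame(
        [(t, g, r) for (t, g), r in sorted(skipped.items())],
        columns=["tissue", "gene", "reason"])
    return EpimutationCallSet(calls=calls, skipped=skipped_df)


def call_epimutations(pm: PromoterMethylation, baseline: BaselineTable,
                      sheet: pd.DataFrame,
                      thresholds: dict[str, float] | None = None) -> EpimutationCallSet:
    """Cancer-associated epimutation calls (strict delta > model threshold)."""
    return _call(pm, baseline, sheet, role="cancer",
                 thresholds=thresholds or dict(DEFAULT_THRESHOLDS))


def call_healthy_test(pm: PromoterMethylation, baseline: BaselineTable,
                      sheet: pd.DataFrame,
                      threshold: float = HEALTHY_TEST_THRESHOLD) -> EpimutationCallSet:
    """Epimutation screen of the healthy test cohort at the 0.33 margin."""
    return _call(pm, baseline, sheet, role="test_control",
                 thresholds=threshold, out_model="test_control")
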