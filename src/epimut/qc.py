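"""Probe-level quality filtering of a beta matrix.

Removal rules, applied as a union over probes:

* detection failure — cells with detection p > 0.01 are masked to missing;
  probes failing in at least ``fail_fraction`` of samples are removed;
* cross-reactive probes (external blocklist);
* probes overlapping SNVs within +/- 1 bp of the CpG (external blocklist);
* probes on chromosomes X and Y;
* probes absent from the annotation (reported under their own rule).

Per-rule counts may overlap; a probe is removed once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .annotation import SEX_CHROMOSOMES

DETECTION_P_CUTOFF = 0.01


@dataclass
class QCReport:
    n_probes_in: int
    n_failed_detection: int
    n_cross_reactive: int
    n_snp_adjacent: int
    n_sex_chromosome: int
    n_no_annotation: int
    n_probes_out: int
    n_cells_masked: int
    removed: dict[str, list[str]] = field(default_factory=dict)
    skipped_rules: list[str] = field(default_factory=list)

    def removed_union(self) -> set[str]:
        out: set[str] = set()
        for probes in self.removed.values():
            out.update(probes)
        return out


def filter_probes(
    beta: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    blocklist_cross_reactive: set[str] | None = None,
    blocklist_snp: set[str] | None = None,
    annotation: pd.DataFrame | None = None,
    fail_fraction: float = 0.05,
    skip_sex: bool = False,
) -> tuple[pd.DataFrame, QCReport]:
    """Apply the probe exclusion rules; returns (filtered beta, report).

    Cells with detection p above 0.01 are always masked to missing; the probe
    itself is removed only when the failing fraction of samples reaches
    ``fail_fraction``. Missing blocklists skip their rule with a warning.
    Sample order is preserved; probe order of survivors is preserved.
    """
    report = QCReport(n_probes_in=len(beta), n_failed_detection=0,
                      n_cross_reactive=0, n_snp_adjacent=0, n_sex_chromosome=0,
                      n_no_annotation=0, n_probes_out=0, n_cells_masked=0)
    beta = beta.copy()

    if detection_p is not None:
        if detection_p.shape != beta.shape:
            raise ValueError(
                f"detection_p shape {detection_p.shape} does not match beta {beta.shape}")
        detection_p = detection_p.reindex(index=beta.index, columns=beta.columns)
        if detection_p.isna().any().any():
            raise ValueError("detection_p does not cover the beta matrix")
        failing = detection_p > DETECTION_P_CUTOFF
        report.n_cells_masked = int((failing & beta.notna()).to_numpy().sum())
        beta[failing] = float("nan")
        failed = beta.index[failing.mean(axis=1) >= fail_fraction]
        report.removed["failed_detection"] = sorted(failed)
    else:
        report.skipped_rules.append("failed_detection")

    for rule, blocklist in (("cross_reactive", blocklist_cross_reactive),
                            ("snp_adjacent", blocklist_snp)):
        if blocklist is None:
            warnings.warn(f"no {rule} blocklist supplied; rule skipped", stacklevel=2)
            report.skipped_rules.append(rule)
        else:
            report.removed[rule] = sorted(set(beta.index) & set(blocklist))

    if annotation is not None:
        chrom = annotation.drop_duplicates("probe_id").set_index("probe_id")["chrom"]
        chrom = chrom.reindex(beta.index)
        report.removed["no_annotation"] = sorted(beta.index[chrom.isna()])
        if not skip_sex:
            sex = chrom.astype(str).isin(SEX_CHROMOSOMES)
            report.removed["sex_chromosome"] = sorted(beta.index[sex.fillna(False)])
        else:
            report.skipped_rules.append("sex_chromosome")
    else:
        report.skipped_rules.extend(["sex_chromosome", "no_annotation"])

    report.n_failed_detection = len(report.removed.get("failed_detection", []))
    report.n_cross_reactive = len(report.removed.get("cross_reactive", []))
    report.n_snp_adjacent = len(report.removed.get("snp_adjacent", []))
    report.n_sex_chromosome = len(report.removed.get("sex_chromosome", []))
    report.n_no_annotation = len(report.removed.get("no_annotation", []))

    drop = report.removed_union()
    filtered = beta.loc[[p for p in beta.index if p not in drop]]
    report.n_probes_out = len(filtered)
    assert report.n_probes_out == report.n_probes_in - len(drop)
    return filtered, report
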