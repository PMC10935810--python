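"""TSV / GMT / YAML readers and writers for every pipeline schema.

All tabular formats are tab-separated with a header row. Matrices have a
feature-id first column and sample-id header; expression matrices carry a
``#unit_tag=...`` comment line before the header. NA tokens are ``NA``, the
empty string and ``nan``. Writers emit deterministic row order and a fixed
float format so outputs are diffable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

NA_TOKENS = ["NA", "nan", ""]
FLOAT_FORMAT = "%.6g"

MATRIX_KINDS = ("beta", "detection_p", "expression")


def _check_rectangular(path: Path, skiprows: int = 0) -> None:
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= skiprows:
                continue
            ncols = line.rstrip("\n").count("\t") + 1
            if width is None:
                width = ncols
            elif ncols != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({ncols} fields, expected {width})")


def read_matrix(path: str | Path, kind: str = "beta") -> pd.DataFrame:
    """Read a feature x sample matrix; validates values for the given kind."""
    if kind not in MATRIX_KINDS:
        raise ValueError(f"unknown matrix kind {kind!r}")
    path = Path(path)
    tag = None
    skip = 0
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#unit_tag="):
        tag = first.strip().split("=", 1)[1]
        skip = 1
    _check_rectangular(path, skiprows=skip)
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip,
                     na_values=NA_TOKENS, keep_default_na=False)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()[:5]
        raise ValueError(f"{path}: duplicate feature ids: {list(dups)}")
    values = df.to_numpy(dtype=float)  # raises on non-numeric cells
    df = pd.DataFrame(values, index=df.index, columns=df.columns)
    if kind == "beta":
        bad = (values < 0) | (values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"{path}: beta value {values[i, j]} outside [0, 1] "
                f"for probe {df.index[i]!r}, sample {df.columns[j]!r}")
    if kind == "detection_p" and ((values < 0) | (values > 1)).any():
        raise ValueError(f"{path}: detection p outside [0, 1]")
    if kind == "expression":
        if (values < 0).any():
            raise ValueError(f"{path}: negative expression value")
        df.attrs["unit_tag"] = tag or "unknown"
    df.index.name = df.index.name or "feature_id"
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, kind: str = "beta") -> None:
    path = Path(path)
    df = df.sort_index().reindex(sorted(df.columns), axis=1)
    with open(path, "w") as fh:
        if kind == "expression":
            fh.write(f"#unit_tag={df.attrs.get('unit_tag', 'unknown')}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, na_rep="NA")


def read_cohort_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "role", "cell_model"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"{path}: cohort sheet missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    bad_roles = set(sheet["role"]) - {"cancer", "baseline_control", "test_control"}
    if bad_roles:
        raise ValueError(f"{path}: unknown roles {sorted(bad_roles)}")
    return sheet


def write_cohort_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.sort_values("sample_id").to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    from .annotation import assign_region_class
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str},
                      na_values=NA_TOKENS, keep_default_na=False)
    ann["gene"] = ann["gene"].fillna("")
    if "region_class" not in ann.columns:
        needed = {"tss", "strand"}
        if not needed <= set(ann.columns):
            raise ValueError(f"{path}: need region_class or tss+strand columns")
        def _cls(row):
            utr5 = ((row["utr5_start"], row["utr5_end"])
                    if "utr5_start" in row and pd.notna(row.get("utr5_start")) else None)
            exon1 = ((row["exon1_start"], row["exon1_end"])
                     if "exon1_start" in row and pd.notna(row.get("exon1_start")) else None)
            return assign_region_class(int(row["pos"]), int(row["tss"]), row["strand"],
                                       utr5=utr5, exon1=exon1, gene=row.get("gene", ""))
        ann["region_class"] = ann.apply(_cls, axis=1)
    ann["cpg_island"] = ann["cpg_island"].astype(int).astype(bool)
    return ann


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out["cpg_island"] = out["cpg_island"].astype(int)
    out.sort_values(["probe_id", "gene"]).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_blocklist(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_blocklist(probes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for probe in sorted(probes):
            fh.write(probe + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: survival table missing columns {sorted(missing)}")
    return df


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df.sort_values("sample_id").to_csv(path, sep="\t", index=False,
                                       float_format=FLOAT_FORMAT)


def read_drug_response(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"cell_line", "compound", "ic50_z"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: drug table missing columns {sorted(missing)}")
    if df.duplicated(subset=["cell_line", "compound"]).any():
        raise ValueError(f"{path}: duplicate (cell_line, compound) records")
    return df


def write_drug_response(df: pd.DataFrame, path: str | Path) -> None:
    df.sort_values(["cell_line", "compound"]).to_csv(path, sep="\t", index=False,
                                                     float_format=FLOAT_FORMAT)


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.sort_values(["sample", "gene"]).to_csv(path, sep="\t", index=False,
                                                 float_format=FLOAT_FORMAT)


def read_calls(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return config


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
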