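"""Transcriptional consequences of promoter hypermethylation.

Partitions samples into hypermethylated vs. comparison groups using the same
model-specific margins as the epimutation caller, then compares expression
between the groups with a Wilcoxon rank-sum test (exact enumeration for small
groups, normal approximation with tie correction otherwise). Correlation of
promoter beta with expression (Spearman by default) detects both canonical
silencing (negative) and the occasional positively-coupled exception.
Expression matrices carry a ``unit_tag`` (FPKM / TPM / simulated); cohorts
with different tags are never compared directly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import BaselineTable, DEFAULT_THRESHOLDS, PromoterMethylation

logger = logging.getLogger(__name__)

EXACT_MAX_GROUP = 10   # both groups at most this size -> exact rank-sum
SPEARMAN_EXACT_MAX_N = 9


class UnitMismatchError(ValueError):
    pass


def unit_tag(expr: pd.DataFrame) -> str:
    return str(expr.attrs.get("unit_tag", "unknown"))


@dataclass
class MethylationPartition:
    gene: str
    hyper: list[str]
    other: list[str]
    testable: bool
    reason: str = ""


def partition_by_methylation(pm: PromoterMethylation, baseline: BaselineTable,
                             sheet: pd.DataFrame, gene: str,
                             expr_samples: list[str] | None = None,
                             thresholds: dict[str, float] | None = None
                             ) -> MethylationPartition:
    """Split cancer samples into hypermethylated vs. comparison for one gene.

    A sample is "hyper" when its promoter-mean delta over the tissue baseline
    strictly exceeds its cell model's margin. Restricted to samples with
    expression available when ``expr_samples`` is given. Empty groups flag the
    partition untestable.
    """
    if gene not in pm.beta.index:
        raise KeyError(f"gene {gene!r} not in promoter methylation matrix")
    thresholds = thresholds or dict(DEFAULT_THRESHOLDS)
    sheet = sheet.set_index("sample_id") if "sample_id" in sheet.columns else sheet
    hyper, other = [], []
    for sample in pm.beta.columns:
        if sample not in sheet.index or sheet.loc[sample, "role"] != "cancer":
            continue
        if expr_samples is not None and sample not in expr_samples:
            continue
        tissue = sheet.loc[sample, "tissue"]
        model = sheet.loc[sample, "cell_model"]
        obs = pm.beta.at[gene, sample]
        base = baseline.mean.at[gene, tissue] if tissue in baseline.mean.columns else np.nan
        if pd.isna(obs) or pd.isna(base):
            continue
        (hyper if obs - base > thresholds[model] else other).append(sample)
    testable = bool(hyper) and bool(other)
    reason = "" if testable else ("no hypermethylated samples" if not hyper
                                  else "no comparison samples")
    return MethylationPartition(gene=gene, hyper=hyper, other=other,
                                testable=testable, reason=reason)


@dataclass
class ExpressionComparison:
    gene: str
    n_hyper: int
    n_other: int
    statistic: float
    p: float
    direction: int          # sign of (hyper median - other median)
    method: str


def compare_expression(expr: pd.DataFrame, hyper: list[str], other: list[str],
                       gene: str, other_expr: pd.DataFrame | None = None,
                       mode: str = "nonparametric") -> ExpressionComparison:
    """Compare expression of ``gene`` between the two groups.

    Wilcoxon rank-sum by default: exact when both groups have at most 10
    samples, otherwise the normal approximation with tie correction. With
    ``mode="auto"`` a two-sample t-test is used instead when both groups pass
    a Shapiro–Wilk normality check at alpha 0.05 (the routing is logged).
    ``other_expr`` allows the comparison group to come from a second matrix,
    which must share the unit tag.
    """
    src_other = expr if other_expr is None else other_expr
    if unit_tag(expr) != unit_tag(src_other):
        raise UnitMismatchError(
            f"cannot compare {unit_tag(expr)} with {unit_tag(src_other)} expression")
    x = expr.loc[gene, hyper].dropna().to_numpy(dtype=float)
    y = src_other.loc[gene, other].dropna().to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both groups need at least 2 expression values")

    method = "wilcoxon"
    if mode == "auto":
        try:
            normal = (shapiro_normality(x).p > 0.05 and shapiro_normality(y).p > 0.05
                      if min(len(x), len(y)) >= 3 else False)
        except ValueError:
            normal = False
        if normal:
            method = "t-test"
        logger.info("test routing for %s: %s", gene, method)

    if method == "t-test":
        res = stats.ttest_ind(x, y)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif (len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP):
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        statistic, p = float(res.statistic), float(res.pvalue)
        method = "wilcoxon-exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        statistic, p = float(res.statistic), float(res.pvalue)
        method = "wilcoxon-asymptotic"

    direction = int(np.sign(np.median(x) - np.median(y)))
    if np.array_equal(np.sort(x), np.sort(y)):
        direction = 0
        p = 1.0
    return ExpressionComparison(gene=gene, n_hyper=len(x), n_other=len(y),
                                statistic=statistic, p=p, direction=direction,
                                method=method)


@dataclass
class CorrelationResult:
    gene: str
    method: str
    coefficient: float
    p: float
    n: int
    flagged: bool = False
    flag_reason: str = ""


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Spearman p by enumeration of rank permutations (no ties)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc ** 2).sum() * (pc ** 2).sum(axis=1))
    rhos = np.abs(pc @ rxc / denom)
    obs = abs(float(np.corrcoef(rx, ry)[0, 1]))
    return float((rhos >= obs - 1e-12).mean())


def methylation_expression_correlation(pm: PromoterMethylation, expr: pd.DataFrame,
                                       gene: str, method: str = "spearman"
                                       ) -> CorrelationResult:
    """Correlate promoter beta with expression across paired samples.

    Spearman p uses exact enumeration when n <= 9 and the ranks are tie-free;
    otherwise the t-approximation. Zero variance in either variable flags the
    result instead of producing a coefficient.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    shared = [s for s in pm.beta.columns if s in expr.columns]
    pairs = pd.DataFrame({"beta": pm.beta.loc[gene, shared],
                          "expr": expr.loc[gene, shared]}).dropna()
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >= 3 paired samples, got {n}")
    x = pairs["beta"].to_numpy(dtype=float)
    y = pairs["expr"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(gene=gene, method=method, coefficient=float("nan"),
                                 p=float("nan"), n=n, flagged=True,
                                 flag_reason="zero variance")
    if method == "pearson":
        res = stats.pearsonr(x, y)
        return CorrelationResult(gene, method, float(res.statistic), float(res.pvalue), n)
    rho = float(stats.spearmanr(x, y).statistic)
    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if n <= SPEARMAN_EXACT_MAX_N and not ties:
        p = _exact_spearman_p(x, y)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return CorrelationResult(gene, method, rho, p, n)


@dataclass
class ShapiroResult:
    statistic: float
    p: float
    n: int


def shapiro_normality(values) -> ShapiroResult:
    """Shapiro–Wilk normality check for 3 <= n <= 5000 non-constant values."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if not 3 <= len(arr) <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(arr)}")
    if np.ptp(arr) == 0:
        raise ValueError("zero variance: normality undefined for a constant vector")
    res = stats.shapiro(arr)
    return ShapiroResult(statistic=float(res.statistic), p=float(res.pvalue), n=len(arr))
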