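"""Clinical correlates: survival by expression quartile and drug sensitivity.

Survival analysis mirrors the standard oncology workflow: patients are split
into the top and bottom expression quartiles of a candidate silenced gene,
overall survival is estimated with the Kaplan–Meier product-limit estimator,
groups are compared with the log-rank (Mantel–Cox) test, and the effect size
is a univariate Cox proportional-hazards ratio (Efron tie handling, Wald
confidence interval). Drug association pools (cell line, compound) pairs for
a set of same-pathway compounds and reports the Spearman correlation and an
ordinary least-squares slope of IC50 z-score on promoter methylation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats

from .calling import PromoterMethylation


def quartile_groups(expr_values: pd.Series) -> pd.Series:
    """Label samples as high / low / excluded by extreme expression quartiles.

    The top 25% are "high", the bottom 25% "low", the middle half "excluded";
    group sizes are floor(n/4). Ties are broken by stable sample-id order so
    the split is deterministic. A constant vector carries no ordering
    information: all samples are excluded (``attrs["degenerate"]`` is set).
    Requires n >= 8.
    """
    values = expr_values.dropna()
    n = len(values)
    if n < 8:
        raise ValueError(f"cohort too small for quartile split (n={n} < 8)")
    labels = pd.Series("excluded", index=values.index, name="expression_group")
    if float(values.max()) == float(values.min()):
        labels.attrs["degenerate"] = True
        return labels
    labels.attrs["degenerate"] = False
    k = n // 4
    ordered = values.iloc[np.argsort(values.index.to_numpy(), kind="stable")]
    ordered = ordered.sort_values(kind="stable")
    labels[ordered.index[:k]] = "low"
    labels[ordered.index[-k:]] = "high"
    return labels


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in records.columns:
            raise ValueError(f"survival records need a {col!r} column")
    if (records["time"] < 0).any():
        raise ValueError("negative survival time")
    if not records["event"].isin((0, 1)).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return records


def km_estimate(records: pd.DataFrame) -> pd.DataFrame:
    """Kaplan–Meier product-limit curve: DataFrame (time, survival).

    Starts at S(0) = 1; censored times reduce the risk set without a step.
    """
    records = _check_records(records)
    if len(records) == 0:
        raise ValueError("no survival records")
    km = KaplanMeierFitter()
    km.fit(records["time"], records["event"])
    out = km.survival_function_.reset_index()
    out.columns = ["time", "survival"]
    return out


def logrank_test(records: pd.DataFrame, labels: pd.Series) -> tuple[float, float]:
    """Two-group log-rank (Mantel–Cox) test; returns (chi2 statistic, p)."""
    records = _check_records(records)
    groups = labels.reindex(records.index) if len(labels) != len(records) else \
        pd.Series(np.asarray(labels), index=records.index)
    uniq = pd.unique(groups.dropna())
    if len(uniq) != 2:
        raise ValueError(f"log-rank needs exactly 2 non-empty groups, got {list(uniq)}")
    a = records[groups == uniq[0]]
    b = records[groups == uniq[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("one group is empty")
    res = _lifelines_logrank(a["time"], b["time"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    n: int
    n_events: int


def cox_univariate(records: pd.DataFrame, covariate: pd.Series | np.ndarray) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Wald CI)."""
    records = _check_records(records)
    x = np.asarray(covariate, dtype=float)
    if len(x) != len(records):
        raise ValueError("covariate length does not match records")
    if int(records["event"].sum()) < 2:
        raise ValueError("need at least 2 events")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    df = pd.DataFrame({"time": records["time"].to_numpy(),
                       "event": records["event"].to_numpy(), "x": x})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox fit did not converge: {err}") from err
    coef = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    return CoxResult(
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - 1.959963984540054 * se)),
        ci_high=float(np.exp(coef + 1.959963984540054 * se)),
        p=float(cph.summary.loc["x", "p"]),
        coef=coef,
        n=len(df),
        n_events=int(df["event"].sum()),
    )


@dataclass
class DrugAssociation:
    gene: str
    compounds: tuple[str, ...]
    n_pairs: int
    rho: float
    rho_p: float
    slope: float
    slope_p: float
    flagged: bool = False
    flag_reason: str = ""


def drug_sensitivity_assoc(pm: PromoterMethylation, drugs: pd.DataFrame, gene: str,
                           compound_set: list[str] | tuple[str, ...]) -> DrugAssociation:
    """Pooled methylation–IC50 association across a compound set.

    Pairs every cell line's promoter beta for ``gene`` with its IC50 z-score
    for each listed compound, then reports Spearman rho and the OLS slope of
    z on beta (both with p). Requires >= 5 pooled pairs; constant methylation
    flags the result.
    """
    if gene not in pm.beta.index:
        raise KeyError(f"gene {gene!r} not in promoter methylation matrix")
    sub = drugs[drugs["compound"].isin(set(compound_set))]
    beta = pm.beta.loc[gene]
    merged = sub.assign(beta=sub["cell_line"].map(beta)).dropna(subset=["beta", "ic50_z"])
    if len(merged) < 5:
        raise ValueError(f"need >= 5 paired observations, got {len(merged)}")
    x = merged["beta"].to_numpy(dtype=float)
    y = merged["ic50_z"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        return DrugAssociation(gene=gene, compounds=tuple(compound_set),
                               n_pairs=len(merged), rho=float("nan"),
                               rho_p=float("nan"), slope=float("nan"),
                               slope_p=float("nan"), flagged=True,
                               flag_reason="constant methylation")
    sp = stats.spearmanr(x, y)
    ols = stats.linregress(x, y)
    return DrugAssociation(gene=gene, compounds=tuple(compound_set),
                           n_pairs=len(merged), rho=float(sp.statistic),
                           rho_p=float(sp.pvalue), slope=float(ols.slope),
                           slope_p=float(ols.pvalue))
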