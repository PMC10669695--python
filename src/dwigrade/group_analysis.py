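"""Two-group comparisons and inter-parameter correlations.

Each DWI parameter is compared between the low- and high-grade classes with
a normality-gated test: if both groups pass Shapiro–Wilk at α = 0.05 a
two-sided Welch t-test is used, otherwise a two-sided Mann–Whitney U test
(exact null for combined n ≤ 20 without ties, normal approximation with tie
correction otherwise).  Pairwise correlations use Pearson when both
variables pass Shapiro–Wilk and Spearman otherwise.  No multiple-testing
correction is applied by default; a Holm adjustment is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparisonResult",
    "CorrelationMatrix",
    "normality_gate",
    "compare_groups",
    "compare_all_parameters",
    "correlation_matrix",
]

SHAPIRO_ALPHA = 0.05
EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class GroupComparisonResult:
    parameter: str
    test_used: str  # "t" or "mann_whitney"
    statistic: float
    p_value: float
    mean_low: float
    sd_low: float
    mean_high: float
    sd_high: float
    shapiro_p_low: float
    shapiro_p_high: float
    warning: str | None = None


@dataclass(frozen=True)
class CorrelationMatrix:
    parameters: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    method: pd.DataFrame  # "pearson" / "spearman" / "undefined" per pair


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # constant sample: treat as decisively non-normal
    return float(stats.shapiro(x).pvalue)


def normality_gate(values_low, values_high,
                   alpha: float = SHAPIRO_ALPHA) -> tuple[str, str | None]:
    """Choose "t" iff both groups pass Shapiro–Wilk, else "mann_whitney".

    A constant group cannot be tested for normality; the gate falls back to
    the rank test and returns a warning flag.
    """
    low = np.asarray(values_low, dtype=float)
    high = np.asarray(values_high, dtype=float)
    if low.size < 3 or high.size < 3:
        return "mann_whitney", "group too small for Shapiro-Wilk"
    if np.ptp(low) == 0 or np.ptp(high) == 0:
        return "mann_whitney", "constant group"
    if _shapiro_p(low) > alpha and _shapiro_p(high) > alpha:
        return "t", None
    return "mann_whitney", None


def _mannwhitney(low: np.ndarray, high: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([low, high])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= EXACT_MW_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"  # normal approximation with tie correction
    res = stats.mannwhitneyu(low, high, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(values_low, values_high, parameter: str = "",
                   test: str = "auto") -> GroupComparisonResult:
    """Two-sided low-vs-high comparison.

    ``test="auto"`` applies the normality gate; "t" or "mann_whitney"
    force the corresponding branch.
    """
    low = np.asarray(values_low, dtype=float)
    high = np.asarray(values_high, dtype=float)
    if low.size < 2 or high.size < 2:
        raise ValueError("each group needs at least two observations")
    if test == "auto":
        test, warning = normality_gate(low, high)
    elif test in ("t", "mann_whitney"):
        warning = None
    else:
        raise ValueError("test must be 'auto', 't' or 'mann_whitney'")
    if test == "t":
        res = stats.ttest_ind(low, high, equal_var=False)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        statistic, p = _mannwhitney(low, high)
    return GroupComparisonResult(
        parameter=parameter, test_used=test, statistic=statistic, p_value=p,
        mean_low=float(low.mean()), sd_low=float(low.std(ddof=1)),
        mean_high=float(high.mean()), sd_high=float(high.std(ddof=1)),
        shapiro_p_low=_shapiro_p(low) if low.size >= 3 else float("nan"),
        shapiro_p_high=_shapiro_p(high) if high.size >= 3 else float("nan"),
        warning=warning,
    )


def compare_all_parameters(table: pd.DataFrame, parameters,
                           holm: bool = False) -> pd.DataFrame:
    """Per-parameter group comparison of a cohort table with a grade column."""
    low = table[table["grade"] == "low"]
    high = table[table["grade"] == "high"]
    results = [compare_groups(low[p].to_numpy(), high[p].to_numpy(), p)
               for p in parameters]
    df = pd.DataFrame([r.__dict__ for r in results])
    if holm:
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        df["p_holm"] = adj
    return df


def correlation_matrix(table: pd.DataFrame,
                       parameters=None) -> CorrelationMatrix:
    """Pairwise Pearson-or-Spearman correlations with the normality gate.

    Pearson is used for a pair when both columns pass Shapiro–Wilk at 0.05,
    Spearman otherwise; a constant column yields an undefined entry (NaN).
    """
    params = tuple(parameters) if parameters is not None else tuple(table.columns)
    if len(table) < 3:
        raise ValueError("at least 3 complete rows required")
    r = pd.DataFrame(np.eye(len(params)), index=params, columns=params)
    p = pd.DataFrame(np.zeros((len(params), len(params))),
                     index=params, columns=params)
    method = pd.DataFrame("", index=params, columns=params)
    normal = {c: (np.ptp(table[c].to_numpy()) > 0
                  and _shapiro_p(table[c].to_numpy()) > SHAPIRO_ALPHA)
              for c in params}
    for i, a in enumerate(params):
        method.loc[a, a] = "identity"
        for b in params[i + 1:]:
            x, y = table[a].to_numpy(float), table[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rv, pv, meth = float("nan"), float("nan"), "undefined"
            elif normal[a] and normal[b]:
                rv, pv = stats.pearsonr(x, y)
                meth = "pearson"
            else:
                rv, pv = stats.spearmanr(x, y)
                meth = "spearman"
            r.loc[a, b] = r.loc[b, a] = float(rv)
            p.loc[a, b] = p.loc[b, a] = float(pv)
            method.loc[a, b] = method.loc[b, a] = meth
    return CorrelationMatrix(parameters=params, r=r, p=p, method=method)
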