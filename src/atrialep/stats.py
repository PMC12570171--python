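"""Cohort-level statistics: group comparisons, correlation, contingency.

Thin, explicitly-typed wrappers around scipy.stats chosen to match common
clinical reporting: two-sided Welch t tests (robust to unequal variances,
identical to the pooled test when variances agree), Pearson correlation
with R^2, chi-squared (with continuity correction) and two-sided Fisher
exact tests on 2x2 tables, and Bonferroni multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary requires n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


@dataclass
class CorrelationResult:
    r: float
    r2: float
    n: int
    p: float


def welch_t(sample_a: np.ndarray, sample_b: np.ndarray) -> TTestResult:
    """Two-sided Welch t test (Welch–Satterthwaite degrees of freedom)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need n >= 2 in each group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0)
        raise ValueError("zero variance in both samples with unequal means")
    res = sst.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


def welch_t_from_summary(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Welch t test from group moments (n, mean, SD) — lets printed summary
    tables be checked without the raw samples."""
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return TTestResult(t=0.0, df=float(a.n + b.n - 2), p=1.0)
        raise ValueError("zero variance in both samples with unequal means")
    res = sst.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                   equal_var=False)
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return TTestResult(t=float(res.statistic), df=float(df),
                       p=float(res.pvalue))


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson product-moment correlation with R^2 (sign kept in r)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sst.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r2=r * r, n=len(x), p=float(res.pvalue))


def contingency(table: np.ndarray, method: str = "fisher") -> float:
    """p-value for a 2x2 table: 'chi2' (with continuity correction) or
    'fisher' (exact, two-sided by the usual probability-ordering rule)."""
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab = tab.astype(float)
        if np.any(tab < 0) or np.any(tab != np.round(tab)):
            raise ValueError("counts must be non-negative integers")
        tab = tab.astype(int)
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("empty margin in contingency table")
    if method == "chi2":
        res = sst.chi2_contingency(tab, correction=True)
        return float(res.pvalue)
    if method == "fisher":
        _, p = sst.fisher_exact(tab, alternative="two-sided")
        return float(p)
    raise ValueError(f"unknown method {method!r}")


def bonferroni(p_values: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m*p); m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    return np.minimum(1.0, m * p)


def group_report(features: pd.DataFrame, groups: np.ndarray) -> pd.DataFrame:
    """Per-feature group means +/- SD, Welch p and Bonferroni-adjusted p.

    ``features``: one row per subject, one column per feature.
    ``groups``: binary labels aligned with the rows.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    rows = []
    for col in features.columns:
        a = features.loc[groups == labels[0], col].dropna().to_numpy()
        b = features.loc[groups == labels[1], col].dropna().to_numpy()
        try:
            tt = welch_t(a, b)
            p = tt.p
        except ValueError:
            p = np.nan
        rows.append({"feature": col,
                     f"mean_{labels[0]}": np.mean(a) if len(a) else np.nan,
                     f"sd_{labels[0]}": np.std(a, ddof=1) if len(a) > 1 else np.nan,
                     f"mean_{labels[1]}": np.mean(b) if len(b) else np.nan,
                     f"sd_{labels[1]}": np.std(b, ddof=1) if len(b) > 1 else np.nan,
                     "p": p})
    rep = pd.DataFrame(rows).set_index("feature")
    finite = rep["p"].notna()
    adj = np.full(len(rep), np.nan)
    adj[finite.to_numpy()] = bonferroni(rep.loc[finite, "p"].to_numpy(),
                                        m=int(finite.sum()))
    rep["p_bonferroni"] = adj
    return rep
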