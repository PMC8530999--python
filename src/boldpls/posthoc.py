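"""Post-hoc battery on latent scores and cohort variables.

Pairwise two-sample t-tests of brain/behavior scores between diagnostic
groups, Pearson correlations of scores with continuous disease-severity
measures, t-tests by binary medication flags, chi-squared tests for
categorical contingency tables, and Benjamini-Hochberg FDR control at
q < 0.05 within each test family.

Standard statistics are delegated to scipy.stats; this module owns the
BH step-up rule, the battery structure, the family definitions, and
pairwise missing-data handling (per-test deletion with n_used reported).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_FDR_Q = 0.05


@dataclass
class TestResult:
    name: str
    statistic: float
    df: float | tuple
    p: float
    n_used: int
    fdr_significant: bool | None = None  # set only by the FDR pass

    def as_row(self) -> dict:
        df = self.df if not isinstance(self.df, tuple) else f"{self.df[0]},{self.df[1]}"
        return {
            "measure": self.name,
            "statistic": self.statistic,
            "df": df,
            "p": self.p,
            "fdr_sig": self.fdr_significant,
            "n_used": self.n_used,
        }


def _clean(x) -> np.ndarray:
    x = np.asarray(x, float)
    return x[np.isfinite(x)]


def two_sample_t(a, b, name: str = "t", welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test, pooled variance by default (Welch by
    flag)."""
    a, b = _clean(a), _clean(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not welch and np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if welch else a.size + b.size - 2
    return TestResult(name, float(res.statistic), df, float(res.pvalue), a.size + b.size)


def oneway_anova(samples: dict, name: str = "anova") -> TestResult:
    """One-way ANOVA across the groups in ``samples`` (label -> values)."""
    groups = [_clean(v) for v in samples.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere")
    f, p = stats.f_oneway(*groups)
    n = sum(g.size for g in groups)
    return TestResult(name, float(f), (len(groups) - 1, n - len(groups)), float(p), n)


def chi_square_test(contingency, name: str = "chi2") -> TestResult:
    """Pearson chi-squared on an R x C count table, no continuity
    correction; df = (R-1)(C-1)."""
    table = np.asarray(contingency, float)
    if table.min() < 0:
        raise ValueError("negative counts")
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least two rows and columns with positive margins")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(name, float(res.statistic), int(res.dof), float(res.pvalue), int(table.sum()))


def pearson_r_test(x, y, name: str = "r") -> TestResult:
    """Pearson correlation with the two-sided t-approximation p-value;
    rows with a missing value in either variable are dropped pairwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need n >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input")
    r, p = stats.pearsonr(x, y)
    return TestResult(name, float(r), x.size - 2, float(p), x.size)


def fdr_bh(p_values, q: float = DEFAULT_FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q.

    Reject all p <= p_(k*) with k* = max{k : p_(k) <= k q / m}; ties are
    handled by a stable sort.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    ok = np.flatnonzero([ps[k - 1] <= k * q / m for k in range(1, m + 1)])
    if ok.size == 0:
        return np.zeros(m, bool)
    return p <= ps[ok[-1]]


def _apply_fdr(results: list, q: float) -> None:
    flags = fdr_bh([r.p for r in results], q)
    for r, f in zip(results, flags):
        r.fdr_significant = bool(f)


def posthoc_battery(
    brain_scores,
    behavior_scores,
    cohort: pd.DataFrame,
    severity_columns: tuple = (),
    medication_columns: tuple = (),
    q: float = DEFAULT_FDR_Q,
) -> pd.DataFrame:
    """The full post-hoc table for one latent component.

    Family 1: brain and behavior scores compared between every pair of
    diagnostic groups (pooled-variance t-tests). Family 2: Pearson
    correlations of scores with continuous severity columns and t-tests of
    scores by binary medication flags. FDR is applied once per family at
    level q. Missing values are dropped per test; columns that are entirely
    missing are skipped.
    """
    brain_scores = np.asarray(brain_scores, float)
    behavior_scores = np.asarray(behavior_scores, float)
    groups = cohort["group"].to_numpy()
    labels = sorted(pd.unique(groups))

    family_scores: list[TestResult] = []
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            ia, ib = groups == ga, groups == gb
            for sname, scores in (("brain", brain_scores), ("behavior", behavior_scores)):
                family_scores.append(
                    two_sample_t(scores[ia], scores[ib], name=f"{sname}_score {ga} vs {gb}")
                )
    _apply_fdr(family_scores, q)

    family_assoc: list[TestResult] = []
    for col in severity_columns:
        if col not in cohort.columns or cohort[col].notna().sum() == 0:
            continue
        vals = cohort[col].to_numpy(float)
        for sname, scores in (("brain", brain_scores), ("behavior", behavior_scores)):
            family_assoc.append(pearson_r_test(scores, vals, name=f"{sname}_score ~ {col}"))
    for col in medication_columns:
        if col not in cohort.columns or cohort[col].notna().sum() == 0:
            continue
        flag = cohort[col].to_numpy(float)
        ok = np.isfinite(flag)
        for sname, scores in (("brain", brain_scores), ("behavior", behavior_scores)):
            on, off = scores[ok & (flag > 0)], scores[ok & (flag == 0)]
            if on.size < 2 or off.size < 2:
                continue
            family_assoc.append(two_sample_t(on, off, name=f"{sname}_score by {col}"))
    if family_assoc:
        _apply_fdr(family_assoc, q)

    rows = [dict(r.as_row(), family="scores_by_group") for r in family_scores]
    rows += [dict(r.as_row(), family="severity_medication") for r in family_assoc]
    return pd.DataFrame(rows)
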