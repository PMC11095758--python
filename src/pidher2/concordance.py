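"""Agreement between quantitative PID results and pathologist DAB scores.

Covers the cohort-level statistics: ordinary least squares of PID value on
the ordinal DAB score (R^2), the 4x4 DAB x PID contingency table with
row-normalised percentages (PV%), variance-test-gated two-sample
comparisons (Student's pooled t when an F-test accepts equal variances at
alpha, Welch otherwise), and replicate-run reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DAB_CLASSES, CoreRecord

ORDINAL = {c: i for i, c in enumerate(DAB_CLASSES)}


@dataclass
class ConcordanceReport:
    """Regression and cross-tabulation of PID against DAB scores."""

    r_squared: float | None = None
    slope: float | None = None
    intercept: float | None = None
    table: pd.DataFrame | None = None  # counts, DAB rows x PID columns
    pv_percent: pd.DataFrame | None = None  # row percentages of `table`
    n: int = 0
    regression_form: str = "ols pid_value ~ ordinal(dab)"
    pv_definition: str = "row (DAB-class-wise) percentage"
    adjacent_comparisons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "regression_form": self.regression_form,
            "pv_definition": self.pv_definition,
        }
        if self.table is not None:
            out["table"] = {r: self.table.loc[r].to_dict() for r in self.table.index}
            out["pv_percent"] = {r: self.pv_percent.loc[r].round(1).to_dict() for r in self.pv_percent.index}
        if self.adjacent_comparisons:
            out["adjacent_comparisons"] = {k: v.to_dict() for k, v in self.adjacent_comparisons.items()}
        return out


@dataclass
class GroupComparison:
    """Two-sample comparison gated by a variance-ratio test.

    The F-test (larger sample variance in the numerator, two-sided p)
    decides the t-test flavour: Student's pooled t when f_p >= alpha,
    Welch otherwise. ``significant`` uses the two-tailed t p-value at
    alpha; ``significant_strict`` applies the stricter 0.001 threshold
    used when starring plots.
    """

    f_statistic: float
    f_p: float
    test_used: str  # "student" | "welch"
    t_statistic: float
    t_p: float
    significant: bool
    significant_strict: bool
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "f_p": self.f_p,
            "test_used": self.test_used,
            "t_statistic": self.t_statistic,
            "t_p": self.t_p,
            "significant": self.significant,
            "significant_strict": self.significant_strict,
            "alpha": self.alpha,
        }


def _paired_arrays(records: list[CoreRecord]) -> tuple[np.ndarray, np.ndarray]:
    pairs = [
        (ORDINAL[r.dab_consensus], r.pid_value)
        for r in records
        if r.dab_consensus is not None and r.pid_value is not None
    ]
    if not pairs:
        return np.empty(0), np.empty(0)
    x, y = zip(*pairs)
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def fit_score_regression(records: list[CoreRecord]) -> ConcordanceReport:
    """OLS of PID value on the ordinal DAB score (0,1,2,3); R^2 = 1 - SSR/SST."""
    x, y = _paired_arrays(records)
    if x.size < 3:
        raise ValueError(f"regression needs at least 3 records with both scores, got {x.size}")
    if np.unique(x).size < 2:
        raise ValueError("all DAB scores identical: R^2 is undefined, not zero")
    res = stats.linregress(x, y)
    return ConcordanceReport(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=int(x.size),
    )


def contingency(records: list[CoreRecord]) -> ConcordanceReport:
    """4x4 DAB (rows) x PID (columns) counts with row percentages (PV%)."""
    rows = [(r.dab_consensus, r.pid_score) for r in records if r.dab_consensus is not None and r.pid_score is not None]
    if not rows:
        raise ValueError("no records with both a DAB consensus and a PID score")
    dab = pd.Categorical([a for a, _ in rows], categories=DAB_CLASSES)
    pid = pd.Categorical([b for _, b in rows], categories=DAB_CLASSES)
    table = pd.crosstab(dab, pid, rownames=["dab"], colnames=["pid"], dropna=False)
    table = table.reindex(index=DAB_CLASSES, columns=DAB_CLASSES, fill_value=0)
    row_tot = table.sum(axis=1)
    pv = 100.0 * table.div(row_tot.replace(0, np.nan), axis=0)
    return ConcordanceReport(table=table, pv_percent=pv, n=int(table.to_numpy().sum()))


def compare_groups(a, b, alpha: float = 0.05) -> GroupComparison:
    """Variance-gated two-sample comparison of two value groups.

    Two-sided F-test on the variance ratio with the larger sample variance
    in the numerator; equal variance is accepted when f_p >= alpha, and the
    two-tailed t-test is then Student's pooled form, otherwise Welch's.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"each group needs n >= 2, got {a.size} and {b.size}")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / va if va > 0 else np.inf, b.size - 1, a.size - 1
    if np.isinf(f):
        f_p = 0.0
    elif va == vb:
        f_p = 1.0
    else:
        f_p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    equal_var = f_p >= alpha
    t_res = stats.ttest_ind(a, b, equal_var=equal_var)
    t_p = float(t_res.pvalue)
    return GroupComparison(
        f_statistic=float(f),
        f_p=float(f_p),
        test_used="student" if equal_var else "welch",
        t_statistic=float(t_res.statistic),
        t_p=t_p,
        significant=bool(t_p < alpha),
        significant_strict=bool(t_p < 0.001),
        alpha=alpha,
    )


def adjacent_class_comparisons(records: list[CoreRecord], alpha: float = 0.05) -> dict[str, GroupComparison]:
    """Compare PID values of each adjacent DAB-class pair (0 vs 1+, ...)."""
    by_class: dict[str, list[float]] = {c: [] for c in DAB_CLASSES}
    for r in records:
        if r.dab_consensus is not None and r.pid_value is not None:
            by_class[r.dab_consensus].append(r.pid_value)
    out = {}
    for lo, hi in zip(DAB_CLASSES, DAB_CLASSES[1:]):
        if len(by_class[lo]) >= 2 and len(by_class[hi]) >= 2:
            out[f"{lo}_vs_{hi}"] = compare_groups(by_class[lo], by_class[hi], alpha=alpha)
    return out


def full_report(records: list[CoreRecord], alpha: float = 0.05) -> ConcordanceReport:
    """Regression + contingency + adjacent-class comparisons in one report."""
    reg = fit_score_regression(records)
    tab = contingency(records)
    reg.table, reg.pv_percent = tab.table, tab.pv_percent
    reg.adjacent_comparisons = adjacent_class_comparisons(records, alpha=alpha)
    return reg


def reproducibility(runs: list[list[CoreRecord]]) -> dict:
    """Per-run regression R^2 and pairwise between-run PID correlations.

    Runs are matched on shared core ids; at least two runs are required.
    """
    if len(runs) < 2:
        raise ValueError("reproducibility needs at least two runs")
    per_run = [fit_score_regression(run) for run in runs]
    maps = [{r.core_id: r.pid_value for r in run if r.pid_value is not None} for run in runs]
    shared = sorted(set.intersection(*(set(m) for m in maps)))
    if len(shared) < 3:
        raise ValueError(f"runs share only {len(shared)} cores; need at least 3 for correlations")
    correlations = {}
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            xi = np.array([maps[i][c] for c in shared])
            xj = np.array([maps[j][c] for c in shared])
            correlations[f"run{i + 1}_run{j + 1}"] = float(stats.pearsonr(xi, xj).statistic)
    return {
        "per_run_r_squared": [rep.r_squared for rep in per_run],
        "between_run_correlation": correlations,
        "n_shared_cores": len(shared),
    }
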