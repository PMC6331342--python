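"""Outcome definitions, Kaplan-Meier/log-rank machinery, and optimal-cutoff stratification.

Overall survival is the interval from diagnosis to last news; relapse
status is dichotomized at 12 months after the end of first-line
chemotherapy (an event strictly before 12 months counts as relapse).
Patients are stratified on a continuous score by scanning every admissible
midpoint between consecutive distinct score values and keeping the split
with the smallest log-rank p — an exhaustive version of iterating sample
size thresholds.  The minimal p is reported uncorrected, with an explicit
multiplicity caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

DAYS_PER_MONTH = 30.4375  # calendar-average month

MULTIPLICITY_CAVEAT = (
    "threshold chosen by minimal log-rank p over the full scan; "
    "the reported p is not corrected for this multiplicity"
)


def overall_survival(diagnosis_date: date, last_news_date: date) -> float:
    """Months between diagnosis and last news (days / 30.4375)."""
    if last_news_date < diagnosis_date:
        raise ValueError("last news precedes diagnosis")
    return (last_news_date - diagnosis_date).days / DAYS_PER_MONTH


def relapse_at_12(
    end_first_line_date: date, relapse_date: date | None
) -> str:
    """'yes' iff relapse occurs strictly before 12 months after first-line end."""
    if relapse_date is None:
        return "no"
    if relapse_date < end_first_line_date:
        raise ValueError("relapse precedes end of first-line treatment")
    months = (relapse_date - end_first_line_date).days / DAYS_PER_MONTH
    return "yes" if months < 12.0 else "no"


def km_logrank(
    table: pd.DataFrame, group_col: str = "group"
) -> tuple[dict[str, KaplanMeierFitter], float, float]:
    """Kaplan-Meier fits per group plus the log-rank test across groups.

    ``table`` needs columns ``time``, ``event`` and ``group_col``.  Returns
    (fits keyed by group, chi-square statistic, p value).
    """
    if table["event"].sum() < 1:
        raise ValueError("log-rank test requires at least one event")
    fits: dict[str, KaplanMeierFitter] = {}
    for g, sub in table.groupby(group_col):
        if len(sub) == 0:
            raise ValueError(f"group {g} is empty")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(sub["time"], event_observed=sub["event"])
        fits[str(g)] = kmf
    if table[group_col].nunique() < 2:
        raise ValueError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(table["time"], table[group_col], table["event"])
    return fits, float(res.test_statistic), float(res.p_value)


@dataclass
class CutoffResult:
    threshold: float
    group_sizes: tuple[int, int]  # (n below, n at/above)
    statistic: float
    p_value: float
    scan: pd.DataFrame = field(repr=False)  # every candidate with its p
    caveat: str = MULTIPLICITY_CAVEAT


def optimal_cutoff(
    table: pd.DataFrame,
    score_col: str = "score",
    min_group_fraction: float = 0.1,
) -> CutoffResult:
    """Exhaustive midpoint scan for the score threshold minimizing log-rank p.

    Candidates are midpoints between consecutive distinct scores whose
    induced low/high split leaves both groups at least
    ``min_group_fraction`` of the cohort.  Ties in p go to the smaller
    threshold (deterministic).
    """
    scores = table[score_col].to_numpy(dtype=float)
    n = len(scores)
    distinct = np.unique(scores)
    if len(distinct) < 2:
        raise ValueError("optimal_cutoff needs at least two distinct scores")
    floor = min_group_fraction * n

    rows = []
    for lo, hi in zip(distinct, distinct[1:]):
        thr = (lo + hi) / 2.0
        below = scores < thr
        if below.sum() < floor or (~below).sum() < floor:
            continue
        split = table.assign(_grp=np.where(below, "below", "at_or_above"))
        _, stat, p = km_logrank(split, group_col="_grp")
        rows.append(
            {
                "threshold": thr,
                "n_below": int(below.sum()),
                "n_above": int((~below).sum()),
                "statistic": stat,
                "p": p,
            }
        )
    if not rows:
        raise ValueError("no candidate threshold satisfies the group-size floor")
    scan = pd.DataFrame(rows)
    best = scan.sort_values(["p", "threshold"]).iloc[0]
    return CutoffResult(
        threshold=float(best["threshold"]),
        group_sizes=(int(best["n_below"]), int(best["n_above"])),
        statistic=float(best["statistic"]),
        p_value=float(best["p"]),
        scan=scan,
    )


def group_compare(
    a, b=None, kind: str = "rank-sum"
) -> tuple[float, float]:
    """Two-sided group comparison: rank-sum, t, fisher (2x2) or spearman.

    ``fisher`` takes a 2x2 count table as ``a``; ``spearman`` takes the two
    paired vectors.  Returns (statistic, p).
    """
    if kind == "fisher":
        tab = np.asarray(a)
        if tab.shape != (2, 2):
            raise ValueError("fisher requires a 2x2 count table")
        stat, p = stats.fisher_exact(tab, alternative="two-sided")
        return float(stat), float(p)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("groups must be non-empty")
    if kind == "rank-sum":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif kind == "t":
        res = stats.ttest_ind(a, b)
    elif kind == "spearman":
        res = stats.spearmanr(a, b)
    else:
        raise ValueError(f"unknown test kind: {kind}")
    return float(res.statistic), float(res.pvalue)
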