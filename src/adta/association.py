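"""Agreement between the automated score and pathologist TIL grading.

Pathologists grade infiltrate on the ordinal scale absent (0) / non-brisk
(1) / brisk (2).  Two analyses connect that grading to the continuous
automated score: a Spearman rank correlation (mid-ranks for ties, p from
the t approximation) and an omnibus comparison of score distributions
across grades (Kruskal–Wallis with tie correction by default; one-way
ANOVA available as the parametric alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SpearmanResult", "GradeComparisonResult", "spearman",
           "grade_stratified_test"]


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GradeComparisonResult:
    statistic: float
    p_value: float
    method: str
    group_summaries: pd.DataFrame  # per grade: n, median, q1, q3


def _complete_pairs(scores, grades) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    grades = np.asarray(grades, dtype=float)
    keep = ~(np.isnan(scores) | np.isnan(grades))
    return scores[keep], grades[keep]


def spearman(scores, grades) -> SpearmanResult:
    """Spearman rank correlation between per-patient scores and TIL grades.

    Requires >= 3 complete pairs and nonzero rank variance on both sides
    (grades all equal make the correlation undefined).
    """
    s, g = _complete_pairs(scores, grades)
    if len(s) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(s)}")
    if np.unique(g).size < 2 or np.unique(s).size < 2:
        raise ValueError("zero rank variance: all grades (or scores) identical")
    rho, p = stats.spearmanr(s, g)
    return SpearmanResult(rho=float(rho), p_value=float(p), n=len(s))


def grade_stratified_test(
    scores,
    grades,
    method: Literal["kruskal", "anova"] = "kruskal",
) -> GradeComparisonResult:
    """Compare score distributions across TIL grades.

    Kruskal–Wallis H (tie-corrected, chi-square with k-1 df) by default.
    Degenerate case: if every score is identical across all groups the
    tie-corrected H is defined as 0 with p = 1.
    """
    s, g = _complete_pairs(scores, grades)
    levels = np.unique(g)
    groups = [s[g == lev] for lev in levels]
    groups = [grp for grp in groups if len(grp) >= 1]
    if sum(len(grp) >= 2 for grp in groups) < 2:
        raise ValueError("need >= 2 grades with >= 2 patients each")
    if method == "kruskal":
        if np.unique(s).size == 1:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*groups)
        name = "kruskal-wallis"
    elif method == "anova":
        stat, p = stats.f_oneway(*groups)
        name = "one-way-anova"
    else:
        raise ValueError(f"unknown method {method!r}")
    summaries = pd.DataFrame(
        {
            "grade": levels.astype(int),
            "n": [int((g == lev).sum()) for lev in levels],
            "median": [float(np.median(s[g == lev])) for lev in levels],
            "q1": [float(np.percentile(s[g == lev], 25)) for lev in levels],
            "q3": [float(np.percentile(s[g == lev], 75)) for lev in levels],
        }
    )
    return GradeComparisonResult(
        statistic=float(stat), p_value=float(p), method=name,
        group_summaries=summaries,
    )
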