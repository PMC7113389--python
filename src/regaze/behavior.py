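"""Paired questionnaire analyses: rating scales and topic identification.

Willingness-to-reread and appreciation are 5-point ratings compared
between the first and last reading session with paired t-tests. Topic
identification is a paired binary outcome compared with Bowker's symmetry
test, which for a 2x2 table is McNemar's test (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["StatResult", "paired_t", "bowker_test", "paired_binary_table",
           "describe_sessions"]


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its degrees of freedom and two-sided p."""

    statistic: float
    df: int
    p: float
    n: int
    direction: str  # sign of (first - last), or "none"

    def to_dict(self) -> dict:
        return asdict(self)


def paired_t(first, last) -> StatResult:
    """Classical paired-samples t-test on first-vs-last values.

    Pairs must be aligned (same participant x sonnet order in both
    vectors). df = n - 1; two-sided p. A zero-variance difference vector
    is degenerate and raises.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(last, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("first/last must be 1-d and equally long")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(a, b)
    mean_diff = diff.mean()
    direction = "first>last" if mean_diff > 0 else ("first<last" if mean_diff < 0 else "none")
    return StatResult(
        statistic=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        n=n,
        direction=direction,
    )


def bowker_test(table) -> StatResult:
    """Bowker's symmetry test on a square K x K paired-category table.

    chi2 = sum over i<j of (n_ij - n_ji)^2 / (n_ij + n_ji), over cell
    pairs with n_ij + n_ji > 0; df = number of such pairs. For K = 2 this
    is McNemar's test without continuity correction.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or t.shape[0] < 2:
        raise ValueError("table must be square with K >= 2")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    k = t.shape[0]
    chi2 = 0.0
    df = 0
    net = 0.0  # summed (upper - lower) discordance, for direction
    for i in range(k):
        for j in range(i + 1, k):
            s = t[i, j] + t[j, i]
            if s > 0:
                chi2 += (t[i, j] - t[j, i]) ** 2 / s
                df += 1
                net += t[i, j] - t[j, i]
    if df == 0:
        raise ValueError("all off-diagonal pairs are zero; test undefined")
    p = float(stats.chi2.sf(chi2, df))
    direction = "upper>lower" if net > 0 else ("upper<lower" if net < 0 else "none")
    return StatResult(statistic=float(chi2), df=df, p=p, n=int(t.sum()),
                      direction=direction)


def paired_binary_table(first_correct, last_correct) -> np.ndarray:
    """2x2 contingency table of paired booleans.

    Rows = first session (correct, wrong), columns = last session, so
    cell [0,1] counts correct->wrong and [1,0] wrong->correct.
    """
    a = np.asarray(first_correct, dtype=bool)
    b = np.asarray(last_correct, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and equally long")
    table = np.zeros((2, 2), dtype=int)
    for x, y in zip(a, b):
        table[0 if x else 1, 0 if y else 1] += 1
    return table


def describe_sessions(records: pd.DataFrame,
                      questions=("willingness", "appreciation")) -> pd.DataFrame:
    """Mean, SD (ddof=1) and n per question per session."""
    if records.empty:
        raise ValueError("no rating records")
    out = []
    for q in questions:
        for ses, grp in records.groupby("session"):
            v = grp[q].astype(float)
            out.append(
                {
                    "question": q,
                    "session": ses,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
                    "n": len(v),
                }
            )
    return pd.DataFrame(out)
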