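"""Shared statistical helpers used across analysis modules.

Standard tests (Welch t, Kruskal-Wallis, Mann-Whitney, chi-square, ANOVA,
hypergeometric) are delegated to scipy/statsmodels; this module adds the
small pieces that have no single canonical implementation in the installed
stack: Dunn's post-hoc z test and a thin wrapper around Benjamini-Hochberg.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are ignored for the adjustment and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def dunn_test(values, groups, adjust: str = "bh") -> pd.DataFrame:
    """Dunn's post-hoc pairwise test after Kruskal-Wallis.

    values : 1-D array of observations
    groups : 1-D array of group labels, same length

    Uses the pooled-rank z statistic with the tie correction
    sum(t^3 - t) / (12 (N - 1)).  Returns a table with one row per
    unordered group pair (group_a, group_b, z, p, q).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have the same length")
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    n = values.size
    ranks = stats.rankdata(values)
    # tie correction term
    _, counts = np.unique(values, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n - 1)) if n > 1 else 0.0

    labels = pd.unique(groups)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    size = {g: int((groups == g).sum()) for g in labels}

    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            se = np.sqrt(
                (n * (n + 1) / 12.0 - tie_term) * (1.0 / size[a] + 1.0 / size[b])
            )
            if se == 0:  # every observation tied
                z, p = 0.0, 1.0
            else:
                z = (mean_rank[a] - mean_rank[b]) / se
                p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if adjust == "bh" and len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    elif len(out):
        out["q"] = out["p"]
    return out


def chi2_independence(table, correction: bool = False):
    """Chi-square test of independence on a contingency table.

    Yates correction is off by default so 2x2 tables reproduce the
    textbook statistic.  Returns (statistic, p, dof, expected).
    """
    stat, p, dof, expected = stats.chi2_contingency(np.asarray(table), correction=correction)
    return stat, p, dof, expected


def welch_rowwise(a: np.ndarray, b: np.ndarray):
    """Row-wise Welch t-test between two sample blocks with NaN support.

    a, b : 2-D arrays (features x samples).  Returns (delta, t, p) where
    delta is mean(a) - mean(b) over observed values per row.
    """
    res = stats.ttest_ind(a, b, axis=1, equal_var=False, nan_policy="omit")
    delta = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    t = np.asarray(res.statistic, dtype=float)
    return delta, t, p
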