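"""Group-wise differential abundance on log2 intensity matrices.

Covers four contrasts used in ECM cohort profiling:

* one-vs-rest upregulation per histological subtype (Welch t on log2
  values, BH FDR; "upregulated" = q < fdr_threshold and mean difference
  >= lfc_threshold log2 units, i.e. fold change >= 2 at the default 1.0);
* exclusive ("uniquely upregulated") protein sets across subtypes;
* arbitrary two-group comparisons (e.g. preoperative treatment vs none);
* stratum-robustness checks (Kruskal-Wallis across e.g. tumor-content
  bins) and a two-class SAM with permutation-estimated FDR for small
  cell-line designs.

Missing values: all tests use observed values only; a protein is excluded
from a contrast when fewer than ``min_group_fraction`` of either arm is
observed or either arm has < 2 observed values (logged).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, welch_rowwise
from .cohort_io import as_frame

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.01
DEFAULT_LFC = 1.0          # log2 units; 1.0 == fold change 2
DEFAULT_MIN_N = 20
MIN_GROUP_FRACTION = 0.5


def _align_labels(df: pd.DataFrame, labels) -> pd.Series:
    labels = pd.Series(labels)
    if not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.reindex(df.columns)
    else:
        if len(labels) != df.shape[1]:
            raise ValueError("labels length does not match sample count")
        labels.index = df.columns
    return labels


def _usable(df: pd.DataFrame, in_group: np.ndarray,
            min_fraction: float = MIN_GROUP_FRACTION) -> pd.Series:
    a = df.loc[:, in_group]
    b = df.loc[:, ~in_group]
    obs_a, obs_b = a.notna().sum(axis=1), b.notna().sum(axis=1)
    ok = (
        (obs_a >= 2) & (obs_b >= 2)
        & (obs_a >= min_fraction * a.shape[1])
        & (obs_b >= min_fraction * b.shape[1])
    )
    dropped = int((~ok).sum())
    if dropped:
        logger.info("excluding %d proteins with insufficient observed values", dropped)
    return ok


def _welch_table(df: pd.DataFrame, in_group: np.ndarray, group_label: str,
                 fdr_threshold: float, lfc_threshold: float) -> pd.DataFrame:
    ok = _usable(df, in_group)
    sub = df.loc[ok]
    delta, t, p = welch_rowwise(sub.loc[:, in_group].to_numpy(),
                                sub.loc[:, ~in_group].to_numpy())
    q = bh_adjust(p)
    out = pd.DataFrame({
        "group_label": group_label,
        "delta_log2": delta,
        "t_statistic": t,
        "p_value": p,
        "q_value": q,
        "direction": np.where(delta >= 0, "up", "down"),
    }, index=sub.index)
    out["upregulated"] = (out["q_value"] < fdr_threshold) & (out["delta_log2"] >= lfc_threshold)
    out["downregulated"] = (out["q_value"] < fdr_threshold) & (out["delta_log2"] <= -lfc_threshold)
    return out


def one_vs_rest_de(matrix, labels, group, min_n: int = DEFAULT_MIN_N,
                   fdr_threshold: float = DEFAULT_FDR,
                   lfc_threshold: float = DEFAULT_LFC) -> pd.DataFrame:
    """Welch t-test of one group against all remaining samples.

    Refuses groups below ``min_n`` samples (default 20, the cohort-size
    floor used when screening subtypes).
    """
    df = as_frame(matrix)
    labels = _align_labels(df, labels)
    in_group = (labels == group).to_numpy()
    if in_group.sum() < min_n:
        raise ValueError(
            f"group {group!r} has {int(in_group.sum())} samples, below min_n={min_n}"
        )
    if (~in_group).sum() < 2:
        raise ValueError("rest arm needs >= 2 samples")
    return _welch_table(df, in_group, str(group), fdr_threshold, lfc_threshold)


def unique_upregulation(matrix, labels, eligible_groups=None,
                        min_n: int = DEFAULT_MIN_N,
                        fdr_threshold: float = DEFAULT_FDR,
                        lfc_threshold: float = DEFAULT_LFC) -> dict[str, set]:
    """Proteins upregulated in exactly one eligible group's one-vs-rest test.

    ``eligible_groups`` defaults to all groups with >= min_n samples.
    Returned sets are pairwise disjoint by construction.
    """
    df = as_frame(matrix)
    labels = _align_labels(df, labels)
    if eligible_groups is None:
        counts = labels.value_counts()
        eligible_groups = [g for g in counts.index if counts[g] >= min_n]
    if len(eligible_groups) < 2:
        raise ValueError("need at least 2 eligible groups")
    flagged = {}
    for g in eligible_groups:
        res = one_vs_rest_de(df, labels, g, min_n=min_n,
                             fdr_threshold=fdr_threshold, lfc_threshold=lfc_threshold)
        flagged[g] = set(res.index[res["upregulated"]])
    unique = {}
    for g in eligible_groups:
        others = set().union(*(flagged[h] for h in eligible_groups if h != g))
        unique[g] = flagged[g] - others
    return unique


def two_group_de(matrix, labels, group_a, group_b,
                 fdr_threshold: float = DEFAULT_FDR,
                 lfc_threshold: float = DEFAULT_LFC) -> pd.DataFrame:
    """Welch t-test between two arbitrary arms (delta = mean_a - mean_b)."""
    df = as_frame(matrix)
    labels = _align_labels(df, labels)
    use = labels.isin([group_a, group_b]).to_numpy()
    df = df.loc[:, use]
    in_a = (labels[use] == group_a).to_numpy()
    if in_a.sum() < 2 or (~in_a).sum() < 2:
        raise ValueError("each arm needs >= 2 samples")
    return _welch_table(df, in_a, f"{group_a}_vs_{group_b}", fdr_threshold, lfc_threshold)


def stratum_robustness(matrix, strata_labels, min_stratum: int = 2):
    """Kruskal-Wallis of each protein (and the per-sample global median) across strata.

    Used to check that abundance is not driven by a stratification variable
    such as percentage tumor content.  Strata smaller than ``min_stratum``
    are merged into the nearest stratum (by sorted label order) with a
    warning.  Returns (per-protein DataFrame, global summary dict).
    """
    df = as_frame(matrix)
    labels = _align_labels(df, strata_labels).astype(str)
    counts = labels.value_counts()
    order = sorted(counts.index)
    if len(order) < 2:
        raise ValueError("need >= 2 strata")
    merged = labels.copy()
    for small in [s for s in order if counts[s] < min_stratum]:
        neighbors = [s for s in order if s != small and counts[s] >= min_stratum]
        if not neighbors:
            raise ValueError("no stratum reaches the minimum size")
        target = min(neighbors, key=lambda s: abs(order.index(s) - order.index(small)))
        logger.warning("stratum %r (< %d samples) merged into %r", small, min_stratum, target)
        merged[merged == small] = target
    strata = sorted(merged.unique())
    if len(strata) < 2:
        raise ValueError("fewer than 2 strata remain after merging")

    def kw(values: pd.Series):
        groups = [values[merged == s].dropna().to_numpy() for s in strata]
        if any(len(g) < 2 for g in groups):
            return np.nan
        if np.ptp(np.concatenate(groups)) == 0:
            return 1.0
        return stats.kruskal(*groups).pvalue

    p = df.apply(kw, axis=1)
    out = pd.DataFrame({"p_value": p, "q_value": bh_adjust(p.to_numpy())}, index=df.index)
    global_median = df.median(axis=0, skipna=True)
    summary = {
        "strata": strata,
        "n_per_stratum": {s: int((merged == s).sum()) for s in strata},
        "global_median_p": float(kw(global_median)),
        "fraction_significant_proteins": float((out["p_value"] < 0.05).mean()),
    }
    return out, summary


# ---------------------------------------------------------------------------
# SAM (significance analysis of microarrays), two-class unpaired


@dataclass
class SamResult:
    d_statistic: pd.Series            # per protein
    s0: float
    fdr_table: pd.DataFrame           # per delta: n_significant, median null count, FDR
    significant: pd.Index             # at the chosen delta
    chosen_delta: float
    n_permutations_used: int
    exhaustive: bool
    extras: dict = field(default_factory=dict)


def _sam_scale(values: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Pooled fudge-free scale s_i per protein."""
    a, b = values[:, in_a], values[:, ~in_a]
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = np.nanmean(a, axis=1), np.nanmean(b, axis=1)
    ssa = np.nansum((a - mean_a[:, None]) ** 2, axis=1)
    ssb = np.nansum((b - mean_b[:, None]) ** 2, axis=1)
    return np.sqrt((1.0 / na + 1.0 / nb) * (ssa + ssb) / (na + nb - 2))


def _sam_d(values: np.ndarray, in_a: np.ndarray, s0: float):
    s = _sam_scale(values, in_a)
    delta = (np.nanmean(values[:, in_a], axis=1)
             - np.nanmean(values[:, ~in_a], axis=1))
    denom = s + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, delta / np.where(denom > 0, denom, 1.0), 0.0)
    return d, s


def _choose_s0(s: np.ndarray, strategy) -> float:
    if isinstance(strategy, (int, float)) and not isinstance(strategy, bool):
        return float(strategy)
    if strategy == "zero":
        return 0.0
    if strategy == "median":
        return float(np.median(s))
    if strategy == "percentile_scan":
        candidates = np.percentile(s, np.arange(0, 101, 5))
        return _percentile_scan(s, candidates)
    raise ValueError(f"unknown s0 strategy {strategy!r}")


def _percentile_scan(s: np.ndarray, candidates: np.ndarray) -> float:
    # Tusher-style: choose s0 minimizing the coefficient of variation of
    # the MAD of 1/(s + s0) across s quantile windows.
    edges = np.percentile(s, np.linspace(0, 100, 11))
    best, best_cv = float(candidates[0]), np.inf
    for cand in candidates:
        mads = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            window = s[(s >= lo) & (s <= hi)]
            if window.size < 2:
                continue
            inv = 1.0 / (window + cand)
            mads.append(stats.median_abs_deviation(inv))
        mads = np.array(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=0) / mads.mean()
        if cv < best_cv:
            best, best_cv = float(cand), cv
    return best


def sam_two_class(matrix, labels, group_a=None, n_permutations: int = 1000,
                  seed: int = 0, s0_strategy="median",
                  deltas=None, fdr_target: float = 0.05) -> SamResult:
    """Two-class SAM: moderated d statistic with permutation-estimated FDR.

    d_i = (mean_A - mean_B) / (s_i + s0).  The null distribution comes from
    label permutations: all distinct assignments when their count is
    <= n_permutations, otherwise a seeded random subset.  For each delta
    threshold, FDR = median permutation count of |d*| >= delta divided by
    the observed count, clipped to [0, 1].  ``significant`` holds proteins
    at the smallest delta whose FDR is <= fdr_target.
    """
    df = as_frame(matrix)
    labels = _align_labels(df, labels)
    uniq = [u for u in pd.unique(labels.dropna())]
    if len(uniq) != 2:
        raise ValueError(f"need exactly 2 groups, got {uniq}")
    if group_a is None:
        group_a = uniq[0]
    in_a = (labels == group_a).to_numpy()
    na, nb = int(in_a.sum()), int((~in_a).sum())
    if na < 2 or nb < 2:
        raise ValueError("each group needs >= 2 samples")

    values = df.to_numpy(dtype=float)
    s = _sam_scale(values, in_a)
    s0 = _choose_s0(s, s0_strategy)
    d_obs, _ = _sam_d(values, in_a, s0)

    n_total = na + nb
    n_all = math.comb(n_total, na)
    if n_all <= n_permutations:
        assignments = []
        for combo in itertools.combinations(range(n_total), na):
            perm = np.zeros(n_total, dtype=bool)
            perm[list(combo)] = True
            assignments.append(perm)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        idx = np.arange(n_total)
        assignments = []
        for _ in range(n_permutations):
            perm = np.zeros(n_total, dtype=bool)
            perm[rng.choice(idx, size=na, replace=False)] = True
            assignments.append(perm)
        exhaustive = False

    null_abs = np.stack([np.abs(_sam_d(values, perm, s0)[0]) for perm in assignments])
    obs_abs = np.abs(d_obs)

    if deltas is None:
        finite = np.sort(obs_abs[np.isfinite(obs_abs)])
        deltas = np.unique(np.round(finite, 10))
        if deltas.size > 50:
            deltas = np.quantile(deltas, np.linspace(0, 1, 50))
    rows = []
    for delta in np.asarray(deltas, dtype=float):
        n_sig = int((obs_abs >= delta).sum())
        null_counts = (null_abs >= delta).sum(axis=1)
        med_null = float(np.median(null_counts))
        fdr = float(np.clip(med_null / n_sig, 0.0, 1.0)) if n_sig else 0.0
        rows.append({"delta": delta, "n_significant": n_sig,
                     "median_null_count": med_null, "fdr": fdr})
    fdr_table = pd.DataFrame(rows)

    passing = fdr_table[(fdr_table["fdr"] <= fdr_target) & (fdr_table["n_significant"] > 0)]
    if len(passing):
        chosen_delta = float(passing["delta"].iloc[0])
        significant = df.index[obs_abs >= chosen_delta]
    else:
        chosen_delta = float("inf")
        significant = df.index[[]]
    return SamResult(
        d_statistic=pd.Series(d_obs, index=df.index),
        s0=s0, fdr_table=fdr_table, significant=significant,
        chosen_delta=chosen_delta, n_permutations_used=len(assignments),
        exhaustive=exhaustive,
        extras={"group_a": group_a, "n_a": na, "n_b": nb},
    )
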