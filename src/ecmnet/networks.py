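"""Coregulated-network discovery and molecular subtyping.

Workflow: pairwise-complete Pearson similarity over proteins, Monti-style
consensus clustering (of proteins, or of samples for subtype discovery),
cluster-significance testing against a single-Gaussian null (SigClust),
per-sample cluster median scores, and association of scores/subgroups with
clinical variables.

Consensus clustering repeatedly subsamples items, clusters each subsample
hierarchically (1 - r distance for similarity input, Euclidean for feature
input), and records how often item pairs co-cluster among the resamples
that drew both.  The number of clusters is chosen by minimum PAC, the
proportion of consensus values falling in an ambiguous intermediate band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform

from ._stats import bh_adjust, chi2_independence, dunn_test
from .cohort_io import ClinicalTable, as_frame

logger = logging.getLogger(__name__)

PAC_LOWER, PAC_UPPER = 0.1, 0.9
DEFAULT_MIN_PAIRS = 10
STABLE_PAC_THRESHOLD = 0.5


@dataclass
class SimilarityMatrix:
    """Symmetric Pearson correlation matrix with per-pair observation counts."""

    values: pd.DataFrame
    pair_n: pd.DataFrame
    min_pairs: int = DEFAULT_MIN_PAIRS

    @property
    def item_ids(self) -> list[str]:
        return list(self.values.index)


def correlation_similarity(matrix, min_pairs: int = DEFAULT_MIN_PAIRS) -> SimilarityMatrix:
    """Pairwise-complete Pearson correlation between protein rows.

    Pairs with fewer than ``min_pairs`` joint observations are masked
    (NaN); zero-variance proteins get masked rows/columns rather than
    propagating NaN.  The diagonal is set to 1.
    """
    df = as_frame(matrix)
    if df.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation similarity")
    corr = df.T.corr(method="pearson", min_periods=max(min_pairs, 2))
    observed = df.notna().astype(float).to_numpy()
    pair_n = pd.DataFrame(observed @ observed.T, index=df.index, columns=df.index).astype(int)
    corr = corr.mask(pair_n < min_pairs)
    zero_var = df.std(axis=1, skipna=True).fillna(0.0) == 0
    if zero_var.any():
        logger.warning("masking %d zero-variance proteins in similarity", int(zero_var.sum()))
        corr.loc[zero_var, :] = np.nan
        corr.loc[:, zero_var] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return SimilarityMatrix(corr, pair_n, min_pairs)


@dataclass
class ConsensusResult:
    consensus: dict                      # k -> item x item co-clustering frequency
    pac: dict                            # k -> proportion of ambiguous clustering
    chosen_k: int
    assignments: pd.Series               # item -> cluster id (1..chosen_k)
    stable: bool                         # min PAC below the stability threshold
    resample_log: dict = field(default_factory=dict)


def _consensus_distance(data) -> tuple[pd.Index, np.ndarray]:
    """Full square distance matrix for either input mode."""
    if isinstance(data, SimilarityMatrix):
        r = data.values.to_numpy(dtype=float)
        r = np.where(np.isnan(r), 0.0, r)          # masked pairs treated as uncorrelated
        dist = 1.0 - r
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2.0
        return data.values.index, dist
    df = as_frame(data)
    filled = df.to_numpy(dtype=float)
    if np.isnan(filled).any():
        row_means = np.nanmean(filled, axis=1)
        idx = np.where(np.isnan(filled))
        filled[idx] = np.take(row_means, idx[0])
    dist = squareform(pdist(filled, metric="euclidean"))
    return df.index, dist


def consensus_cluster(data, k_range=range(2, 9), n_resamples: int = 1000,
                      subsample_fraction: float = 0.8, linkage: str = "average",
                      seed: int = 0, fixed_k: int | None = None,
                      stable_pac_threshold: float = STABLE_PAC_THRESHOLD) -> ConsensusResult:
    """Monti-style consensus clustering with PAC model selection.

    data : SimilarityMatrix (1 - r distance) or items x features frame
    fixed_k : reproduction mode; still computes consensus/PAC for k_range
        but forces the final assignment to ``fixed_k`` clusters.
    """
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 2 for k in ks) or not ks:
        raise ValueError("k_range must contain integers >= 2 (k=1 is trivially all-ones)")
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    index, dist = _consensus_distance(data)
    n = len(index)
    if n < max(ks) + 2:
        raise ValueError(f"need at least max(k)+2 = {max(ks) + 2} items, got {n}")
    m = max(int(round(subsample_fraction * n)), max(ks) + 1)
    rng = np.random.default_rng(seed)

    co_cluster = {k: np.zeros((n, n)) for k in ks}
    co_sampled = np.zeros((n, n))
    for _ in range(n_resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = dist[np.ix_(idx, idx)]
        condensed = squareform(sub, checks=False)
        tree = scipy_linkage(condensed, method=linkage)
        co_sampled[np.ix_(idx, idx)] += 1.0
        for k in ks:
            labels = fcluster(tree, k, criterion="maxclust")
            for c in np.unique(labels):
                members = idx[labels == c]
                co_cluster[k][np.ix_(members, members)] += 1.0

    consensus, pac = {}, {}
    off_diag = ~np.eye(n, dtype=bool)
    sampled = co_sampled > 0
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(sampled, co_cluster[k] / np.where(sampled, co_sampled, 1.0), 0.0)
        np.fill_diagonal(cons, 1.0)
        consensus[k] = pd.DataFrame(cons, index=index, columns=index)
        vals = cons[off_diag & sampled]
        pac[k] = float(((vals > PAC_LOWER) & (vals < PAC_UPPER)).mean()) if vals.size else 1.0

    if fixed_k is not None:
        chosen_k = fixed_k
    else:
        # minimum PAC; among exact ties prefer the largest k.  With a
        # deterministic hierarchical inner clusterer, coarser cuts of a
        # clean k*-cluster structure are also perfectly stable (PAC 0), so
        # ties at the minimum indicate nested stable partitions and the
        # finest one is the informative choice.
        min_pac_val = min(pac[k] for k in ks)
        chosen_k = max(k for k in ks if pac[k] == min_pac_val)
    if fixed_k is not None and fixed_k not in consensus:
        raise ValueError(f"fixed_k={fixed_k} not in k_range")
    final_dist = squareform(1.0 - consensus[chosen_k].to_numpy(), checks=False)
    final_tree = scipy_linkage(final_dist, method=linkage)
    labels = fcluster(final_tree, chosen_k, criterion="maxclust")
    min_pac = min(pac.values())
    stable = min_pac <= stable_pac_threshold
    if not stable:
        logger.warning("no stable consensus structure (min PAC %.3f > %.3f)",
                       min_pac, stable_pac_threshold)
    return ConsensusResult(
        consensus=consensus, pac=pac, chosen_k=int(chosen_k),
        assignments=pd.Series(labels, index=index, name="cluster"),
        stable=stable,
        resample_log={"n_resamples": n_resamples, "subsample_fraction": subsample_fraction,
                      "subsample_size": m, "linkage": linkage, "seed": seed,
                      "min_pac": min_pac},
    )


# ---------------------------------------------------------------------------
# SigClust


def _two_means_ci(x: np.ndarray, rng: np.random.Generator, n_restarts: int = 4,
                  max_iter: int = 100) -> float:
    """2-means cluster index: within-cluster SS / total SS, best of restarts."""
    n = x.shape[0]
    centroid = x.mean(axis=0)
    total_ss = float(((x - centroid) ** 2).sum())
    if total_ss == 0:
        return 1.0
    best = np.inf
    for _ in range(n_restarts):
        picks = rng.choice(n, size=2, replace=False)
        centers = x[picks].astype(float)
        for _ in range(max_iter):
            d = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            assign = d.argmin(axis=1)
            new_centers = np.array([
                x[assign == j].mean(axis=0) if (assign == j).any() else centers[j]
                for j in range(2)
            ])
            if np.allclose(new_centers, centers):
                centers = new_centers
                break
            centers = new_centers
        wss = float(((x - centers[assign]) ** 2).sum())
        best = min(best, wss)
    return best / total_ss


def sigclust(data, n_sim: int = 500, seed: int = 0) -> dict:
    """Test a 2-cluster split against a single multivariate Gaussian null.

    The observed statistic is the 2-means cluster index (within-cluster SS
    over total SS).  The null draws ``n_sim`` datasets of the same shape
    from a zero-mean Gaussian whose covariance eigenvalues come from a
    Ledoit-Wolf-shrunk covariance estimate, hard-thresholded from below at
    a background-noise variance estimated from the MAD of all data values.
    Shrinkage matters: raw sample eigenvalues are over-dispersed at small
    n, which makes the parametric null spuriously anisotropic and the test
    badly conservative.  p = fraction of null cluster indices <= observed.
    """
    x = np.asarray(as_frame(data) if isinstance(data, pd.DataFrame) else data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 10:
        raise ValueError("need a 2-D array with >= 10 items")
    if np.isnan(x).any():
        col_means = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x = x.copy()
        x[idx] = np.take(col_means, idx[1])
    if n_sim < 100:
        warnings.warn(f"n_sim={n_sim} limits p-value resolution to {1.0 / n_sim:.3g}",
                      stacklevel=2)
    n, p = x.shape
    rng = np.random.default_rng(seed)
    ci_obs = _two_means_ci(x - x.mean(axis=0), rng)

    sigma2_bg = (stats.median_abs_deviation(x, axis=None, scale="normal")) ** 2
    from sklearn.covariance import LedoitWolf
    cov = np.atleast_2d(LedoitWolf().fit(x).covariance_)
    eigvals = np.linalg.eigvalsh(cov)
    eigvals = np.maximum(eigvals, sigma2_bg)

    null_ci = np.empty(n_sim)
    scale = np.sqrt(eigvals)
    for s in range(n_sim):
        sim = rng.standard_normal((n, p)) * scale[None, :]
        null_ci[s] = _two_means_ci(sim - sim.mean(axis=0), rng)
    p_value = float((null_ci <= ci_obs).mean())
    return {"p_value": p_value, "cluster_index": float(ci_obs),
            "null_mean_ci": float(null_ci.mean()), "n_sim": n_sim,
            "background_variance": float(sigma2_bg)}


# ---------------------------------------------------------------------------
# Cluster scores and clinical association


def cluster_median_scores(matrix, assignments) -> pd.DataFrame:
    """Per-sample median of observed member abundances, per cluster.

    Returns samples x clusters; a cluster with no measured member in a
    sample yields NaN there.
    """
    df = as_frame(matrix)
    assignments = pd.Series(assignments)
    clusters = sorted(pd.unique(assignments.dropna()))
    out = pd.DataFrame(index=df.columns, columns=[f"C{c}" for c in clusters], dtype=float)
    for c in clusters:
        members = [g for g in assignments.index[assignments == c] if g in df.index]
        if not members:
            raise ValueError(f"cluster {c} has no member present in the matrix")
        out[f"C{c}"] = df.loc[members].median(axis=0, skipna=True)
    return out


def associate_scores(scores: pd.DataFrame, clinical, grade_col: str = "grade",
                     subtype_col: str = "subtype",
                     exclude_subtypes=("DES",)) -> dict:
    """Associate per-sample cluster scores with grade and subtype.

    Grade: two-sided Mann-Whitney (grade 2 vs 3) per cluster, restricted to
    graded cases with ungradeable subtypes (desmoid by default) excluded.
    Subtype: Kruskal-Wallis per cluster plus Dunn pairwise tests with BH
    adjustment.  Subtype levels with < 3 samples are excluded from the
    pairwise tests.
    """
    clin = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    scores = scores.loc[scores.index.intersection(clin.index)]
    clin = clin.loc[scores.index]

    grade = clin[grade_col].astype(str)
    graded = grade.isin(["2", "3"]) & ~clin[subtype_col].isin(exclude_subtypes)
    grade_rows = []
    for cluster in scores.columns:
        g2 = scores.loc[graded & (grade == "2"), cluster].dropna()
        g3 = scores.loc[graded & (grade == "3"), cluster].dropna()
        if len(g2) < 3 or len(g3) < 3:
            logger.warning("cluster %s: too few graded cases for the grade test", cluster)
            continue
        if np.ptp(np.concatenate([g2, g3])) == 0:
            u, p = len(g2) * len(g3) / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(g2, g3, alternative="two-sided")
        grade_rows.append({
            "cluster": cluster, "n_grade2": len(g2), "n_grade3": len(g3),
            "median_grade2": float(g2.median()), "median_grade3": float(g3.median()),
            "direction": "up_in_grade3" if g3.median() > g2.median() else "up_in_grade2",
            "U": float(u), "p_value": float(p),
        })
    grade_table = pd.DataFrame(grade_rows)
    if len(grade_table):
        grade_table["q_value"] = bh_adjust(grade_table["p_value"].to_numpy())

    subtype = clin[subtype_col].astype(str)
    counts = subtype.value_counts()
    usable_levels = [s for s in counts.index if counts[s] >= 3]
    kw_rows, dunn_tables = [], {}
    for cluster in scores.columns:
        groups = [scores.loc[subtype == s, cluster].dropna().to_numpy() for s in usable_levels]
        groups = [g for g in groups if len(g) >= 3]
        if len(groups) < 2:
            continue
        if np.ptp(np.concatenate(groups)) == 0:
            kw_rows.append({"cluster": cluster, "H": 0.0, "p_value": 1.0})
            continue
        kw = stats.kruskal(*groups)
        kw_rows.append({"cluster": cluster, "H": float(kw.statistic),
                        "p_value": float(kw.pvalue)})
        mask = subtype.isin(usable_levels)
        vals = scores.loc[mask, cluster]
        keep = vals.notna()
        dunn_tables[cluster] = dunn_test(vals[keep].to_numpy(),
                                         subtype[mask][keep].to_numpy())
    kw_table = pd.DataFrame(kw_rows)
    if len(kw_table):
        kw_table["q_value"] = bh_adjust(kw_table["p_value"].to_numpy())
    return {"grade": grade_table, "subtype_kw": kw_table, "subtype_dunn": dunn_tables}


def associate_clinical(subgroups, clinical, categorical=None, continuous=None,
                       til_counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Test subgroup labels against clinical variables.

    Categorical variables use the chi-square test of independence
    (no Yates correction); continuous variables use Kruskal-Wallis.
    TIL count columns, if given, are dichotomized at the cohort median
    before the chi-square test.  Single-level variables are skipped with a
    note; low expected cell counts are reported as warnings, not errors.
    """
    clin = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    subgroups = pd.Series(subgroups).reindex(clin.index).dropna()
    clin = clin.loc[subgroups.index]
    if categorical is None:
        categorical = [c for c in ("subtype", "grade", "site", "depth", "margins",
                                   "sex", "performance_status", "preop_treatment")
                       if c in clin.columns]
    if continuous is None:
        continuous = [c for c in ("age", "tumor_size") if c in clin.columns]

    rows = []
    for var in categorical:
        values = clin[var].astype(str)
        levels = values[values != "unknown"].unique()
        if len(levels) < 2:
            rows.append({"variable": var, "test": "chi2", "statistic": np.nan,
                         "p_value": np.nan, "note": "single level; skipped"})
            continue
        mask = values != "unknown"
        table = pd.crosstab(subgroups[mask], values[mask])
        stat, p, dof, expected = chi2_independence(table.to_numpy())
        note = ""
        if (expected < 5).any():
            note = f"{int((expected < 5).sum())} expected cells < 5"
        rows.append({"variable": var, "test": "chi2", "statistic": float(stat),
                     "p_value": float(p), "note": note})
    for var in continuous:
        values = pd.to_numeric(clin[var], errors="coerce")
        groups = [values[subgroups == g].dropna().to_numpy()
                  for g in pd.unique(subgroups)]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            rows.append({"variable": var, "test": "kruskal", "statistic": np.nan,
                         "p_value": np.nan, "note": "too few groups; skipped"})
            continue
        kw = stats.kruskal(*groups)
        rows.append({"variable": var, "test": "kruskal", "statistic": float(kw.statistic),
                     "p_value": float(kw.pvalue), "note": ""})
    if til_counts is not None:
        for marker in til_counts.columns:
            counts = pd.to_numeric(til_counts[marker], errors="coerce").reindex(subgroups.index)
            ok = counts.notna()
            if ok.sum() < 4:
                rows.append({"variable": f"TIL_{marker}", "test": "chi2",
                             "statistic": np.nan, "p_value": np.nan,
                             "note": "too few scored cases; skipped"})
                continue
            high = counts[ok] > counts[ok].median()
            table = pd.crosstab(subgroups[ok], high)
            if table.shape[1] < 2:
                rows.append({"variable": f"TIL_{marker}", "test": "chi2",
                             "statistic": np.nan, "p_value": np.nan,
                             "note": "degenerate split; skipped"})
                continue
            stat, p, dof, expected = chi2_independence(table.to_numpy())
            note = "median-dichotomized"
            if (expected < 5).any():
                note += f"; {int((expected < 5).sum())} expected cells < 5"
            rows.append({"variable": f"TIL_{marker}", "test": "chi2",
                         "statistic": float(stat), "p_value": float(p), "note": note})
    return pd.DataFrame(rows)
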