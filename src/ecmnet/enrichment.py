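"""Single-sample gene-set enrichment (ssGSEA) and overrepresentation analysis.

The ssGSEA score for a sample and a gene set follows the single-sample
running-sum formulation: genes are ranked by abundance (descending, ties
broken by stable lexicographic symbol order), and the enrichment score is
the sum over ranks of the difference between the weighted in-set empirical
CDF (weights |value|^alpha) and the unweighted out-of-set ECDF.  Scores
are optionally normalized per sample by the range of scores across sets.

ORA uses the upper-tail hypergeometric test against a configurable
universe; the default universe is all proteins quantified in the matrix
(not the genome) to respect the detection bias of proteomics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .cohort_io import GeneSetCollection, as_frame

DEFAULT_ALPHA = 0.75


def ssgsea(profile, gene_set, alpha: float = DEFAULT_ALPHA) -> float:
    """ssGSEA enrichment score for one sample profile.

    profile : mapping or Series gene -> value (missing values dropped)
    gene_set : iterable of gene symbols (intersected with the profile)

    Raises ValueError when the intersected set is empty or covers every
    profiled gene (the out-of-set ECDF would be undefined).
    """
    series = pd.Series(profile, dtype=float).dropna()
    if series.index.has_duplicates:
        raise ValueError("duplicate gene symbols in profile")
    members = set(gene_set) & set(series.index)
    if not members:
        raise ValueError("gene set does not intersect the profile")
    if len(members) == len(series):
        raise ValueError("gene set covers the whole profile; out-of-set ECDF undefined")

    # descending by value, ties by gene symbol for determinism
    order = sorted(series.index, key=lambda g: (-series[g], g))
    values = series.loc[order].to_numpy()
    in_set = np.array([g in members for g in order])

    weights = np.abs(values) ** alpha
    in_weights = np.where(in_set, weights, 0.0)
    total_in = in_weights.sum()
    if total_in == 0:
        # all member values are exactly zero: fall back to unweighted ECDF
        in_weights = in_set.astype(float)
        total_in = in_weights.sum()
    p_in = np.cumsum(in_weights) / total_in
    p_out = np.cumsum(~in_set) / (len(order) - len(members))
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(matrix, collection: GeneSetCollection,
                  alpha: float = DEFAULT_ALPHA, normalize: bool = True) -> pd.DataFrame:
    """ssGSEA scores for every sample x gene set (sets x samples frame).

    ``normalize`` rescales each sample's scores by the per-sample range
    across sets (max - min), the usual multi-set normalization; it is a
    no-op for a single set with nonzero score range.
    """
    df = as_frame(matrix)
    usable = {}
    for name, members in collection.items():
        inter = set(members) & set(df.index)
        if inter and len(inter) < df.shape[0]:
            usable[name] = members
    if not usable:
        raise ValueError("no gene set has a usable intersection with the matrix")
    out = pd.DataFrame(index=sorted(usable), columns=df.columns, dtype=float)
    for sample in df.columns:
        profile = df[sample].dropna()
        for name in out.index:
            members = set(usable[name]) & set(profile.index)
            if members and len(members) < len(profile):
                out.loc[name, sample] = ssgsea(profile, members, alpha=alpha)
    if normalize:
        rng = out.max(axis=0) - out.min(axis=0)
        rng = rng.replace(0.0, 1.0)
        out = out / rng
    return out


def hallmark_screen(matrix, collection: GeneSetCollection, subgroup_labels,
                    alpha: float = DEFAULT_ALPHA, fdr_threshold: float = 0.05,
                    min_per_group: int = 3) -> pd.DataFrame:
    """One-way ANOVA of ssGSEA scores across subgroups, per gene set.

    Scores are computed on the supplied matrix (pass the full, unfiltered
    proteome so pathway sets outside the ECM catalog can score).  Returns a
    per-set table with F, p, BH q, a q < fdr_threshold significance flag
    and subgroup mean scores.
    """
    df = as_frame(matrix)
    labels = pd.Series(subgroup_labels)
    if not labels.index.equals(pd.RangeIndex(len(labels))):
        labels = labels.reindex(df.columns)
    else:
        labels.index = df.columns
    groups = [g for g in pd.unique(labels.dropna())]
    if len(groups) < 2:
        raise ValueError("need >= 2 subgroups")
    sizes = labels.value_counts()
    small = [g for g in groups if sizes[g] < min_per_group]
    if small:
        raise ValueError(f"subgroups below {min_per_group} samples: {small}")

    scores = ssgsea_matrix(df, collection, alpha=alpha, normalize=True)
    rows = []
    for name in scores.index:
        per_group = [scores.loc[name, labels == g].dropna().to_numpy() for g in groups]
        pooled = np.concatenate(per_group)
        if np.ptp(pooled) == 0:
            f_stat, p = 0.0, 1.0
            note = "degenerate: identical scores"
        elif all(np.ptp(g) == 0 for g in per_group):
            f_stat, p = np.inf, 0.0
            note = "zero within-group variance"
        else:
            res = stats.f_oneway(*per_group)
            f_stat, p = float(res.statistic), float(res.pvalue)
            note = ""
        row = {"gene_set": name, "F": f_stat, "p_value": p, "note": note}
        for g in groups:
            row[f"mean_{g}"] = float(np.mean(scores.loc[name, labels == g].dropna()))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene_set")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["q_value"] < fdr_threshold
    return out.sort_values("q_value")


def ora(query_set, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation of a query set.

    Every collection set is intersected with the universe first; terms
    whose intersection with the query is empty are kept with p = 1.
    Returns a table sorted by BH q-value.
    """
    query = set(query_set)
    universe = set(universe)
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_universe, n_query = len(universe), len(query)
    rows = []
    for name, members in collection.items():
        term = set(members) & universe
        overlap = len(term & query)
        if term and overlap:
            p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(term), n_query))
        else:
            p = 1.0
        rows.append({
            "term": name, "overlap": overlap, "set_size": len(term),
            "universe_size": n_universe, "query_size": n_query,
            "p_value": min(p, 1.0),
        })
    out = pd.DataFrame(rows).set_index("term")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["q_value", "p_value"])
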