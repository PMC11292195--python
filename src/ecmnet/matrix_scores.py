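"""Gene-set-level patient scores and the prognostic screening procedure.

A candidate collection of ECM gene sets (proteoglycans, basement membrane,
collagens, core matrisome, ...) is summarized per patient either as the
median of observed member abundances or as an ssGSEA score.  The screen
then proceeds in two stages:

1. each set's score is split at the cohort median and tested per survival
   endpoint with the log-rank test; sets significant (p < alpha) for at
   least one endpoint continue;
2. surviving sets enter a multivariable Cox model together with clinical
   covariates (optionally preselected by univariable significance); a set
   is *retained* when its stratum indicator stays significant there,
   i.e. when its prognostic value is independent of baseline
   clinicopathological variables.

A full audit trail (per-set, per-endpoint p-values and the MVA tables) is
emitted so the filtering is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .cohort_io import ClinicalTable, GeneSetCollection, as_frame
from .enrichment import DEFAULT_ALPHA, ssgsea_matrix
from .survival import cox_fit, log_rank, stratify, uva_significant_covariates

logger = logging.getLogger(__name__)

DEFAULT_CLINICAL_COVARIATES = (
    "age", "grade", "subtype", "site", "tumor_size", "depth", "margins",
    "sex", "performance_status",
)


def geneset_median_score(matrix, collection: GeneSetCollection) -> pd.DataFrame:
    """Per-sample median of observed member abundances, per gene set.

    Sets with no member in the matrix are excluded with a warning; genes
    absent from the matrix do not affect the score (intersection first).
    Returns samples x sets.
    """
    df = as_frame(matrix)
    out = {}
    for name, members in collection.items():
        present = [g for g in members if g in df.index]
        if not present:
            logger.warning("gene set %s has no member in the matrix; excluded", name)
            continue
        out[name] = df.loc[present].median(axis=0, skipna=True)
    if not out:
        raise ValueError("no gene set intersects the matrix")
    return pd.DataFrame(out)


def geneset_ssgsea_score(matrix, collection: GeneSetCollection,
                         alpha: float = DEFAULT_ALPHA, normalize: bool = True) -> pd.DataFrame:
    """Per-sample ssGSEA score per gene set (samples x sets)."""
    return ssgsea_matrix(matrix, collection, alpha=alpha, normalize=normalize).T


@dataclass
class ScreenReport:
    stage1: pd.DataFrame              # per set x endpoint: log-rank p, pass flag
    stage2: dict                      # set -> {endpoint -> MVA Cox table}
    retained: list
    scores: pd.DataFrame              # samples x sets
    strata: dict                      # set -> StrataAssignment
    config: dict = field(default_factory=dict)


def prognostic_screen(matrix, collection: GeneSetCollection, clinical,
                      endpoints=("OS", "LRFS", "MFS"), alpha: float = 0.05,
                      score_rule: str = "median",
                      clinical_covariates=DEFAULT_CLINICAL_COVARIATES,
                      covariate_preselect: bool = True,
                      stage1_bh: bool = False,
                      max_endpoint_missing: float = 0.2,
                      ties: str = "efron") -> ScreenReport:
    """Two-stage prognostic screen over a gene-set collection.

    score_rule : 'median' (member-median score) or 'ssgsea'.
    covariate_preselect : restrict the MVA model to clinical covariates
        that are univariably significant (p < alpha) for that endpoint;
        set False for the full-model mode.
    stage1_bh : apply BH across sets within each endpoint at stage 1
        (off by default; raw log-rank p is the reference behavior).
    Endpoints with more than ``max_endpoint_missing`` of samples missing
    are skipped with a warning.
    """
    if not isinstance(clinical, ClinicalTable):
        clinical = ClinicalTable(clinical)
    df = as_frame(matrix)
    if score_rule == "median":
        scores = geneset_median_score(df, collection)
    elif score_rule == "ssgsea":
        scores = geneset_ssgsea_score(df, collection)
    else:
        raise ValueError("score_rule must be 'median' or 'ssgsea'")
    scores = scores.loc[scores.index.intersection(clinical.data.index)]
    clin = clinical.data.loc[scores.index]

    usable_endpoints = []
    for label in endpoints:
        if label not in clinical.endpoint_labels():
            logger.warning("endpoint %s not present; skipped", label)
            continue
        missing = clin[f"{label}_time"].isna().mean()
        if missing > max_endpoint_missing:
            logger.warning("endpoint %s missing for %.0f%% of samples; skipped",
                           label, 100 * missing)
            continue
        usable_endpoints.append(label)
    if not usable_endpoints:
        raise ValueError("no usable survival endpoint")

    strata_by_set, rows = {}, []
    for name in scores.columns:
        assignment = stratify(scores[name], rule="median")
        strata_by_set[name] = assignment
        for label in usable_endpoints:
            ep = clin[[f"{label}_time", f"{label}_event"]].dropna()
            strata = assignment.strata.reindex(ep.index)
            groups = [
                (ep.loc[strata == level, f"{label}_time"],
                 ep.loc[strata == level, f"{label}_event"])
                for level in ("low", "high")
            ]
            try:
                res = log_rank(groups)
                p = res["p_value"]
            except ValueError as err:
                logger.warning("set %s endpoint %s: %s", name, label, err)
                p = np.nan
            rows.append({"gene_set": name, "endpoint": label, "logrank_p": p})
    stage1 = pd.DataFrame(rows)
    if stage1_bh:
        for label in usable_endpoints:
            sel = stage1["endpoint"] == label
            stage1.loc[sel, "logrank_p_adj"] = bh_adjust(stage1.loc[sel, "logrank_p"].to_numpy())
        crit = "logrank_p_adj"
    else:
        crit = "logrank_p"
    stage1["passed"] = stage1[crit] < alpha

    candidates = sorted(stage1.loc[stage1["passed"], "gene_set"].unique())
    stage2, retained = {}, []
    covariates = [c for c in clinical_covariates if c in clin.columns]
    for name in candidates:
        assignment = strata_by_set[name]
        per_endpoint = {}
        independent = False
        passing = stage1[(stage1["gene_set"] == name) & stage1["passed"]]["endpoint"]
        for label in passing:
            records = clin.copy()
            records["time"] = records[f"{label}_time"]
            records["event"] = records[f"{label}_event"]
            records["score_high"] = (assignment.strata == "high").astype(float)
            records = records.dropna(subset=["time", "event"])
            if covariate_preselect:
                chosen = uva_significant_covariates(records, covariates,
                                                    alpha=alpha, ties=ties)
            else:
                chosen = list(covariates)
            try:
                res = cox_fit(records, ["score_high", *chosen], ties=ties)
            except ValueError as err:
                logger.warning("MVA for set %s endpoint %s failed: %s", name, label, err)
                continue
            per_endpoint[label] = res
            if res.p("score_high") < alpha and "score_high" not in res.non_estimable:
                independent = True
        stage2[name] = per_endpoint
        if independent:
            retained.append(name)

    return ScreenReport(
        stage1=stage1, stage2=stage2, retained=retained, scores=scores,
        strata=strata_by_set,
        config={"alpha": alpha, "score_rule": score_rule,
                "endpoints": list(usable_endpoints),
                "covariate_preselect": covariate_preselect,
                "stage1_bh": stage1_bh, "ties": ties},
    )
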