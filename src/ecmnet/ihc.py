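"""Score-level immunohistochemistry computations.

Operates on cell/pixel measurement tables exported from image-analysis
software (segmentation itself is out of scope): the H-score from
per-cell cytoplasmic DAB optical densities, positive-pixel fractions,
section-preservation-adjusted TIL densities, a 1-D three-component
Gaussian mixture for low/intermediate/high case grouping, and the
proteomics-vs-IHC concordance test.

Intensity bins are closed on the left: with the default cutpoints a cell
at exactly 0.18 OD is moderate.  H = 100 * (weak + 2*moderate + 3*strong)
over bin fractions, so H is bounded in [0, 300].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_OD_THRESHOLDS = (0.14, 0.18, 0.23)   # weak / moderate / strong cutpoints
DEFAULT_PIXEL_THRESHOLD = 0.15
DEFAULT_AREA_FACTOR = 1.274                  # counts -> cells per mm^2
MIN_PRESERVATION = 0.5


@dataclass(frozen=True)
class CoreScore:
    core_id: object
    h_score: float
    fractions: dict                           # negative/weak/moderate/strong -> fraction
    n_cells: int


def h_score(cell_ods, thresholds=DEFAULT_OD_THRESHOLDS, core_id=None) -> CoreScore:
    """H-score of one core from per-cell mean DAB optical densities.

    Bins (closed on the left): negative < t1; weak [t1, t2); moderate
    [t2, t3); strong >= t3.
    """
    od = np.asarray(cell_ods, dtype=float)
    od = od[~np.isnan(od)]
    if od.size == 0:
        raise ValueError("empty core: no cell measurements")
    if (od < 0).any():
        raise ValueError("optical densities must be >= 0")
    t1, t2, t3 = thresholds
    if not (t1 < t2 < t3):
        raise ValueError("thresholds must be strictly increasing")
    fractions = {
        "negative": float((od < t1).mean()),
        "weak": float(((od >= t1) & (od < t2)).mean()),
        "moderate": float(((od >= t2) & (od < t3)).mean()),
        "strong": float((od >= t3).mean()),
    }
    h = 100.0 * (fractions["weak"] + 2.0 * fractions["moderate"] + 3.0 * fractions["strong"])
    return CoreScore(core_id=core_id, h_score=h, fractions=fractions, n_cells=int(od.size))


def h_score_table(cells: pd.DataFrame, od_col: str = "od", core_col: str = "core_id",
                  thresholds=DEFAULT_OD_THRESHOLDS) -> pd.DataFrame:
    """Per-core H-scores from a cell measurement table."""
    rows = []
    for core, grp in cells.groupby(core_col):
        score = h_score(grp[od_col].to_numpy(), thresholds=thresholds, core_id=core)
        rows.append({core_col: core, "h_score": score.h_score, "n_cells": score.n_cells,
                     **{f"frac_{k}": v for k, v in score.fractions.items()}})
    return pd.DataFrame(rows).set_index(core_col)


def positive_pixel_fraction(pixel_ods, threshold: float = DEFAULT_PIXEL_THRESHOLD) -> float:
    """Fraction of pixels at or above the positive-DAB threshold (inclusive)."""
    od = np.asarray(pixel_ods, dtype=float)
    od = od[~np.isnan(od)]
    if od.size == 0:
        raise ValueError("empty pixel input")
    return float((od >= threshold).mean())


def til_density(counts, preservation_fractions, area_factor: float = DEFAULT_AREA_FACTOR):
    """Preservation-adjusted TIL density in cells/mm^2.

    Each replicate count is scaled to 100% section area (count divided by
    its preservation fraction); replicates below 50% preservation are
    excluded; the surviving replicates are averaged and multiplied by the
    area-normalization factor.  Returns NaN when every replicate is
    excluded.
    """
    counts = np.asarray(counts, dtype=float)
    pres = np.asarray(preservation_fractions, dtype=float)
    if counts.shape != pres.shape:
        raise ValueError("counts and preservation fractions must align")
    if ((pres <= 0) | (pres > 1)).any():
        raise ValueError("preservation fractions must be in (0, 1]")
    keep = pres >= MIN_PRESERVATION
    if not keep.any():
        logger.warning("all replicates below %d%% preservation; masked result",
                       int(100 * MIN_PRESERVATION))
        return float("nan")
    adjusted = counts[keep] / pres[keep]
    return float(adjusted.mean() * area_factor)


# ---------------------------------------------------------------------------
# 1-D three-component Gaussian mixture (EM)


@dataclass
class GmmResult:
    means: np.ndarray                 # ascending
    sds: np.ndarray
    weights: np.ndarray
    assignments: pd.Series            # case -> low / intermediate / high
    log_likelihood: float
    converged: bool
    n_iter: int
    extras: dict = field(default_factory=dict)


_GMM_LABELS = ("low", "intermediate", "high")


def _em_1d(x: np.ndarray, means: np.ndarray, max_iter: int, tol: float,
           var_floor: float):
    """EM for a 1-D k-component Gaussian mixture from given initial means.

    The log-likelihood is asserted non-decreasing at every iteration (a
    guaranteed property of EM; a violation indicates a numerical bug).
    """
    k = means.size
    weights = np.full(k, 1.0 / k)
    variances = np.full(k, max(x.var(), var_floor))
    means = means.astype(float).copy()
    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dens = np.array([
            weights[j] * stats.norm.pdf(x, means[j], np.sqrt(variances[j]))
            for j in range(k)
        ])
        total = dens.sum(axis=0)
        total = np.where(total <= 0, np.finfo(float).tiny, total)
        ll = float(np.log(total).sum())
        assert ll >= prev_ll - 1e-8, "EM log-likelihood decreased"
        resp = dens / total
        nk = resp.sum(axis=1)
        nk = np.where(nk <= 0, np.finfo(float).tiny, nk)
        weights = nk / x.size
        means = (resp @ x) / nk
        variances = np.maximum(
            (resp * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk, var_floor
        )
        if abs(ll - prev_ll) < tol * max(abs(ll), 1.0):
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    return means, np.sqrt(variances), weights, prev_ll, converged, n_iter


def gmm_three_groups(case_scores, seed: int = 0, n_restarts: int = 5,
                     max_iter: int = 500, tol: float = 1e-10,
                     var_floor: float = 1e-6) -> GmmResult:
    """Fit three Gaussian components to per-case mean scores by EM.

    Restarts from quantile-based initializations (plus seeded jitter) and
    keeps the best likelihood; components are labelled low / intermediate /
    high by ascending mean.  Refuses degenerate input (all scores equal or
    fewer than 9 cases).
    """
    scores = pd.Series(case_scores, dtype=float).dropna()
    if scores.size < 9:
        raise ValueError("need >= 9 cases for a 3-component mixture")
    x = scores.to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("all scores identical; mixture is degenerate")
    rng = np.random.default_rng(seed)
    spread = x.std()
    base = np.quantile(x, [1 / 6, 3 / 6, 5 / 6])
    best = None
    for r in range(n_restarts):
        init = base if r == 0 else np.sort(base + rng.normal(0, 0.25 * spread, size=3))
        fit = _em_1d(x, init, max_iter=max_iter, tol=tol, var_floor=var_floor)
        if best is None or fit[3] > best[3]:
            best = fit
    means, sds, weights, ll, converged, n_iter = best
    if not converged:
        logger.warning("GMM did not converge within %d iterations", max_iter)
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    dens = np.array([
        weights[j] * stats.norm.pdf(x, means[j], sds[j]) for j in range(3)
    ])
    comp = dens.argmax(axis=0)
    assignments = pd.Series([_GMM_LABELS[c] for c in comp], index=scores.index)
    return GmmResult(means=means, sds=sds, weights=weights, assignments=assignments,
                     log_likelihood=float(ll), converged=bool(converged),
                     n_iter=int(n_iter), extras={"n_restarts": n_restarts, "seed": seed})


def compare_proteomic_vs_ihc(proteomic_values, ihc_clusters, min_per_cluster: int = 3) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney of proteomic values between IHC clusters."""
    values = pd.Series(proteomic_values, dtype=float)
    clusters = pd.Series(ihc_clusters).reindex(values.index)
    ok = values.notna() & clusters.notna()
    values, clusters = values[ok], clusters[ok]
    usable = [c for c in pd.unique(clusters) if (clusters == c).sum() >= min_per_cluster]
    skipped = set(pd.unique(clusters)) - set(usable)
    if skipped:
        logger.warning("clusters below %d cases excluded: %s", min_per_cluster, sorted(skipped))
    if len(usable) < 2:
        raise ValueError("need >= 2 clusters with enough cases")
    rows = []
    for i, a in enumerate(usable):
        for b in usable[i + 1:]:
            va = values[clusters == a].to_numpy()
            vb = values[clusters == b].to_numpy()
            if np.ptp(np.concatenate([va, vb])) == 0:
                u, p = len(va) * len(vb) / 2.0, 1.0
            else:
                u, p = stats.mannwhitneyu(va, vb, alternative="two-sided")
            rows.append({"cluster_a": a, "cluster_b": b, "n_a": len(va), "n_b": len(vb),
                         "U": float(u), "p_value": float(p)})
    return pd.DataFrame(rows)
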