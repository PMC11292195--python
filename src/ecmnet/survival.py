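"""Kaplan-Meier estimation, log-rank testing, Cox regression and stratification.

Thin, contract-checked wrappers around lifelines: the product-limit
estimator, the O-E / hypergeometric-variance log-rank statistic, and Cox
proportional-hazards fits with Efron tie handling (Breslow selectable) and
two-sided Wald inference.  Score-based stratification (median or tertile
rules, with an optional low-vs-rest combination) turns continuous patient
scores into the strata those tests compare.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

SEPARATION_COEF_LIMIT = 15.0  # |log HR| beyond this is treated as monotone likelihood


def km_curve(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step table with one row per distinct time: time, survival,
    at_risk (just before the time), events and censored at that time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need >= 1 record")
    if (times < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table.copy()
    out = pd.DataFrame({
        "time": table.index.to_numpy(dtype=float),
        "at_risk": table["at_risk"].to_numpy(dtype=int),
        "events": table["observed"].to_numpy(dtype=int),
        "censored": table["censored"].to_numpy(dtype=int),
    })
    out["survival"] = kmf.survival_function_at_times(out["time"]).to_numpy()
    return out[out["time"] > 0].reset_index(drop=True) if 0 not in times else out.reset_index(drop=True)


def log_rank(groups) -> dict:
    """Log-rank test across >= 2 groups of (times, events) records.

    groups : list of (times, events) pairs.
    Returns {"statistic", "df", "p_value"} with df = n_groups - 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {g} has zero subjects")
        if (t < 0).any():
            raise ValueError("negative survival time")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    if sum(e.sum() for e in events) == 0:
        raise ValueError("need >= 1 event in total")
    res = multivariate_logrank_test(np.concatenate(times), np.concatenate(labels),
                                    np.concatenate(events))
    return {"statistic": float(res.test_statistic), "df": len(groups) - 1,
            "p_value": float(res.p_value)}


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald inference."""

    table: pd.DataFrame               # coef, hr, hr_lower, hr_upper, se, z, p
    log_likelihood: float
    ties: str
    n: int
    n_events: int
    non_estimable: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "p"])


def cox_fit(records: pd.DataFrame, covariates=None, duration_col: str = "time",
            event_col: str = "event", ties: str = "efron") -> CoxResult:
    """Cox proportional-hazards fit with Wald CIs.

    records : DataFrame with duration, event and covariate columns;
    categorical covariates are expanded to treatment-coded indicators.
    Covariates with |log HR| beyond a divergence limit (monotone
    likelihood / perfect separation) are reported in ``non_estimable``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    df = records.copy()
    if covariates is None:
        covariates = [c for c in df.columns if c not in (duration_col, event_col)]
    df = df[[duration_col, event_col, *covariates]].dropna()
    for cov in covariates:
        if df[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")
    cat_cols = [c for c in covariates if not pd.api.types.is_numeric_dtype(df[c])]
    design = pd.get_dummies(df, columns=cat_cols, drop_first=True, dtype=float)
    n_events = int(design[event_col].sum())
    n_covs = design.shape[1] - 2
    fit_warnings = []
    if n_events < n_covs:
        raise ValueError(
            f"{n_events} events for {n_covs} covariates; model is not identifiable"
        )
    if ties == "efron":
        cph = CoxPHFitter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                cph.fit(design, duration_col=duration_col, event_col=event_col)
            except ConvergenceError as err:
                raise ValueError(f"Cox fit did not converge: {err}") from err
            fit_warnings.extend(str(w.message) for w in caught)
        summary = cph.summary
        table = pd.DataFrame({
            "coef": summary["coef"],
            "hr": summary["exp(coef)"],
            "hr_lower": summary["exp(coef) lower 95%"],
            "hr_upper": summary["exp(coef) upper 95%"],
            "se": summary["se(coef)"],
            "z": summary["z"],
            "p": summary["p"],
        })
        log_likelihood = float(cph.log_likelihood_)
    else:
        from statsmodels.duration.hazard_regression import PHReg
        exog_cols = [c for c in design.columns if c not in (duration_col, event_col)]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = PHReg(design[duration_col], design[exog_cols],
                          status=design[event_col], ties="breslow")
            fit = model.fit()
            fit_warnings.extend(str(w.message) for w in caught)
        coef = pd.Series(fit.params, index=exog_cols)
        se = pd.Series(fit.bse, index=exog_cols)
        z = coef / se
        table = pd.DataFrame({
            "coef": coef,
            "hr": np.exp(coef),
            "hr_lower": np.exp(coef - 1.96 * se),
            "hr_upper": np.exp(coef + 1.96 * se),
            "se": se,
            "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
        })
        log_likelihood = float(model.loglike(fit.params))
    non_estimable = [c for c in table.index if abs(table.loc[c, "coef"]) > SEPARATION_COEF_LIMIT]
    if non_estimable:
        logger.warning("diverging coefficients (possible perfect separation): %s",
                       non_estimable)
    return CoxResult(
        table=table, log_likelihood=log_likelihood, ties=ties,
        n=int(design.shape[0]), n_events=n_events,
        non_estimable=non_estimable, warnings=fit_warnings,
    )


@dataclass
class StrataAssignment:
    strata: pd.Series                 # sample -> "low" / "intermediate" / "high"
    rule: str
    cutoffs: tuple
    combine: str | None = None

    def reapply(self, scores) -> pd.Series:
        """Reapplying the stored cutoffs reproduces the assignment."""
        return _apply_cutoffs(pd.Series(scores, dtype=float), self.rule,
                              self.cutoffs, self.combine)


def _apply_cutoffs(scores: pd.Series, rule: str, cutoffs, combine) -> pd.Series:
    out = pd.Series(index=scores.index, dtype=object)
    if rule == "median":
        (cut,) = cutoffs
        out[scores <= cut] = "low"
        out[scores > cut] = "high"
    else:
        lo, hi = cutoffs
        out[scores <= lo] = "low"
        out[(scores > lo) & (scores <= hi)] = "intermediate"
        out[scores > hi] = "high"
        if combine == "intermediate+high":
            out = out.replace({"intermediate": "high"})
    out[scores.isna()] = np.nan
    return out


def stratify(scores, rule: str = "median", combine: str | None = None) -> StrataAssignment:
    """Split continuous scores into low/high (median) or tertile strata.

    The median rule assigns ``low`` to scores <= the cohort median
    (ties at the cutoff go low).  The tertile rule bins at the empirical
    tertiles; ``combine='intermediate+high'`` merges the upper two bins to
    give the low-vs-rest contrast used for single-marker tertile analyses.
    """
    scores = pd.Series(scores, dtype=float)
    observed = scores.dropna()
    if rule == "median":
        if observed.size < 2:
            raise ValueError("median rule needs >= 2 non-missing scores")
        if combine is not None:
            raise ValueError("combine only applies to the tertile rule")
        cutoffs = (float(observed.median()),)
    elif rule == "tertile":
        if observed.size < 3:
            raise ValueError("tertile rule needs >= 3 non-missing scores")
        cutoffs = tuple(float(q) for q in observed.quantile([1 / 3, 2 / 3]))
    else:
        raise ValueError("rule must be 'median' or 'tertile'")
    if observed.nunique() == 1:
        raise ValueError("all scores identical; no informative split")
    strata = _apply_cutoffs(scores, rule, cutoffs, combine)
    if strata.dropna().nunique() < 2:
        raise ValueError("stratification produced a single stratum")
    return StrataAssignment(strata=strata, rule=rule, cutoffs=cutoffs, combine=combine)


def administrative_censor(times, events, horizon: float = 60.0):
    """Censor all follow-up at a fixed horizon (e.g. 60 months for 5-year framing)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    capped = np.minimum(times, horizon)
    return capped, np.where(times <= horizon, events, 0)


def uva_significant_covariates(records: pd.DataFrame, covariates,
                               duration_col: str = "time", event_col: str = "event",
                               alpha: float = 0.05, ties: str = "efron") -> list:
    """Covariates significant in univariable Cox fits (any expanded level).

    Implements the usual preselection for multivariable models: a
    covariate enters the multivariable model when its univariable Wald
    p-value is below ``alpha``.
    """
    selected = []
    for cov in covariates:
        sub = records[[duration_col, event_col, cov]].dropna()
        if sub[cov].nunique() < 2:
            continue
        try:
            res = cox_fit(sub, [cov], duration_col, event_col, ties=ties)
        except ValueError:
            continue
        if (res.table["p"] < alpha).any():
            selected.append(cov)
    return selected
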