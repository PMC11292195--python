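import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ecmnet import survival


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_four_events_no_censoring():
    km = survival.km_curve([1, 2, 3, 4], [1, 1, 1, 1])
    np.testing.assert_allclose(km["survival"], [0.75, 0.5, 0.25, 0.0])
    np.testing.assert_allclose(km["at_risk"], [4, 3, 2, 1])


def test_km_censored_then_event():
    # product-limit: S(t) = 1 for t < 10, S(10) = 0 (risk set size 1 at t=10)
    km = survival.km_curve([5, 10], [0, 1])
    s_at = dict(zip(km["time"], km["survival"]))
    assert s_at[5.0] == 1.0
    assert s_at[10.0] == 0.0


def test_km_all_censored_stays_at_one():
    km = survival.km_curve([3, 6, 9], [0, 0, 0])
    assert (km["survival"] == 1.0).all()


def test_km_equals_one_minus_ecdf_without_censoring():
    rng = np.random.default_rng(0)
    times = rng.exponential(10, 40)
    km = survival.km_curve(times, np.ones(40, dtype=int))
    for t, s in zip(km["time"], km["survival"]):
        assert s == pytest.approx(1.0 - (times <= t).mean(), abs=1e-12)


def test_km_rejects_negative_times():
    with pytest.raises(ValueError, match="negative"):
        survival.km_curve([-1, 2], [1, 1])


# ---------------------------------------------------------------------------
# Log-rank


def logrank_oracle_two_groups(t1, e1, t2, e2):
    """Hand-tabulated O - E / hypergeometric variance over shared risk sets."""
    records = [(t, e, 0) for t, e in zip(t1, e1)] + [(t, e, 1) for t, e in zip(t2, e2)]
    event_times = sorted({t for t, e, _ in records if e == 1})
    o_minus_e, var = 0.0, 0.0
    for et in event_times:
        at_risk = [(t, e, g) for t, e, g in records if t >= et]
        n = len(at_risk)
        n1 = sum(1 for t, e, g in at_risk if g == 0)
        d = sum(1 for t, e, g in at_risk if e == 1 and t == et)
        d1 = sum(1 for t, e, g in at_risk if e == 1 and t == et and g == 0)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_log_rank_identical_groups():
    t = [2, 4, 6, 8]
    e = [1, 0, 1, 1]
    res = survival.log_rank([(t, e), (t, e)])
    assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
    assert res["p_value"] == pytest.approx(1.0)


def test_log_rank_matches_hand_tabulation_on_8_subjects():
    t1, e1 = [1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1]
    t2, e2 = [5.0, 6.0, 7.0, 8.0], [1, 0, 1, 1]
    res = survival.log_rank([(t1, e1), (t2, e2)])
    oracle = logrank_oracle_two_groups(t1, e1, t2, e2)
    assert res["statistic"] == pytest.approx(oracle, rel=1e-9)
    assert res["df"] == 1


def test_log_rank_df_contract_and_errors():
    t = [1, 2, 3]
    e = [1, 1, 0]
    res = survival.log_rank([(t, e), (t, e), ([4, 5, 6], [1, 0, 1])])
    assert res["df"] == 2
    with pytest.raises(ValueError, match="zero subjects"):
        survival.log_rank([(t, e), ([], [])])
    with pytest.raises(ValueError, match="event"):
        survival.log_rank([([1, 2], [0, 0]), ([3], [0])])


# ---------------------------------------------------------------------------
# Cox


def cox_partial_loglik_1d(beta, times, events, x):
    """Breslow partial log-likelihood for one covariate (no ties in the toy)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return ll


def test_cox_coefficient_matches_1d_grid_search():
    rng = np.random.default_rng(12)
    n = 20
    x = rng.integers(0, 2, n).astype(float)
    times = rng.exponential(1.0 / (0.1 * np.exp(0.9 * x)))
    events = np.ones(n, dtype=int)
    assert len(np.unique(times)) == n   # no ties: Efron == Breslow
    df = pd.DataFrame({"time": times, "event": events, "x": x})
    res = survival.cox_fit(df, ["x"])
    oracle = optimize.minimize_scalar(
        lambda b: -cox_partial_loglik_1d(b, times, events, x),
        bounds=(-5, 5), method="bounded",
        options={"xatol": 1e-8}).x
    assert res.table.loc["x", "coef"] == pytest.approx(oracle, abs=1e-3)
    assert res.table.loc["x", "hr_lower"] < res.hr("x") < res.table.loc["x", "hr_upper"]


def test_cox_duplicating_records_preserves_hr():
    # the likelihood-scaling property is exact under Breslow ties (the
    # Efron correction re-weights within tied groups, so it is only
    # approximate there)
    rng = np.random.default_rng(3)
    n = 30
    x = rng.standard_normal(n)
    times = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x)))
    df = pd.DataFrame({"time": times, "event": 1, "x": x})
    single = survival.cox_fit(df, ["x"], ties="breslow")
    doubled = survival.cox_fit(pd.concat([df, df], ignore_index=True), ["x"],
                               ties="breslow")
    assert doubled.table.loc["x", "coef"] == pytest.approx(
        single.table.loc["x", "coef"], abs=1e-6)
    assert doubled.table.loc["x", "se"] < single.table.loc["x", "se"]


def test_cox_efron_and_breslow_agree_without_ties():
    rng = np.random.default_rng(4)
    n = 40
    x = rng.standard_normal(n)
    times = rng.exponential(1.0 / (0.05 * np.exp(0.6 * x)))
    df = pd.DataFrame({"time": times, "event": 1, "x": x})
    efron = survival.cox_fit(df, ["x"], ties="efron")
    breslow = survival.cox_fit(df, ["x"], ties="breslow")
    assert efron.table.loc["x", "coef"] == pytest.approx(
        breslow.table.loc["x", "coef"], abs=1e-5)


def test_cox_detects_separation():
    # events all in one covariate arm and strictly earlier -> monotone likelihood
    df = pd.DataFrame({
        "time": [1, 2, 3, 4, 11, 12, 13, 14],
        "event": [1, 1, 1, 1, 1, 1, 1, 1],
        "x": [1.0, 1, 1, 1, 0, 0, 0, 0],
    })
    res = survival.cox_fit(df, ["x"])
    assert "x" in res.non_estimable


def test_cox_refuses_constant_covariate_and_overparameterization():
    df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 0, 0],
                       "x": [1.0, 1.0, 1.0]})
    with pytest.raises(ValueError, match="constant"):
        survival.cox_fit(df, ["x"])
    df2 = pd.DataFrame({"time": [1, 2, 3], "event": [1, 0, 0],
                        "a": [1.0, 2, 3], "b": [4.0, 5, 7]})
    with pytest.raises(ValueError, match="identifiable"):
        survival.cox_fit(df2, ["a", "b"])


def test_log_rank_agrees_with_cox_score_direction():
    # two-group log-rank statistic approx equals squared Wald z of binary Cox
    rng = np.random.default_rng(8)
    n = 100
    grp = rng.integers(0, 2, n)
    times = rng.exponential(1.0 / (0.05 * np.exp(0.8 * grp)))
    events = np.ones(n, dtype=int)
    lr = survival.log_rank([(times[grp == 0], events[grp == 0]),
                            (times[grp == 1], events[grp == 1])])
    cox = survival.cox_fit(pd.DataFrame({"time": times, "event": events,
                                         "g": grp.astype(float)}), ["g"])
    z2 = cox.table.loc["g", "z"] ** 2
    assert lr["statistic"] == pytest.approx(z2, rel=0.1)


# ---------------------------------------------------------------------------
# Stratification


def test_stratify_median_rule_inclusive():
    scores = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
    res = survival.stratify(scores, rule="median")
    assert set(res.strata[res.strata == "low"].index) == {"a", "b"}
    assert set(res.strata[res.strata == "high"].index) == {"c", "d"}
    # ties straddling the median all go low
    tied = pd.Series({"a": 1.0, "b": 2.0, "c": 2.0, "d": 2.0, "e": 9.0})
    res_t = survival.stratify(tied, rule="median")
    assert (res_t.strata[["b", "c", "d"]] == "low").all()


def test_stratify_tertile_and_combine():
    scores = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
    res = survival.stratify(scores, rule="tertile")
    assert res.strata.tolist() == ["low", "intermediate", "high"]
    res_c = survival.stratify(pd.Series([1.0, 2, 3, 4, 5, 6]), rule="tertile",
                              combine="intermediate+high")
    assert set(res_c.strata.unique()) == {"low", "high"}
    assert (res_c.strata == "low").sum() == 2


def test_stratify_reapply_reproduces_assignment():
    rng = np.random.default_rng(5)
    scores = pd.Series(rng.standard_normal(50))
    res = survival.stratify(scores, rule="tertile")
    pd.testing.assert_series_equal(res.reapply(scores), res.strata)


def test_stratify_refuses_degenerate_input():
    with pytest.raises(ValueError, match="identical"):
        survival.stratify(pd.Series([2.0, 2.0, 2.0]))
    with pytest.raises(ValueError, match=">= 3"):
        survival.stratify(pd.Series([1.0, 2.0]), rule="tertile")


def test_administrative_censoring_at_60_months():
    times, events = survival.administrative_censor([30, 70, 60], [1, 1, 1], horizon=60)
    np.testing.assert_allclose(times, [30, 60, 60])
    np.testing.assert_allclose(events, [1, 0, 1])
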