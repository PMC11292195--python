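import numpy as np
import pandas as pd
import pytest

from ecmnet import diffexp
from ecmnet._stats import bh_adjust


def brute_force_bh(pvalues):
    """Independent step-up implementation of Benjamini-Hochberg."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * n / rank_from_top)
        q[i] = running_min
    return q


def test_bh_matches_stepup_on_hand_vector():
    p = np.array([0.001, 0.01, 0.02, 0.04, 0.05])
    np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("n", [7, 100, 1000])
def test_bh_matches_stepup_on_random_vectors(seed, n):
    p = np.random.default_rng(seed).uniform(size=n)
    np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def make_matrix(n_proteins=50, n_samples=60, seed=0, sd=0.3):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(0, sd, (n_proteins, n_samples)),
                      index=[f"P{i:03d}" for i in range(n_proteins)],
                      columns=[f"s{j:03d}" for j in range(n_samples)])
    labels = pd.Series(["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2),
                       index=df.columns)
    return df, labels


def test_one_vs_rest_fold_change_threshold_is_inclusive():
    # group mean exactly 1.0 log2 unit above rest (fold change exactly 2)
    base = np.tile([0.0, 1.0], 10)
    df = pd.DataFrame(
        np.vstack([np.concatenate([base + 1.0, base]),
                   np.concatenate([base, base])]),
        index=["shifted", "flat"],
        columns=[f"s{j}" for j in range(40)])
    labels = pd.Series(["A"] * 20 + ["B"] * 20, index=df.columns)
    res = diffexp.one_vs_rest_de(df, labels, "A", min_n=20)
    assert res.loc["shifted", "delta_log2"] == 1.0
    assert res.loc["shifted", "q_value"] < 0.01
    assert bool(res.loc["shifted", "upregulated"])
    assert res.loc["flat", "delta_log2"] == 0.0
    assert not res.loc["flat", "upregulated"]


def test_one_vs_rest_refuses_small_groups():
    df, labels = make_matrix(n_samples=30)
    with pytest.raises(ValueError, match="below min_n"):
        diffexp.one_vs_rest_de(df, labels, "A", min_n=20)


def test_flags_invariant_to_column_order_and_constant_shift():
    df, labels = make_matrix(seed=5)
    df.iloc[0, (labels == "A").to_numpy()] += 2.0
    res = diffexp.one_vs_rest_de(df, labels, "A", min_n=10)
    perm = np.random.default_rng(1).permutation(df.columns)
    res_perm = diffexp.one_vs_rest_de(df[perm], labels[perm], "A", min_n=10)
    pd.testing.assert_series_equal(res["upregulated"], res_perm["upregulated"])
    res_shift = diffexp.one_vs_rest_de(df + 7.5, labels, "A", min_n=10)
    pd.testing.assert_series_equal(res["upregulated"], res_shift["upregulated"])
    np.testing.assert_allclose(res["delta_log2"], res_shift["delta_log2"], atol=1e-9)


def test_unique_upregulation_assigns_exclusive_sets():
    rng = np.random.default_rng(7)
    n_per = 30
    cols = [f"s{j}" for j in range(3 * n_per)]
    labels = pd.Series(["A"] * n_per + ["B"] * n_per + ["C"] * n_per, index=cols)
    df = pd.DataFrame(rng.normal(0, 0.3, (20, 3 * n_per)), columns=cols,
                      index=[f"P{i}" for i in range(20)])
    df.loc["P0", labels == "A"] += 2.0                 # unique to A
    df.loc["P1", labels.isin(["A", "B"])] += 3.0       # shared A and B
    unique = diffexp.unique_upregulation(df, labels, ["A", "B", "C"], min_n=20)
    assert "P0" in unique["A"]
    assert all("P1" not in s for s in unique.values())
    # pairwise disjoint
    assert not (unique["A"] & unique["B"]) and not (unique["A"] & unique["C"])


def test_unique_upregulation_all_empty_when_no_signal():
    df, labels = make_matrix(seed=11)
    unique = diffexp.unique_upregulation(df, labels, ["A", "B"], min_n=20)
    assert all(len(s) == 0 for s in unique.values())


def test_two_group_copies_yield_no_flags():
    rng = np.random.default_rng(3)
    half = rng.normal(0, 0.5, (30, 10))
    df = pd.DataFrame(np.hstack([half, half]),
                      columns=[f"s{j}" for j in range(20)])
    labels = pd.Series(["T"] * 10 + ["C"] * 10, index=df.columns)
    res = diffexp.two_group_de(df, labels, "T", "C")
    assert not res["upregulated"].any()
    assert np.allclose(res["delta_log2"], 0.0)


def test_two_group_detects_large_shift_and_is_antisymmetric():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(rng.normal(0, 0.2, (15, 20)),
                      columns=[f"s{j}" for j in range(20)])
    labels = pd.Series(["T"] * 10 + ["C"] * 10, index=df.columns)
    df.loc[0, labels == "T"] += 3.0
    res = diffexp.two_group_de(df, labels, "T", "C")
    assert bool(res.loc[0, "upregulated"])
    swapped = diffexp.two_group_de(df, labels, "C", "T")
    np.testing.assert_allclose(res["delta_log2"], -swapped["delta_log2"], atol=1e-12)
    assert bool(swapped.loc[0, "downregulated"])


def test_stratum_robustness_null_and_shifted():
    rng = np.random.default_rng(6)
    df = pd.DataFrame(rng.normal(0, 1, (200, 90)),
                      columns=[f"s{j}" for j in range(90)])
    strata = pd.Series(["low"] * 30 + ["mid"] * 30 + ["high"] * 30, index=df.columns)
    table, summary = diffexp.stratum_robustness(df, strata)
    frac = summary["fraction_significant_proteins"]
    assert 0.02 <= frac <= 0.09        # 95% binomial band around 0.05, n=200
    assert summary["global_median_p"] > 0.05
    df.loc[0, strata == "high"] += 5.0
    table2, _ = diffexp.stratum_robustness(df, strata)
    assert table2.loc[0, "p_value"] < 1e-3


def test_stratum_robustness_single_stratum_errors():
    df = pd.DataFrame(np.zeros((3, 4)), columns=list("abcd"))
    with pytest.raises(ValueError, match="2 strata"):
        diffexp.stratum_robustness(df, pd.Series(["x"] * 4, index=df.columns))


def test_small_stratum_merged_with_warning(caplog):
    rng = np.random.default_rng(8)
    df = pd.DataFrame(rng.normal(0, 1, (5, 11)), columns=[f"s{j}" for j in range(11)])
    strata = pd.Series(["a"] * 5 + ["b"] * 5 + ["c"], index=df.columns)
    with caplog.at_level("WARNING"):
        _, summary = diffexp.stratum_robustness(df, strata)
    assert summary["strata"] == ["a", "b"]
    assert summary["n_per_stratum"]["b"] == 6


# ---------------------------------------------------------------------------
# SAM


def sam_toy(seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(0, 1, (20, 6))
    vals[0, :3] += 10.0
    df = pd.DataFrame(vals, columns=list("abcdef"),
                      index=[f"P{i}" for i in range(20)])
    labels = pd.Series(["A"] * 3 + ["B"] * 3, index=df.columns)
    return df, labels


def test_sam_identical_groups_give_zero_d():
    half = np.tile(np.arange(5, dtype=float)[:, None], (1, 3))
    df = pd.DataFrame(np.hstack([half, half]), columns=list("abcdef"))
    labels = pd.Series(["A"] * 3 + ["B"] * 3, index=df.columns)
    res = diffexp.sam_two_class(df, labels, seed=0, s0_strategy=1.0)
    assert np.allclose(res.d_statistic, 0.0)
    assert len(res.significant) == 0


@pytest.mark.parametrize("s0_strategy", ["median", "zero", "percentile_scan"])
def test_sam_separated_protein_has_largest_d(s0_strategy):
    df, labels = sam_toy()
    res = diffexp.sam_two_class(df, labels, seed=0, s0_strategy=s0_strategy)
    assert res.d_statistic.abs().idxmax() == "P0"
    assert res.exhaustive and res.n_permutations_used == 20
    assert ((res.fdr_table["fdr"] >= 0) & (res.fdr_table["fdr"] <= 1)).all()


def test_sam_exhaustive_enumeration_is_deterministic_and_antisymmetric():
    df, labels = sam_toy()
    res1 = diffexp.sam_two_class(df, labels, group_a="A", seed=0)
    res2 = diffexp.sam_two_class(df, labels, group_a="A", seed=99)
    pd.testing.assert_series_equal(res1.d_statistic, res2.d_statistic)
    pd.testing.assert_frame_equal(res1.fdr_table, res2.fdr_table)
    swapped = diffexp.sam_two_class(df, labels, group_a="B", seed=0)
    np.testing.assert_allclose(res1.d_statistic, -swapped.d_statistic, atol=1e-12)


def test_sam_random_subset_reproducible_with_seed():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(rng.normal(0, 1, (10, 16)),
                      columns=[f"s{j}" for j in range(16)])
    labels = pd.Series(["A"] * 8 + ["B"] * 8, index=df.columns)
    res1 = diffexp.sam_two_class(df, labels, n_permutations=50, seed=5)
    res2 = diffexp.sam_two_class(df, labels, n_permutations=50, seed=5)
    assert not res1.exhaustive
    pd.testing.assert_frame_equal(res1.fdr_table, res2.fdr_table)
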