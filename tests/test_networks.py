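import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecmnet import networks
from conftest import make_block_matrix


# ---------------------------------------------------------------------------
# Pearson similarity


def test_pearson_matches_direct_covariance_formula():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([2.0, 4.0, 5.0, 9.0])
    df = pd.DataFrame([x, y], index=["a", "b"], columns=list("wxyz"))
    sim = networks.correlation_similarity(df, min_pairs=2)
    # brute-force Pearson from raw sums
    r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
    assert sim.values.loc["a", "b"] == pytest.approx(r_oracle, abs=1e-12)


def test_duplicated_and_negated_rows():
    x = np.array([0.5, 1.5, -1.0, 2.0, 0.0])
    df = pd.DataFrame([x, x.copy(), -x], index=["a", "a2", "neg"],
                      columns=[f"s{i}" for i in range(5)])
    sim = networks.correlation_similarity(df, min_pairs=3)
    assert sim.values.loc["a", "a2"] == pytest.approx(1.0)
    assert sim.values.loc["a", "neg"] == pytest.approx(-1.0)
    assert np.allclose(np.diag(sim.values), 1.0)


def test_min_pairs_masking_and_zero_variance(caplog):
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.standard_normal((3, 12)),
                      index=["a", "b", "const"],
                      columns=[f"s{i}" for i in range(12)])
    df.loc["b", df.columns[:8]] = np.nan      # only 4 joint observations with a
    df.loc["const"] = 3.14
    with caplog.at_level("WARNING"):
        sim = networks.correlation_similarity(df, min_pairs=5)
    assert np.isnan(sim.values.loc["a", "b"])
    assert sim.pair_n.loc["a", "b"] == 4
    assert np.isnan(sim.values.loc["a", "const"])


def test_similarity_invariant_to_affine_rescaling():
    df, _ = make_block_matrix(n_blocks=2, n_proteins=5, n_samples=30, seed=3)
    sim = networks.correlation_similarity(df)
    rescaled = df.mul(np.linspace(0.5, 3.0, len(df)), axis=0).add(
        np.arange(len(df)), axis=0)
    sim2 = networks.correlation_similarity(rescaled)
    np.testing.assert_allclose(sim.values, sim2.values, atol=1e-10)


# ---------------------------------------------------------------------------
# Consensus clustering


def test_exact_duplicate_profiles_give_binary_consensus():
    a = np.array([0.0, 0.0, 5.0, 5.0, 0.0, 1.0])
    b = np.array([5.0, 5.0, 0.0, 0.0, 1.0, 0.0])
    df = pd.DataFrame([a, a, a, b, b, b], index=list("uvwxyz"),
                      columns=[f"s{i}" for i in range(6)])
    res = networks.consensus_cluster(df, k_range=[2], n_resamples=50,
                                     subsample_fraction=0.9, seed=0)
    cons = res.consensus[2]
    within_u = cons.loc["u", "v"]
    between = cons.loc["u", "x"]
    assert within_u == pytest.approx(1.0)
    assert between == pytest.approx(0.0)
    assert res.assignments["u"] == res.assignments["v"] != res.assignments["x"]


def test_consensus_recovers_three_blocks(block_matrix):
    from sklearn.metrics import adjusted_rand_score
    df, truth = block_matrix
    sim = networks.correlation_similarity(df)
    res = networks.consensus_cluster(sim, k_range=range(2, 7), n_resamples=80, seed=4)
    assert res.chosen_k == 3
    assert adjusted_rand_score(truth, res.assignments.to_numpy()) > 0.9
    assert res.stable
    for cons in res.consensus.values():
        vals = cons.to_numpy()
        assert vals.min() >= 0 and vals.max() <= 1
        assert np.allclose(np.diag(vals), 1.0)


def test_structureless_data_is_flagged_unstable():
    rng = np.random.default_rng(9)
    df = pd.DataFrame(rng.standard_normal((40, 200)),
                      index=[f"p{i}" for i in range(40)])
    sim = networks.correlation_similarity(df)
    res = networks.consensus_cluster(sim, k_range=range(2, 6), n_resamples=60, seed=1)
    assert not res.stable
    assert min(res.pac.values()) > networks.STABLE_PAC_THRESHOLD


def test_consensus_permutation_equivariance():
    df, _ = make_block_matrix(n_blocks=2, n_proteins=8, n_samples=40, seed=6)
    res = networks.consensus_cluster(df, k_range=[2], n_resamples=60, seed=2)
    perm = np.random.default_rng(0).permutation(df.index)
    res_p = networks.consensus_cluster(df.loc[perm], k_range=[2], n_resamples=60, seed=2)
    # same partition regardless of item order (consensus uses per-item resampling,
    # so compare the induced partitions, not the matrices)
    co = res.assignments.loc[perm].to_numpy()
    co_p = res_p.assignments.to_numpy()
    from sklearn.metrics import adjusted_rand_score
    assert adjusted_rand_score(co, co_p) == pytest.approx(1.0)


def test_consensus_refuses_k1_only_and_tiny_inputs():
    df, _ = make_block_matrix(n_blocks=2, n_proteins=5, n_samples=20)
    with pytest.raises(ValueError, match="k_range"):
        networks.consensus_cluster(df, k_range=[1], n_resamples=10)
    with pytest.raises(ValueError, match="items"):
        networks.consensus_cluster(df.iloc[:4], k_range=[2, 5], n_resamples=10)


# ---------------------------------------------------------------------------
# SigClust


def test_sigclust_separated_clusters_significant():
    rng = np.random.default_rng(1)
    x = np.vstack([rng.standard_normal((15, 4)), rng.standard_normal((15, 4)) + 10.0])
    res = networks.sigclust(x, n_sim=500, seed=3)
    assert res["p_value"] < 0.01
    assert 0 < res["cluster_index"] < 1


def test_sigclust_deterministic_given_seed():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((25, 5))
    r1 = networks.sigclust(x, n_sim=150, seed=11)
    r2 = networks.sigclust(x, n_sim=150, seed=11)
    assert r1 == r2


def test_sigclust_rotation_invariance_loose():
    rng = np.random.default_rng(4)
    x = np.vstack([rng.standard_normal((20, 3)), rng.standard_normal((20, 3)) + 6.0])
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    p1 = networks.sigclust(x, n_sim=300, seed=5)["p_value"]
    p2 = networks.sigclust(x @ q, n_sim=300, seed=5)["p_value"]
    assert abs(p1 - p2) <= 0.05


def test_sigclust_low_nsim_warns():
    x = np.random.default_rng(0).standard_normal((12, 3))
    with pytest.warns(UserWarning, match="resolution"):
        networks.sigclust(x, n_sim=50, seed=0)


# ---------------------------------------------------------------------------
# Cluster scores and associations


def test_cluster_median_score_conventions():
    df = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [1.0, 2.0, np.nan],
                       "s3": [np.nan, np.nan, np.nan]},
                      index=["p1", "p2", "p3"])
    assignments = pd.Series({"p1": 1, "p2": 1, "p3": 1})
    scores = networks.cluster_median_scores(df, assignments)
    assert scores.loc["s1", "C1"] == 2.0
    assert scores.loc["s2", "C1"] == 1.5
    assert np.isnan(scores.loc["s3", "C1"])
    even = pd.DataFrame({"s": [1.0, 2.0, 3.0, 10.0]}, index=list("abcd"))
    scores_even = networks.cluster_median_scores(even, pd.Series(1, index=list("abcd")))
    assert scores_even.loc["s", "C1"] == 2.5


def dunn_oracle(values, groups):
    """Direct textbook Dunn z computation (independent of the package path)."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    n = len(values)
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    ties = (counts**3 - counts).sum() / (12 * (n - 1))
    out = {}
    labels = list(dict.fromkeys(groups))
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ra, rb = ranks[groups == a].mean(), ranks[groups == b].mean()
            na, nb = (groups == a).sum(), (groups == b).sum()
            se = np.sqrt((n * (n + 1) / 12 - ties) * (1 / na + 1 / nb))
            z = (ra - rb) / se
            out[(a, b)] = (z, 2 * stats.norm.sf(abs(z)))
    return out


def test_dunn_matches_direct_formula_on_toy():
    values = np.array([1.0, 2, 3, 4, 5, 10, 11, 12, 13, 14, 2, 3, 3, 4, 20])
    groups = np.array(["a"] * 5 + ["b"] * 5 + ["c"] * 5)
    from ecmnet._stats import dunn_test
    table = dunn_test(values, groups)
    oracle = dunn_oracle(values, groups)
    for _, row in table.iterrows():
        z, p = oracle[(row.group_a, row.group_b)]
        assert row.z == pytest.approx(z, abs=1e-12)
        assert row.p == pytest.approx(p, abs=1e-12)


def make_clinical_scores(seed=0, shift_grade3=0.0):
    rng = np.random.default_rng(seed)
    n = 60
    subtype = np.array((["LMS"] * 20 + ["UPS"] * 20 + ["DES"] * 20))
    grade = np.array((["2"] * 10 + ["3"] * 10) * 3)
    scores = pd.DataFrame({"C1": rng.standard_normal(n)},
                          index=[f"s{i}" for i in range(n)])
    scores.loc[(grade == "3") & (subtype != "DES"), "C1"] += shift_grade3
    clin = pd.DataFrame({"subtype": subtype, "grade": grade}, index=scores.index)
    return scores, clin


def test_associate_scores_identical_groups_p_one():
    scores, clin = make_clinical_scores(seed=1)
    scores["C1"] = 1.0  # identical everywhere
    res = networks.associate_scores(scores, clin)
    assert (res["grade"]["p_value"] == 1.0).all()


def test_associate_scores_detects_grade_shift_and_excludes_des():
    scores, clin = make_clinical_scores(seed=2, shift_grade3=3.0)
    res = networks.associate_scores(scores, clin)
    row = res["grade"].iloc[0]
    assert row.p_value < 1e-3
    assert row.direction == "up_in_grade3"
    assert row.n_grade2 + row.n_grade3 == 40   # DES cases excluded
    assert "C1" in res["subtype_dunn"]


def test_associate_clinical_chi2_and_single_level():
    subgroups = pd.Series(["G1"] * 10 + ["G2"] * 10,
                          index=[f"s{i}" for i in range(20)])
    clin = pd.DataFrame({
        "sex": ["F"] * 10 + ["M"] * 10,          # perfectly associated
        "depth": ["deep"] * 20,                   # single level
    }, index=subgroups.index)
    res = networks.associate_clinical(subgroups, clin,
                                      categorical=["sex", "depth"], continuous=[])
    sex = res[res.variable == "sex"].iloc[0]
    assert sex.statistic == pytest.approx(20.0)   # textbook chi2 for [[10,0],[0,10]]
    assert sex.p_value < 1e-3
    depth = res[res.variable == "depth"].iloc[0]
    assert "skipped" in depth.note


def test_associate_clinical_til_median_split():
    rng = np.random.default_rng(3)
    subgroups = pd.Series(rng.choice(["G1", "G2"], 40),
                          index=[f"s{i}" for i in range(40)])
    til = pd.DataFrame({"CD3": rng.poisson(20, 40)}, index=subgroups.index)
    res = networks.associate_clinical(subgroups, pd.DataFrame(index=subgroups.index),
                                      categorical=[], continuous=[], til_counts=til)
    row = res[res.variable == "TIL_CD3"].iloc[0]
    assert "median-dichotomized" in row.note
    assert 0 <= row.p_value <= 1
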