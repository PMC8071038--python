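"""Subsampling engine, Box-Cox z-scores, empirical p-values, rankings."""

import warnings

import numpy as np
import pandas as pd
import pytest

from brainwcn import compare as cp
from brainwcn.centrality import MEASURES


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------

def test_zscore_definition_and_degenerate_rules():
    control = np.array([1.0, 2.0, 3.0, 4.0])
    mean, sd = control.mean(), control.std()
    z, flag = cp.zscore(mean, control)
    assert z == 0.0 and flag == ""
    z, _ = cp.zscore(mean + 2 * sd, control)
    assert z == pytest.approx(2.0)
    z, flag = cp.zscore(5.0, np.full(10, 5.0))
    assert z == 0.0 and flag == "by_construction"
    z, flag = cp.zscore(7.0, np.full(10, 5.0))
    assert np.isinf(z) and z > 0 and flag == "sd_zero"


def test_zscore_and_pvalue_affine_invariance():
    rng = np.random.default_rng(0)
    control = rng.normal(10, 2, 500)
    case = 13.7
    z0, _ = cp.zscore(case, control)
    p0, _ = cp.empirical_pvalue(case, control)
    for a, b in [(2.5, -7.0), (0.3, 100.0)]:
        z1, _ = cp.zscore(a * case + b, a * control + b)
        p1, _ = cp.empirical_pvalue(a * case + b, a * control + b)
        assert z1 == pytest.approx(z0, rel=1e-9)
        assert p1 == p0


# ---------------------------------------------------------------------------
# Empirical p-values
# ---------------------------------------------------------------------------

def test_empirical_pvalue_counts_extremes_one_tailed():
    K = 50000
    rng = np.random.default_rng(1)
    control = rng.normal(size=K)
    # place the case so that exactly 3 controls are more extreme
    case = np.sort(control)[-4] + 1e-12
    p, flag = cp.empirical_pvalue(case, control, K)
    assert p == pytest.approx(3 / K)          # 6e-5, the printed-table ratio
    assert flag == ""
    # below the mean: counting flips to the left tail
    case_low = np.sort(control)[3] + 1e-12
    p_low, _ = cp.empirical_pvalue(case_low, control, K)
    assert p_low == pytest.approx(4 / K)


def test_empirical_pvalue_floor_is_one_over_K():
    K = 50000
    control = np.random.default_rng(2).normal(size=K)
    p, flag = cp.empirical_pvalue(control.max() + 1.0, control, K)
    assert p == pytest.approx(1 / K) and p == pytest.approx(2e-5)
    assert flag == "<1/K"


def test_empirical_pvalue_median_case_near_half():
    control = np.random.default_rng(3).normal(size=10001)
    p, _ = cp.empirical_pvalue(np.median(control), control)
    assert p == pytest.approx(0.5, abs=0.02)


def test_degenerate_control_equal_case_is_by_construction():
    p, flag = cp.empirical_pvalue(5.0, np.full(100, 5.0), 100)
    assert p == 1.0 and flag == "by_construction"


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def test_boxcox_recovers_lambda_zero_for_lognormal():
    rng = np.random.default_rng(4)
    sample = np.exp(rng.normal(size=10_000))
    bc, transformed = cp.boxcox_fit(sample)
    assert abs(bc.lmbda) < 0.1
    # transformed sample is approximately normal: modest skewness
    from scipy import stats
    assert abs(stats.skew(transformed)) < 0.1


def test_boxcox_recovers_lambda_one_for_shifted_normal():
    rng = np.random.default_rng(5)
    sample = rng.normal(50, 2, 10_000)
    bc, _ = cp.boxcox_fit(sample)
    z_raw, _ = cp.zscore(53.0, sample)
    z_bc, _ = cp._stable_boxcox_z(53.0, sample, bc.lmbda, bc.shift)
    # transform is smooth and monotone; the z direction is preserved
    assert np.sign(z_bc) == np.sign(z_raw)


def test_boxcox_shifts_nonpositive_input():
    sample = np.array([-2.0, -1.0, 0.5, 3.0, 8.0, 2.2, 1.1])
    bc, transformed = cp.boxcox_fit(sample)
    assert bc.shift > 2.0
    assert np.isfinite(transformed).all()
    # extra_min extends the shift so the case value stays transformable
    bc2, _ = cp.boxcox_fit(sample, extra_min=-5.0)
    assert bc2.shift > 5.0
    assert np.isfinite(bc2.transform(-5.0 + 1e-9))


def test_boxcox_constant_input_flagged_identity():
    bc, transformed = cp.boxcox_fit(np.full(20, 3.3))
    assert bc.flag == "identity"
    assert np.all(transformed == 3.3)


def test_stable_boxcox_z_handles_extreme_lambda():
    # data far from zero with small relative spread: ML lambda explodes and
    # the textbook transform collapses below double precision
    rng = np.random.default_rng(6)
    control = rng.normal(15.4, 0.02, 300)
    from scipy import stats
    _, lmbda = stats.boxcox(control)
    assert abs(lmbda) > 5
    z, flag = cp._stable_boxcox_z(15.35, control, lmbda, 0.0)
    assert flag == "" and np.isfinite(z) and z < -1


# ---------------------------------------------------------------------------
# Subsampling engine
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def engine_result(prepared):
    _, by_group, _ = prepared
    engine = cp.GroupComparison(n_repetitions=12, random_state=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = engine.fit(by_group["control"]).compare(by_group["case"])
    return engine, result


def test_subsample_profiles_deterministic_and_streamed(prepared):
    _, by_group, _ = prepared
    values = by_group["control"].node_values()
    runs = []
    for _ in range(2):
        profs = list(cp.subsample_profiles(values, n_subsample=30,
                                           n_repetitions=3, random_state=9))
        runs.append(np.stack([p.to_numpy() for p in profs]))
    np.testing.assert_array_equal(runs[0], runs[1])
    assert runs[0].shape == (3, values.shape[1], len(MEASURES))


def test_full_group_without_replacement_reproduces_single_network(prepared):
    _, by_group, _ = prepared
    values = by_group["control"].node_values()
    profs = list(cp.subsample_profiles(values, n_subsample=len(values),
                                       n_repetitions=3, replace=False,
                                       random_state=0))
    np.testing.assert_array_equal(profs[0].to_numpy(), profs[1].to_numpy())
    np.testing.assert_array_equal(profs[0].to_numpy(), profs[2].to_numpy())


def test_whole_network_degree_constant_at_fixed_density(engine_result):
    engine, result = engine_result
    degree = engine.control_whole_network_["degree"]
    assert degree.nunique() == 1
    n_nodes = len(engine.node_ids_)
    n_pairs = n_nodes * (n_nodes - 1) // 2
    m = n_pairs - 1 - int(np.floor(0.85 * (n_pairs - 1)))
    assert degree.iloc[0] == pytest.approx(2 * m / n_nodes)


def test_degree_z_and_p_flagged_by_construction(engine_result):
    _, result = engine_result
    row = result.whole_network.loc["degree"]
    assert row["z"] == 0.0 and row["z_flag"] == "by_construction"
    assert row["p"] == 1.0 and row["p_flag"] == "by_construction"


def test_comparison_is_deterministic_under_seed(prepared):
    _, by_group, _ = prepared
    results = []
    for _ in range(2):
        engine = cp.GroupComparison(n_repetitions=6, random_state=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results.append(engine.fit(by_group["control"])
                           .compare(by_group["case"]))
    pd.testing.assert_frame_equal(results[0].whole_network,
                                  results[1].whole_network, check_exact=True)
    pd.testing.assert_frame_equal(results[0].per_node, results[1].per_node,
                                  check_exact=True)


def test_single_node_stats_equal_per_node_loop(engine_result):
    engine, result = engine_result
    m_sub = result.conventions["n_subsample"]
    control_arr = engine._null_cache[m_sub][0]
    case_profile = engine.case_profile_
    long = result.per_node.set_index(["feature_id", "measure"])
    rng = np.random.default_rng(0)
    nodes = rng.choice(len(engine.node_ids_), size=5, replace=False)
    for i in nodes:
        node = engine.node_ids_[i]
        for m, measure in enumerate(MEASURES):
            vals = control_arr[:, i, m]
            vals = vals[~np.isnan(vals)]
            case_val = case_profile.iloc[i, m]
            if np.isnan(case_val) or len(vals) == 0:
                continue
            expected = cp._compare_one(case_val, vals, use_boxcox=True)
            row = long.loc[(node, measure)]
            assert row["z"] == pytest.approx(expected["z"], abs=1e-12)
            assert row["p"] == pytest.approx(expected["p"], abs=1e-15)


def test_case_equal_to_control_distribution_gives_zero_z():
    rng = np.random.default_rng(7)
    control = rng.normal(size=(40, 3, len(MEASURES))) + 5
    case = pd.DataFrame(control.mean(axis=0),
                        index=list("abc"), columns=list(MEASURES))
    # exact-mean case values: z == 0 for every node and measure
    long, excluded = cp.single_node_stats(control, case, use_boxcox=False)
    assert excluded.empty
    assert np.allclose(long["z"], 0.0, atol=1e-12)


def test_single_node_missing_fraction_exclusion():
    control = np.random.default_rng(8).normal(size=(10, 2, len(MEASURES)))
    control[:6, 0, 0] = np.nan      # 60% missing for node a, measure degree
    case = pd.DataFrame(np.zeros((2, len(MEASURES))),
                        index=list("ab"), columns=list(MEASURES))
    long, excluded = cp.single_node_stats(control, case, use_boxcox=False,
                                          max_missing_frac=0.5)
    assert len(excluded) == 1
    assert excluded.iloc[0]["feature_id"] == "a"
    assert not ((long.feature_id == "a") & (long.measure == "degree")).any()


def test_node_set_mismatch_raises():
    control = np.zeros((5, 3, len(MEASURES)))
    case = pd.DataFrame(np.zeros((2, len(MEASURES))), columns=list(MEASURES))
    with pytest.raises(ValueError, match="mismatch"):
        cp.single_node_stats(control, case)


# ---------------------------------------------------------------------------
# Ranking and cluster map
# ---------------------------------------------------------------------------

def test_rank_nodes_orders_by_absolute_z_with_sign_kept():
    per_node = pd.DataFrame({
        "feature_id": list("abcd"),
        "measure": ["strength"] * 4,
        "z": [1.0, -3.0, 2.0, -0.5],
        "p": [0.5, 0.01, 0.1, 0.8],
    })
    top = cp.rank_nodes(per_node, "strength", k=3)
    assert list(top.feature_id) == ["b", "c", "a"]
    assert top.loc[0, "z"] == -3.0
    assert list(top["rank"]) == [1, 2, 3]


def test_rank_nodes_tiebreak_and_truncation():
    per_node = pd.DataFrame({
        "feature_id": ["x", "m", "a"],
        "measure": ["ipr"] * 3,
        "z": [0.0, 0.0, 0.0],
        "p": [1.0] * 3,
    })
    top = cp.rank_nodes(per_node, "ipr", k=10)
    assert list(top.feature_id) == ["a", "m", "x"]    # alphabetical on ties
    assert len(top) == 3                               # truncated to available
    with pytest.raises(ValueError, match="not present"):
        cp.rank_nodes(per_node, "degree", k=1)


def test_rank_nodes_formats_with_metadata(engine_result, prepared):
    _, result = engine_result
    table, _, _ = prepared
    top = cp.rank_nodes(result, "clustering", k=5, metadata=table.metadata)
    assert list(top.columns) == ["rank", "feature_id", "hemisphere", "region",
                                 "feature_kind", "measure", "z"]
    assert len(top) == 5


def test_cluster_map_properties():
    rng = np.random.default_rng(9)
    base = rng.normal(size=(50, len(MEASURES)))
    profile = pd.DataFrame(base, columns=list(MEASURES))
    profile["strength"] = profile["degree"] * 2 + rng.normal(0, 1e-6, 50)
    cmap = cp.centrality_cluster_map(profile, n_clusters=4)
    corr = cmap.correlation
    assert np.allclose(corr.values, corr.values.T)
    assert np.allclose(np.diag(corr.values), 1.0)
    # a duplicated (monotone) column correlates 1 and shares its cluster
    assert corr.loc["degree", "strength"] == pytest.approx(1.0)
    assert cmap.labels["degree"] == cmap.labels["strength"]
    assert set(cmap.leaf_order) == set(MEASURES)


def test_cluster_map_on_comparison_profiles(engine_result):
    engine, _ = engine_result
    cmap = cp.centrality_cluster_map(engine.case_profile_)
    assert cmap.correlation.shape == (len(MEASURES), len(MEASURES))
    assert cmap.labels.nunique() <= 4


def test_result_export_writes_flagged_tables(tmp_path, engine_result):
    _, result = engine_result
    paths = result.write(tmp_path)
    wn = pd.read_csv(tmp_path / "whole_network.csv", index_col=0)
    assert "z" in wn.columns and len(wn) == len(MEASURES)
    pn = pd.read_csv(tmp_path / "per_node.csv")
    assert {"feature_id", "measure", "z", "p"} <= set(pn.columns)
    import json
    meta = json.loads((tmp_path / "comparison_metadata.json").read_text())
    assert meta["n_repetitions"] == 12
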