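"""Differential abundance: t-tests, z-scores, clustering, volcano tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet

from targetmet.stats import hierarchical_cluster, ttest_groups, volcano_table, zscore_rows


def _samples(groups):
    return pd.DataFrame(
        {"group": groups, "role": ["study"] * len(groups)},
        index=pd.Index([f"s{i}" for i in range(len(groups))], name="sample_id"),
    )


def test_student_t_matches_closed_form():
    """A=(10,11,12) vs B=(20,21,22): pooled-variance t = -12.247,
    p = 2.55e-4 (frozen from the closed-form pooled t with df=4)."""
    imputed = pd.DataFrame([[10, 11, 12, 20, 21, 22]], index=["m"], columns=[f"s{i}" for i in range(6)])
    res = ttest_groups(imputed, _samples(["A"] * 3 + ["B"] * 3), "A", "B")
    assert res.loc[0, "t"] == pytest.approx(-12.247449, abs=1e-6)
    assert res.loc[0, "p"] == pytest.approx(2.552167e-4, rel=1e-6)
    assert res.loc[0, "log2fc"] == pytest.approx(np.log2(21 / 11))
    assert bool(res.loc[0, "significant"])


def test_identical_groups_not_significant():
    imputed = pd.DataFrame([[5.0, 6.0, 7.0, 5.0, 6.0, 7.0]], index=["m"], columns=[f"s{i}" for i in range(6)])
    res = ttest_groups(imputed, _samples(["A"] * 3 + ["B"] * 3), "A", "B")
    assert res.loc[0, "log2fc"] == 0.0
    assert not bool(res.loc[0, "significant"])


def test_degenerate_zero_variance_convention():
    same = pd.DataFrame([[4.0, 4.0, 4.0, 4.0]], index=["m"], columns=[f"s{i}" for i in range(4)])
    res = ttest_groups(same, _samples(["A", "A", "B", "B"]), "A", "B")
    assert res.loc[0, "p"] == 1.0 and res.loc[0, "t"] == 0.0
    diff = pd.DataFrame([[4.0, 4.0, 8.0, 8.0]], index=["m"], columns=[f"s{i}" for i in range(4)])
    res = ttest_groups(diff, _samples(["A", "A", "B", "B"]), "A", "B")
    assert res.loc[0, "p"] == 0.0


def test_group_swap_negates_log2fc_preserves_p():
    rng = np.random.default_rng(8)
    imputed = pd.DataFrame(
        rng.lognormal(12, 0.3, (20, 8)), index=[f"m{i}" for i in range(20)], columns=[f"s{i}" for i in range(8)]
    )
    samples = _samples(["A"] * 4 + ["B"] * 4)
    ab = ttest_groups(imputed, samples, "A", "B")
    ba = ttest_groups(imputed, samples, "B", "A")
    np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"])
    np.testing.assert_allclose(ab["p"], ba["p"])


def test_small_groups_and_overlap_rejected():
    imputed = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"], columns=["s0", "s1", "s2"])
    with pytest.raises(ValueError, match=">= 2"):
        ttest_groups(imputed, _samples(["A", "A", "B"]), "A", "B")


def test_welch_variant_differs_under_unequal_variance():
    imputed = pd.DataFrame(
        [[10.0, 10.1, 9.9, 9.95, 20.0, 35.0, 5.0, 28.0]],
        index=["m"],
        columns=[f"s{i}" for i in range(8)],
    )
    samples = _samples(["A"] * 4 + ["B"] * 4)
    p_student = ttest_groups(imputed, samples, "A", "B", variant="student").loc[0, "p"]
    p_welch = ttest_groups(imputed, samples, "A", "B", variant="welch").loc[0, "p"]
    assert p_student != p_welch


def test_fc_bound_flag_follows_detection():
    imputed = pd.DataFrame(
        [[10.0, 12.0, 20.0, 22.0], [10.0, 12.0, 20.0, 22.0]],
        index=["all_detected", "partly_imputed"],
        columns=[f"s{i}" for i in range(4)],
    )
    detected = pd.DataFrame(
        [[True, True, True, True], [True, False, True, True]],
        index=imputed.index,
        columns=imputed.columns,
    )
    res = ttest_groups(imputed, _samples(["A", "A", "B", "B"]), "A", "B", detected=detected)
    assert list(res["fc_is_bound"]) == [False, True]


def test_q_values_are_bh_adjusted():
    rng = np.random.default_rng(3)
    imputed = pd.DataFrame(
        rng.lognormal(12, 0.3, (50, 12)), index=[f"m{i}" for i in range(50)], columns=[f"s{i}" for i in range(12)]
    )
    res = ttest_groups(imputed, _samples(["A"] * 6 + ["B"] * 6), "A", "B")
    assert (res["q"] >= res["p"] - 1e-12).all()
    assert res["q"].max() <= 1.0


def test_zscore_rows_sample_sd_and_constants():
    m = pd.DataFrame([[1.0, 2.0, 3.0], [7.0, 7.0, 7.0]], index=["r1", "r2"], columns=list("abc"))
    z = zscore_rows(m)
    np.testing.assert_allclose(z.loc["r1"], [-1.0, 0.0, 1.0])  # sample sd of (1,2,3) is 1
    np.testing.assert_array_equal(z.loc["r2"], [0.0, 0.0, 0.0])
    # re-scoring an already z-scored row is the identity
    np.testing.assert_allclose(zscore_rows(z).loc["r1"], z.loc["r1"])


def test_cluster_merges_identical_rows_first():
    m = pd.DataFrame(
        [[0.0, 1.0, 2.0], [0.0, 1.0, 2.0], [9.0, 1.0, -4.0]], index=["a", "b", "c"], columns=list("xyz")
    )
    result = hierarchical_cluster(m)
    assert result.row_linkage[0, 2] == 0.0  # first merge at distance zero
    first = {result.z.index[int(result.row_linkage[0, 0])], result.z.index[int(result.row_linkage[0, 1])]}
    assert first == {"a", "b"}


def test_cluster_toy_one_dimensional():
    """Points {0, 1, 10}: 0 and 1 merge before 10 joins."""
    m = pd.DataFrame([[0.0], [1.0], [10.0]], index=["p0", "p1", "p10"], columns=["x"])
    result = hierarchical_cluster(m)
    merged = {m.index[int(result.row_linkage[0, 0])], m.index[int(result.row_linkage[0, 1])]}
    assert merged == {"p0", "p1"}
    assert result.row_linkage[0, 2] == pytest.approx(1.0)
    assert result.row_linkage[1, 2] == pytest.approx(10.0)  # complete linkage to the far point


def test_cluster_topology_invariant_to_row_order():
    rng = np.random.default_rng(4)
    m = pd.DataFrame(rng.normal(size=(8, 5)), index=[f"m{i}" for i in range(8)], columns=list("abcde"))
    perm = m.sample(frac=1, random_state=1)
    r1 = hierarchical_cluster(m)
    r2 = hierarchical_cluster(perm)
    # cophenetic distances between named rows are a topology fingerprint
    d1 = cophenet(r1.row_linkage)
    d2 = cophenet(r2.row_linkage)
    sq1 = pd.DataFrame(_squareform(d1), index=m.index, columns=m.index)
    sq2 = pd.DataFrame(_squareform(d2), index=perm.index, columns=perm.index)
    np.testing.assert_allclose(sq1.to_numpy(), sq2.loc[m.index, m.index].to_numpy())


def _squareform(condensed):
    from scipy.spatial.distance import squareform

    return squareform(condensed)


def test_cluster_rejects_nan_and_single_row():
    bad = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]], index=["a", "b"], columns=["x", "y"])
    with pytest.raises(ValueError, match="NaN"):
        hierarchical_cluster(bad)
    with pytest.raises(ValueError, match=">= 2"):
        hierarchical_cluster(pd.DataFrame([[1.0, 2.0]], index=["a"], columns=["x", "y"]))


def test_volcano_boundary_and_shape():
    comparisons = pd.DataFrame(
        {
            "metabolite": ["at_alpha", "null", "strong"],
            "log2fc": [1.0, 0.0, -2.0],
            "p": [0.05, 1.0, 1e-6],
            "significant": [False, False, True],  # p = 0.05 is NOT significant (strict <)
        }
    )
    v = volcano_table(comparisons)
    assert len(v) == 3
    assert not bool(v.loc[0, "significant"])
    assert v.loc[1, "neg_log10_p"] == 0.0
    assert v.loc[2, "neg_log10_p"] == pytest.approx(6.0)


def test_significance_is_strictly_below_alpha():
    imputed = pd.DataFrame(
        [[10, 11, 12, 20, 21, 22]], index=["m"], columns=[f"s{i}" for i in range(6)], dtype=float
    )
    samples = _samples(["A"] * 3 + ["B"] * 3)
    res = ttest_groups(imputed, samples, "A", "B", alpha=2.552167e-4)
    assert not bool(res.loc[0, "significant"])  # p == alpha fails a strict <
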