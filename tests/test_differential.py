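"""Differential analysis: exact NB test, BH adjustment, fold changes,
Welch tests and hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micnet import (ValidationError, bh_adjust, fold_change_ddct, hcluster,
                    nb_test, welch_test_dct)


def _frame(rows, n_a, n_b):
    df = pd.DataFrame(rows)
    df.index = [f"f{i}" for i in range(len(df))]
    df.columns = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    groups = pd.Series(["a"] * n_a + ["b"] * n_b, index=df.columns)
    return df, groups


def test_nb_identical_counts_p_one():
    """With identical counts everywhere the observed split is modal, so the
    two-sided tail sum covers the whole distribution."""
    df, groups = _frame([[7, 7, 7, 7, 7, 7]], 3, 3)
    res = nb_test(df, groups)
    assert res["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-9)


def test_nb_strong_shift_small_p():
    df, groups = _frame([[50, 55, 45, 48, 400, 410, 390, 420]], 4, 4)
    assert nb_test(df, groups)["p_value"].iloc[0] < 1e-4


def test_nb_requires_two_levels_and_replicates():
    df, groups = _frame([[1, 2, 3, 4]], 2, 2)
    with pytest.raises(ValidationError):
        nb_test(df, pd.Series(["a", "a", "a", "a"], index=df.columns))
    with pytest.raises(ValidationError):
        nb_test(df, pd.Series(["a", "b", "b", "b"], index=df.columns))


def test_nb_non_integer_rejected_unless_rounded():
    df, groups = _frame([[1.5, 2.5, 3.5, 4.5]], 2, 2)
    with pytest.raises(ValidationError):
        nb_test(df, groups, round_counts=False)
    assert 0 < nb_test(df, groups)["p_value"].iloc[0] <= 1


def test_bh_hand_case():
    """Step-up on [.01, .02, .03, .04] collapses to .04 everywhere."""
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_single_and_saturated():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)
    assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
@settings(max_examples=100, derandomize=True)
def test_bh_monotone_and_dominates_p(ps):
    q = bh_adjust(ps)
    order = np.argsort(ps)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q >= np.asarray(ps) - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()


def _dct(rows, samples):
    df = pd.DataFrame(rows, columns=samples)
    df.index = [f"g{i}" for i in range(len(df))]
    return df


@pytest.mark.parametrize("ddct, fold, flagged", [
    (0.0, 1.0, False),
    (-1.0, 2.0, False),
    (-1.585, 3.0, True),   # just past the log2 > 1.58 boundary
    (1.585, 1 / 3.0, True),
    (-1.57, 2.97, False),  # just below the boundary
])
def test_fold_change_threshold(ddct, fold, flagged):
    dct = _dct([[ddct, ddct, 0.0, 0.0]], ["a1", "a2", "b1", "b2"])
    [res] = fold_change_ddct(dct, ["a1", "a2"], ["b1", "b2"])
    assert res.delta_delta_ct == pytest.approx(ddct)
    assert res.fold_change == pytest.approx(fold, rel=1e-2)
    assert res.passes_3fold is flagged


def test_fold_change_antisymmetry():
    rng = np.random.default_rng(2)
    dct = _dct(rng.normal(0, 2, size=(5, 6)), [f"s{i}" for i in range(6)])
    a, b = [f"s{i}" for i in range(3)], [f"s{i}" for i in range(3, 6)]
    fwd = fold_change_ddct(dct, a, b)
    rev = fold_change_ddct(dct, b, a)
    for f, r in zip(fwd, rev):
        assert f.fold_change * r.fold_change == pytest.approx(1.0)


def test_fold_change_missing_group_flagged():
    dct = _dct([[np.nan, np.nan, 1.0, 2.0]], ["a1", "a2", "b1", "b2"])
    [res] = fold_change_ddct(dct, ["a1", "a2"], ["b1", "b2"])
    assert res.missing


def test_fold_change_overlapping_groups_rejected():
    dct = _dct([[1.0, 2.0, 3.0]], ["s1", "s2", "s3"])
    with pytest.raises(ValidationError):
        fold_change_ddct(dct, ["s1", "s2"], ["s2", "s3"])


def test_welch_identical_groups_p_one():
    dct = _dct([[1.0, 1.0, 1.0, 1.0]], ["a1", "a2", "b1", "b2"])
    assert welch_test_dct(dct, ["a1", "a2"], ["b1", "b2"]).iloc[0] == 1.0


def test_welch_calibration_and_power():
    rng = np.random.default_rng(5)
    n_sims = 400
    null = rng.normal(0, 1, size=(n_sims, 17))
    df = pd.DataFrame(null, columns=[f"s{i}" for i in range(17)])
    a, b = [f"s{i}" for i in range(8)], [f"s{i}" for i in range(8, 17)]
    p = welch_test_dct(df, a, b)
    assert 0.02 <= (p < 0.05).mean() <= 0.08
    shifted = null.copy()
    shifted[:, 8:] += 3.0
    p = welch_test_dct(pd.DataFrame(shifted, columns=df.columns), a, b)
    assert (p < 0.05).mean() >= 0.95


def test_hcluster_identical_pair_merges_first():
    m = _dct([[0.0, 0.0, 5.0], [1.0, 1.0, 9.0]], ["x", "y", "z"])
    dend = hcluster(m)
    assert dend.heights[0] == pytest.approx(0.0)
    assert set(dend.leaf_order) == {"x", "y", "z"}


def test_hcluster_line_example():
    """1-D city-block points at 0, 1, 10, 11: pairs merge at height 1, the
    final average-linkage merge sits at 10."""
    m = _dct([[0.0, 1.0, 10.0, 11.0]], ["a", "b", "c", "d"])
    dend = hcluster(m)
    assert np.allclose(sorted(dend.heights[:2]), [1.0, 1.0])
    assert dend.heights[2] == pytest.approx(10.0)


def test_hcluster_heights_nondecreasing(reduced_cohort):
    from micnet import normalize_delta_ct
    dct = normalize_delta_ct(reduced_cohort.stemcell)
    dend = hcluster(dct.values)
    assert (np.diff(dend.heights) >= -1e-9).all()
    newick = dend.to_newick()
    assert newick.endswith(";") and newick.count(",") == len(dend.labels) - 1


def test_hcluster_column_permutation_invariant():
    rng = np.random.default_rng(3)
    m = _dct(rng.normal(size=(6, 5)), [f"s{i}" for i in range(5)])
    d1 = hcluster(m)
    perm = ["s3", "s0", "s4", "s2", "s1"]
    d2 = hcluster(m[perm])
    assert np.allclose(np.sort(d1.heights), np.sort(d2.heights))


def test_hcluster_missing_handling():
    m = _dct([[0.0, 0.1, np.nan], [1.0, 1.1, np.nan], [2.0, 2.2, np.nan]],
             ["x", "y", "z"])
    with pytest.raises(ValidationError):
        hcluster(m[["x"]])
    dend = hcluster(m)  # z is all-missing -> excluded
    assert dend.labels == ["x", "y"]
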