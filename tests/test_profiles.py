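"""Per-group profiles, z-scores, grouping, and rank-based contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import hippocoupling as hc
from hippocoupling._stats import rank_sum_p, signed_rank_p

from conftest import toy_annotation, toy_counts


def _norm_from_dense(dense):
    return hc.log_normalize(toy_counts(np.asarray(dense)))


# ---------------------------------------------------------------------------
# enumeration oracles, independent of the scipy-backed implementation

def oracle_signed_rank(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s)
         for signs in itertools.product([0, 1], repeat=d.size)]
    )
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


def oracle_rank_sum(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ranks = rankdata(np.concatenate([a, b]))
    r_obs = ranks[: len(a)].sum()
    rs = np.array([sum(c) for c in itertools.combinations(ranks, len(a))])
    return min(1.0, 2 * min((rs <= r_obs).mean(), (rs >= r_obs).mean()))


# ---------------------------------------------------------------------------
# aggregate / zscore / split_by

def test_aggregate_arithmetic():
    # one gene, one group of 4 cells with normalized values (0, 0, 2, 4):
    # choose raw counts whose normalized values are controlled via equal totals
    dense = np.array([[0, 0, 2, 4], [6, 6, 4, 2]])  # equal per-cell totals
    norm = _norm_from_dense(dense)
    ann = toy_annotation(["A"] * 4)
    with pytest.raises(ValueError):
        hc.zscore(hc.aggregate(norm, ann))  # single group: no z-score
    prof = hc.aggregate(norm, ann)
    v = np.asarray(norm.values.todense())
    assert prof.x.loc["g0", "A"] == pytest.approx(v[0].mean())
    assert prof.pct_pos.loc["g0", "A"] == pytest.approx(50.0)
    assert prof.pct_pos.loc["g1", "A"] == pytest.approx(100.0)
    assert int(prof.n_cells["A"]) == 4


def test_aggregate_constant_and_absent_genes():
    dense = np.array([[3, 3, 3, 3], [0, 0, 0, 0]])
    norm = _norm_from_dense(dense)
    prof = hc.aggregate(norm, toy_annotation(["A", "A", "B", "B"]))
    v = np.asarray(norm.values.todense())
    np.testing.assert_allclose(prof.x.loc["g0"], v[0, 0], atol=1e-12)
    assert prof.pct_pos.loc["g0"].eq(100).all()
    assert prof.x.loc["g1"].eq(0).all() and prof.pct_pos.loc["g1"].eq(0).all()


def test_aggregate_commutes_with_cell_permutation(small_norm):
    norm, ann = small_norm
    rng = np.random.default_rng(0)
    perm = rng.permutation(norm.shape[1])
    shuffled = hc.NormalizedMatrix(
        norm.values[:, perm], norm.gene_ids, norm.cell_ids[perm], norm.scale_factor
    )
    p1 = hc.aggregate(norm, ann)
    p2 = hc.aggregate(shuffled, ann)
    pd.testing.assert_frame_equal(p1.x, p2.x)
    pd.testing.assert_frame_equal(p1.pct_pos, p2.pct_pos)


def test_canonical_group_order(small_profile):
    assert hc.profiles.canonical_group_order(["CA2", "Astro", "DG"]) == ["Astro", "DG", "CA2"]
    assert hc.profiles.canonical_group_order(["b", "a", "zz"]) == ["a", "b", "zz"]


def test_zscore_rows():
    x = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["a", "b"],
                     columns=["t1", "t2", "t3"])
    prof = hc.TypeProfile(x=x, pct_pos=x * 0, n_cells=pd.Series({"t1": 1, "t2": 1, "t3": 1}))
    z = hc.zscore(prof).z
    np.testing.assert_allclose(z.loc["a"], [-1.0, 0.0, 1.0], atol=1e-12)
    np.testing.assert_allclose(z.loc["b"], 0.0, atol=1e-12)
    assert abs(z.loc["a"].mean()) < 1e-12


def test_split_by_crossed_labels():
    ann = toy_annotation(["A", "A", "B", "B"], sexes=["F", "M", "F", "F"])
    lab = hc.split_by(ann, keys=("group", "sex"))
    assert set(lab) == {"A|F", "A|M", "B|F"}  # B|M absent naturally
    single = hc.split_by(ann, keys=("group",))
    assert set(single) == {"A", "B"}


# ---------------------------------------------------------------------------
# contrasts

def test_paired_contrast_identical_genes(small_profile):
    prof = small_profile
    x = prof.x.copy()
    x.loc["gB"] = x.iloc[0]
    x = x.rename(index={x.index[0]: "gA"})
    p2 = hc.TypeProfile(x=x, pct_pos=prof.pct_pos, n_cells=prof.n_cells)
    res = hc.paired_gene_contrast(p2, "gA", "gB")
    assert res.p == 1.0 and res.log2fc == 0.0


def test_paired_contrast_all_positive_13_groups():
    """13 cell types with one gene above the other everywhere: the exact
    two-sided signed-rank p is 2 / 2^13."""
    groups = [f"t{i}" for i in range(13)]
    xa = np.linspace(1.0, 2.5, 13) + np.linspace(0.3, 0.9, 13)
    xb = np.linspace(1.0, 2.5, 13)
    x = pd.DataFrame([xa, xb], index=["gA", "gB"], columns=groups)
    prof = hc.TypeProfile(x=x, pct_pos=x * 0, n_cells=pd.Series(1, index=groups))
    res = hc.paired_gene_contrast(prof, "gA", "gB")
    assert res.p == pytest.approx(2 / 2**13, abs=1e-15)
    assert res.log2fc > 0


def test_paired_contrast_three_groups_enumeration():
    groups = ["t0", "t1", "t2"]
    xa = np.array([2.0, 3.0, 1.0])
    xb = np.array([1.0, 1.0, 4.0])  # differences (+1, +2, -3)
    x = pd.DataFrame([xa, xb], index=["gA", "gB"], columns=groups)
    prof = hc.TypeProfile(x=x, pct_pos=x * 0, n_cells=pd.Series(1, index=groups))
    res = hc.paired_gene_contrast(prof, "gA", "gB")
    assert res.p == pytest.approx(oracle_signed_rank(xa, xb), abs=1e-15)


def test_within_group_contrast_small_exact():
    """gene_a=(1,2) vs gene_b=(3,4) in one group: exact two-sided p = 1/3."""
    # raw counts arranged so the two cells' normalized values keep order
    dense = np.array([[1, 2], [3, 4]])
    norm = _norm_from_dense(dense)
    ann = toy_annotation(["A", "A"])
    res = hc.gene_within_group_contrast(norm, ann, "g0", "g1", "A")
    assert res.p == pytest.approx(1 / 3, abs=1e-15)
    assert res.log2fc < 0


def test_within_group_contrast_identical_and_errors(small_norm):
    dense = np.array([[1, 2, 3], [1, 2, 3]])
    norm = _norm_from_dense(dense)
    ann = toy_annotation(["A", "A", "A"])
    res = hc.gene_within_group_contrast(norm, ann, "g0", "g1", "A")
    assert res.p == 1.0 and res.log2fc == 0.0
    with pytest.raises(ValueError):
        hc.gene_within_group_contrast(norm, ann, "g0", "g1", "missing")


def test_rank_invariance_under_scaling():
    rng = np.random.default_rng(4)
    a = rng.normal(2, 1, size=6)
    b = rng.normal(2.5, 1, size=6)
    assert rank_sum_p(a, b) == pytest.approx(rank_sum_p(2 * a, 2 * b), abs=1e-15)


@pytest.mark.parametrize("test_fn,oracle", [
    (signed_rank_p, oracle_signed_rank),
    (rank_sum_p, oracle_rank_sum),
])
def test_rank_tests_match_enumeration(test_fn, oracle):
    """Implementation agrees with exhaustive enumeration at n <= 8 on 200
    random tie-free instances (both signed-rank and rank-sum)."""
    rng = np.random.default_rng(123)
    for _ in range(200):
        n = int(rng.integers(2, 9))
        m = int(rng.integers(2, 9))
        if test_fn is signed_rank_p:
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert test_fn(x, y) == pytest.approx(oracle(x, y), abs=1e-12)
        else:
            a, b = rng.normal(size=n), rng.normal(size=m)
            assert test_fn(a, b) == pytest.approx(oracle(a, b), abs=1e-12)


def test_fold_change_conventions():
    from hippocoupling._stats import fold_change_log2
    a = np.array([np.log(2.0)])  # expm1 -> 1
    b = np.array([np.log(4.0)])  # expm1 -> 3
    assert fold_change_log2(a, b, "expm1") == pytest.approx(np.log2(2 / 4))
    assert fold_change_log2(a, b, "logmeans") == pytest.approx(np.log2(2 / 4))
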