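"""Pairwise effect sizes: worked examples, invariances, oracle agreement."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenonet.cohort import CohortTable, VariableSpec
from phenonet.effects import (
    STATUS_DEGENERATE,
    STATUS_INSUFFICIENT_N,
    STATUS_OK,
    bonferroni_threshold,
    complete_pair,
    compute_all_pairs,
    cramers_effect,
    cramers_effect_from_table,
    kw_dunn_effect,
    min_sample_size_correlation,
    spearman_effect,
)

from _oracles import cramers_brute, kw_dunn_brute, spearman_brute


# ------------------------------------------------------------ deletion

def test_complete_pair_identity_without_missing():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([4.0, 5.0, 6.0])
    cx, cy = complete_pair(x, y)
    assert (cx == x).all() and (cy == y).all()

def test_complete_pair_all_missing_gives_empty():
    x = np.array([np.nan, np.nan])
    y = np.array([1.0, 2.0])
    cx, cy = complete_pair(x, y)
    assert len(cx) == len(cy) == 0

def test_complete_pair_union_of_missing_rows_dropped():
    # x missing at rows 2 and 5, y at row 3 (1-based): rows 1, 4, 6 survive
    x = np.array([10.0, np.nan, 30.0, 40.0, np.nan, 60.0])
    y = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
    cx, cy = complete_pair(x, y)
    assert list(cx) == [10.0, 40.0, 60.0]
    assert list(cy) == [1.0, 4.0, 6.0]

def test_complete_pair_categorical_columns():
    x = np.array(["a", np.nan, "b", "a"], dtype=object)
    y = np.array(["u", "v", np.nan, "w"], dtype=object)
    cx, cy = complete_pair(x, y)
    assert list(cx) == ["a", "a"] and list(cy) == ["u", "w"]


# ------------------------------------------------------------ Spearman

def test_spearman_perfect_monotone_both_directions():
    x = np.arange(10.0)
    up = np.exp(x)
    down = -(x**3)
    for y in (up, down):
        r2, p, n = spearman_effect(x, y)
        assert r2 == 1.0 and p == 0.0 and n == 10

def test_spearman_worked_example():
    # d = (−1, 1, −1, 1, 0): r = 1 − 6·4/(5·24) = 0.8, r² = 0.64
    r2, p, n = spearman_effect([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert r2 == pytest.approx(0.64, abs=1e-12)

def test_spearman_symmetry_and_monotone_invariance(rng):
    x = rng.normal(size=40)
    y = rng.normal(size=40)
    r2_xy, p_xy, _ = spearman_effect(x, y)
    r2_yx, p_yx, _ = spearman_effect(y, x)
    assert r2_xy == pytest.approx(r2_yx, abs=1e-14)
    assert p_xy == pytest.approx(p_yx, abs=1e-14)
    r2_t, _, _ = spearman_effect(np.exp(x), y**3)
    assert r2_t == pytest.approx(r2_xy, abs=1e-12)

def test_spearman_rejects_constant_input():
    with pytest.raises(ValueError):
        spearman_effect([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


# -------------------------------------------------------------- Cramér

def test_cramers_perfect_two_level_association_is_one():
    x = ["a", "a", "b", "b", "a", "b"]
    effect, p, n = cramers_effect(x, x)
    assert effect == pytest.approx(1.0, abs=1e-12)
    assert n == 6

def test_cramers_independence_is_zero():
    # exactly proportional 2×2 table: chi2 = 0
    table = np.array([[10, 20], [5, 10]])
    effect, p, _ = cramers_effect_from_table(table)
    assert effect == 0.0
    assert p == pytest.approx(1.0)

def test_cramers_worked_2x2_table():
    table = np.array([[20, 10], [10, 20]])
    chi2_by_hand = 60 * (20 * 20 - 10 * 10) ** 2 / 30**4
    effect, p, n = cramers_effect_from_table(table)
    assert n == 60
    phi2 = chi2_by_hand / 60
    expected = max(0.0, phi2 - 1 / 59) / min(2 - 1 / 59 - 1, 2 - 1 / 59 - 1)
    assert effect == pytest.approx(expected, abs=1e-12)

def test_cramers_relabeling_and_transpose_invariance(rng):
    x = rng.choice(["a", "b", "c"], size=120)
    y = rng.choice(["u", "v"], size=120)
    e1, p1, _ = cramers_effect(x, y)
    e2, p2, _ = cramers_effect(y, x)
    relabel = {"a": "z9", "b": "z1", "c": "z5"}
    e3, p3, _ = cramers_effect([relabel[v] for v in x], y)
    assert e1 == pytest.approx(e2, abs=1e-14) == pytest.approx(e3, abs=1e-14)
    assert p1 == pytest.approx(p2, abs=1e-14)

def test_cramers_single_level_rejected():
    with pytest.raises(ValueError):
        cramers_effect(["a"] * 10, ["u", "v"] * 5)


# ------------------------------------------------------------- KW/Dunn

def test_kw_dunn_rank_symmetric_groups_give_zero_effect():
    # groups with mirror-image ranks: identical mean ranks, Z_max = 0
    x = [1, 4, 2, 3]
    g = ["a", "a", "b", "b"]
    effect, p, n, h = kw_dunn_effect(x, g)
    assert effect == 0.0

def test_kw_dunn_worked_two_group_example():
    x = [1, 2, 3, 10, 11, 12]
    g = ["g1"] * 3 + ["g2"] * 3
    z = 3 / math.sqrt((6 * 7 / 12) * (2 / 3))
    effect, p, n, h = kw_dunn_effect(x, g)
    assert effect == pytest.approx(z**2 / 6, abs=1e-12)
    assert n == 6

def test_kw_dunn_three_groups_with_ties_matches_oracle():
    x = [1, 2, 2, 3, 3, 3, 4, 1, 2, 5, 5, 4]
    g = ["a", "a", "a", "a", "b", "b", "b", "b", "c", "c", "c", "c"]
    effect, p, _, _ = kw_dunn_effect(x, g)
    eo, po = kw_dunn_brute(x, g)
    assert effect == pytest.approx(eo, abs=1e-10)
    assert p == pytest.approx(po, abs=1e-10)

def test_kw_dunn_monotone_transform_and_relabel_invariance(rng):
    x = rng.normal(size=60)
    g = rng.choice(["a", "b", "c"], size=60)
    e1, p1, _, _ = kw_dunn_effect(x, g)
    e2, p2, _, _ = kw_dunn_effect(np.exp(x), g)
    relabel = {"a": "Z", "b": "A", "c": "M"}
    e3, p3, _, _ = kw_dunn_effect(x, [relabel[v] for v in g])
    assert e1 == pytest.approx(e2, abs=1e-12) == pytest.approx(e3, abs=1e-12)

def test_kw_dunn_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        kw_dunn_effect([1.0, 1.0, 1.0, 1.0], ["a", "a", "b", "b"])
    with pytest.raises(ValueError):
        kw_dunn_effect([1.0, 2.0, 3.0], ["a", "a", "a"])


# -------------------------------------------- oracle agreement (random)

@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.data())
def test_effects_match_brute_force_oracles(data):
    """All three effect sizes agree with first-principles implementations
    on short random vectors (including ties) to 1e-10."""
    n = data.draw(st.integers(min_value=5, max_value=12))
    which = data.draw(st.sampled_from(["spearman", "cramers", "kw"]))
    ints = st.integers(min_value=0, max_value=4)
    if which == "spearman":
        x = data.draw(st.lists(ints, min_size=n, max_size=n))
        y = data.draw(st.lists(ints, min_size=n, max_size=n))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        r2, p, _ = spearman_effect(x, y)
        r2o, po = spearman_brute(x, y)
        assert r2 == pytest.approx(r2o, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)
    elif which == "cramers":
        x = data.draw(st.lists(st.sampled_from("ab"), min_size=n, max_size=n))
        y = data.draw(st.lists(st.sampled_from("uvw"), min_size=n, max_size=n))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        e, p, _ = cramers_effect(x, y)
        eo, po = cramers_brute(x, y)
        assert e == pytest.approx(eo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)
    else:
        x = data.draw(st.lists(ints, min_size=n, max_size=n))
        g = data.draw(st.lists(st.sampled_from("ab"), min_size=n, max_size=n))
        if len(set(x)) < 2 or len(set(g)) < 2:
            return
        e, p, _, _ = kw_dunn_effect(x, g)
        eo, po = kw_dunn_brute(x, g)
        assert e == pytest.approx(eo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_effect_sizes_bounded_in_unit_interval(data):
    n = data.draw(st.integers(min_value=6, max_value=20))
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    x = rng.normal(size=n)
    y = rng.integers(0, 3, size=n).astype(float)
    g = np.array(list("ab"))[rng.integers(0, 2, size=n)]
    if len(set(y)) >= 2:
        r2, _, _ = spearman_effect(x, y)
        assert 0.0 <= r2 <= 1.0
    if len(set(g)) >= 2:
        e, _, _, _ = kw_dunn_effect(x, g)
        assert 0.0 <= e <= 1.0
    cat = np.array(list("uv"))[rng.integers(0, 2, size=n)]
    if len(set(g)) >= 2 and len(set(cat)) >= 2:
        e, _, _ = cramers_effect(cat, g)
        assert 0.0 <= e <= 1.0


# ------------------------------------------------------- dispatch layer

def _tiny_table():
    data = pd.DataFrame(
        {
            "num1": np.r_[np.arange(20.0)],
            "num2": np.r_[np.arange(20.0) ** 2],
            "cat1": ["a", "b"] * 10,
        }
    )
    variables = [
        VariableSpec("num1", "numerical"),
        VariableSpec("num2", "numerical"),
        VariableSpec("cat1", "categorical"),
    ]
    return CohortTable(data=data, variables=variables)

def test_compute_all_pairs_counts_and_kinds():
    results = compute_all_pairs(_tiny_table(), min_n=5)
    assert len(results) == 3
    kinds = {(r.var_a, r.var_b): r.pair_kind for r in results}
    assert kinds[("num1", "num2")] == "num-num"
    assert kinds[("cat1", "num1")] == "num-cat"
    assert all(r.status == STATUS_OK for r in results)

def test_compute_all_pairs_insufficient_n_flag():
    results = compute_all_pairs(_tiny_table(), min_n=790)
    assert all(r.status == STATUS_INSUFFICIENT_N for r in results)
    assert all(r.effect_size is None and r.p_value is None for r in results)

def test_compute_all_pairs_degenerate_after_deletion():
    data = pd.DataFrame(
        {
            "num1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "cat1": ["a", "a", "a", "a", "a", "b"],
        }
    )
    data.loc[5, "num1"] = np.nan  # removing the row makes cat1 constant
    table = CohortTable(
        data=data,
        variables=[VariableSpec("num1", "numerical"), VariableSpec("cat1", "categorical")],
    )
    (res,) = compute_all_pairs(table, min_n=3)
    assert res.status == STATUS_DEGENERATE
    assert res.n_complete == 5

def test_pairs_canonically_ordered():
    results = compute_all_pairs(_tiny_table(), min_n=5)
    assert all(r.var_a < r.var_b for r in results)


# ------------------------------------------------- thresholds / power

def test_bonferroni_matches_published_pair_count():
    assert 1581 * 1580 // 2 == 1248990
    alpha_eff = bonferroni_threshold(0.05, 1581)
    assert alpha_eff == pytest.approx(0.05 / 1248990)
    assert alpha_eff == pytest.approx(4.01e-8, rel=2e-3)

def test_bonferroni_edge_cases():
    assert bonferroni_threshold(0.05, 2) == 0.05
    assert bonferroni_threshold(0.05, 100) == pytest.approx(0.05 / 4950)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 1)

def test_min_sample_size_closed_form():
    from scipy import stats as ss

    z_a = ss.norm.ppf(0.975)
    z_p = ss.norm.ppf(0.8)
    expected = math.ceil(((z_a + z_p) / math.atanh(0.5)) ** 2 + 3)
    assert min_sample_size_correlation(0.5, power=0.8, alpha=0.05) == expected
    # the small-effect case lands near (not exactly on) the conventional 790
    n_small = min_sample_size_correlation(0.1, power=0.8, alpha=0.05)
    assert n_small == math.ceil(((z_a + z_p) / math.atanh(0.1)) ** 2 + 3)
    assert 770 <= n_small <= 800

def test_min_sample_size_monotone_in_power():
    ns = [min_sample_size_correlation(0.1, power=p) for p in (0.5, 0.7, 0.8, 0.9, 0.95)]
    assert ns == sorted(ns)
    with pytest.raises(ValueError):
        min_sample_size_correlation(0.0)
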