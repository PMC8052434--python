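"""Statistical machinery against independent oracles.

Oracles here are deliberately separate implementations: an O(n^2) direct
step-up formula (and statsmodels) for BH, exhaustive relabeling enumeration
for the rank tests, and exact combinatorial tail sums for the hypergeometric
test.
"""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from omiclink.errors import ValidationError
from omiclink.stats import (
    PhenotypeDescriptor,
    bh_adjust,
    classify_phenotype,
    de_test,
    enrich,
    enrichment_test,
    filter_by_significance,
    kruskal_p,
    mannwhitney_p,
)
from omiclink import synthetic

from .conftest import make_layer

# ---------------------------------------------------------------------------
# oracles


def bh_oracle(p):
    """Direct O(n^2) step-up: q_i = min over j with rank>=rank(i) of m*p_(j)/j."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order):
        q[i] = min(min(m * p[order[j]] / (j + 1) for j in range(pos, m)), 1.0)
    return q


def mwu_enumeration_p(x, y):
    """Two-sided exact MWU p by enumerating all C(n1+n2, n1) labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b)

    u_obs = u_of(tuple(range(n1)))
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    total = len(us)
    le = sum(1 for u in us if u <= u_obs + 1e-9) / total
    ge = sum(1 for u in us if u >= u_obs - 1e-9) / total
    return min(1.0, 2.0 * min(le, ge))


def kw_enumeration_p(groups):
    """Exact Kruskal-Wallis p by enumerating all relabelings, scipy H per split."""
    pooled = list(np.concatenate(groups))
    sizes = [len(g) for g in groups]
    h_obs = sps.kruskal(*groups).statistic
    count = total = 0
    idx_all = list(range(len(pooled)))

    def splits(remaining, szs):
        if len(szs) == 1:
            yield (tuple(remaining),)
            return
        for combo in itertools.combinations(remaining, szs[0]):
            rest = [r for r in remaining if r not in set(combo)]
            for tail in splits(rest, szs[1:]):
                yield (combo,) + tail

    for split in splits(idx_all, sizes):
        gs = [[pooled[i] for i in part] for part in split]
        h = sps.kruskal(*gs).statistic
        total += 1
        if h >= h_obs - 1e-9:
            count += 1
    return count / total


def hypergeom_tail_oracle(k, N, K, n):
    """Exact upper tail P(X >= k) via rational combinatorics."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# phenotype typing


class TestClassifyPhenotype:
    def test_two_labels_binary(self):
        d = classify_phenotype(["IR"] * 8 + ["IS"] * 9, "status")
        assert d.kind == "binary" and d.levels == ["IR", "IS"]

    def test_five_subtypes_categorical(self):
        labels = ["differentiated", "immunoreactive", "proliferative",
                  "mesenchymal", "stromal"] * 13
        d = classify_phenotype(labels[:67], "subtype")
        assert d.kind == "categorical" and len(d.levels) == 5

    def test_high_cardinality_numeric_continuous(self):
        rng = np.random.default_rng(0)
        d = classify_phenotype(rng.uniform(20, 80, size=30), "age")
        assert d.kind == "continuous"

    def test_few_distinct_numeric_values_categorical(self):
        d = classify_phenotype([0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2] * 3, "dose")
        assert d.kind == "categorical"

    def test_constant_phenotype_rejected(self):
        with pytest.raises(ValidationError, match="identical"):
            classify_phenotype(["a"] * 5, "flat")

    def test_override_kind(self):
        d = classify_phenotype([0, 1, 2, 0, 1, 2], "enc", kind="continuous")
        assert d.kind == "continuous"

    def test_binary_level_count_enforced(self):
        with pytest.raises(ValidationError):
            PhenotypeDescriptor("x", "binary", levels=["a"], values=np.array(["a"]))


# ---------------------------------------------------------------------------
# differential expression


def layer_from_groups(x, y):
    vals = np.array([list(x) + list(y)], dtype=float)
    return make_layer(vals, ["f0"]), classify_phenotype(
        ["A"] * len(x) + ["B"] * len(y), "g")


class TestDeTest:
    def test_null_feature_p_near_one(self):
        layer, ph = layer_from_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        (res,) = de_test(layer, ph, "parametric")
        assert res.p_value > 0.99

    def test_mwu_exact_small_sample_value(self):
        # complete separation of {1,2,3} and {4,5,6}: two-sided exact p = 0.1
        layer, ph = layer_from_groups([1, 2, 3], [4, 5, 6])
        (res,) = de_test(layer, ph, "nonparametric")
        assert res.test_name == "mann-whitney-u"
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.p_value == pytest.approx(mwu_enumeration_p([1, 2, 3], [4, 5, 6]), abs=1e-12)

    @pytest.mark.parametrize("sizes", [(3, 3), (4, 5), (6, 6), (2, 6)])
    def test_mwu_matches_enumeration(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        for rep in range(5):
            x = rng.standard_normal(sizes[0])
            y = rng.standard_normal(sizes[1]) + 0.5
            _, p = mannwhitney_p(x, y)
            assert p == pytest.approx(mwu_enumeration_p(x, y), abs=1e-10)

    @pytest.mark.parametrize("sizes", [(3, 3, 3), (2, 3, 4), (4, 4), (5, 5)])
    def test_kruskal_matches_enumeration(self, sizes):
        rng = np.random.default_rng(sum(sizes) + 17)
        groups = [rng.standard_normal(s) + 0.4 * k for k, s in enumerate(sizes)]
        _, p = kruskal_p(groups)
        assert p == pytest.approx(kw_enumeration_p(groups), abs=1e-10)

    def test_two_group_kw_and_mwu_rank_features_identically(self):
        rng = np.random.default_rng(3)
        n_feat = 12
        vals = rng.standard_normal((n_feat, 14))
        vals[:4, 7:] += rng.uniform(0.5, 2.0, size=(4, 7))
        layer = make_layer(vals, [f"f{i}" for i in range(n_feat)])
        ph = classify_phenotype(["A"] * 7 + ["B"] * 7, "g")
        mwu = de_test(layer, ph, "nonparametric")
        kw = [kruskal_p([vals[i, :7], vals[i, 7:]]) for i in range(n_feat)]
        order_mwu = np.argsort([r.p_value for r in mwu], kind="stable")
        order_kw = np.argsort([p for _, p in kw], kind="stable")
        assert list(order_mwu) == list(order_kw)

    def test_anova_five_groups(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((1, 20))
        vals[0, :4] += 3.0
        layer = make_layer(vals, ["f0"])
        ph = classify_phenotype([s for s in "abcde" for _ in range(4)], "subtype")
        (res,) = de_test(layer, ph, "parametric")
        assert res.test_name == "anova" and res.p_value < 0.01

    def test_perfect_separation_flagged(self):
        layer, ph = layer_from_groups([1, 1, 1], [2, 2, 2])
        (res,) = de_test(layer, ph, "parametric")
        assert res.flag == "degenerate_separation" and res.p_value == 0.0

    def test_zero_variance_flagged_p_one(self):
        layer, ph = layer_from_groups([5, 5, 5], [5, 5, 5])
        (res,) = de_test(layer, ph, "parametric")
        assert res.flag == "zero_variance" and res.p_value == 1.0

    def test_missing_values_dropped_and_insufficient_flagged(self):
        vals = np.array([[np.nan, np.nan, 1.0, 2.0, 3.0, 4.0],
                         [1.0, 2.0, 1.5, 2.5, 3.0, 4.0]])
        layer = make_layer(vals, ["sparse", "dense"])
        ph = classify_phenotype(["A"] * 3 + ["B"] * 3, "g")
        sparse, dense = de_test(layer, ph, "parametric")
        assert sparse.flag == "insufficient_data" and math.isnan(sparse.p_value)
        assert dense.flag is None

    def test_continuous_regression_and_nonparametric_rejected(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0, 1, 12)
        vals = (2.0 * x + 0.1 * rng.standard_normal(12))[None, :]
        layer = make_layer(vals, ["f0"])
        ph = classify_phenotype(x, "dose", kind="continuous")
        (res,) = de_test(layer, ph, "parametric")
        assert res.test_name == "ls-regression" and res.p_value < 1e-6
        with pytest.raises(ValidationError, match="nonparametric"):
            de_test(layer, ph, "nonparametric")

    def test_welch_matches_scipy_directly(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal(9), rng.standard_normal(11) + 1
        layer, ph = layer_from_groups(x, y)
        (res,) = de_test(layer, ph, "parametric")
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)


# ---------------------------------------------------------------------------
# BH


class TestBH:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_stay_equal(self):
        assert bh_adjust([0.2] * 7) == pytest.approx([0.2] * 7)

    def test_small_vector_by_direct_formula(self):
        p = [0.01, 0.02, 0.04, 0.05]
        # step-up: q4=0.05, q3=min(4*.04/3, .05)=0.05, q2=min(4*.02/2,...)=0.04, q1=0.04
        assert bh_adjust(p) == pytest.approx([0.04, 0.04, 0.05, 0.05])
        assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    def test_matches_oracle_and_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(1, 200))
            p = rng.uniform(size=n)
            q = bh_adjust(p)
            assert np.max(np.abs(q - np.array(bh_oracle(p)))) < 1e-12
            assert np.max(np.abs(q - multipletests(p, method="fdr_bh")[1])) < 1e-12

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_permutation_invariance(self, p, rnd):
        q = bh_adjust(p)
        idx = list(range(len(p)))
        rnd.shuffle(idx)
        q_shuf = bh_adjust([p[i] for i in idx])
        assert np.allclose([q[i] for i in idx], q_shuf, atol=1e-15)

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValidationError):
            bh_adjust([-0.1])


class TestFilter:
    def test_vacuous_and_empty_thresholds(self):
        rng = np.random.default_rng(13)
        layer = make_layer(rng.standard_normal((10, 12)), [f"f{i}" for i in range(10)])
        ph = classify_phenotype(["A"] * 6 + ["B"] * 6, "g")
        res = de_test(layer, ph, "parametric")
        assert filter_by_significance(res, 1.0) == list(range(10))
        assert filter_by_significance(res, 0.0) == []

    def test_planted_effects_recovered(self):
        fx = synthetic.build_fixture(synthetic.default_planted_spec(seed=101))
        layer = fx["layers"][0]
        ph = classify_phenotype(
            fx["samples"].phenotype_values("group", layer.sample_columns), "group")
        res = de_test(layer, ph, "parametric")
        kept = filter_by_significance(res, 0.05, 0.05)
        true = set(fx["true_rows"]["mrna"])
        assert len(set(kept) & true) >= 18

    def test_flagged_features_never_retained(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
                         [0.0, 0.1, 0.2, 3.0, 3.1, 3.2]])
        layer = make_layer(vals, ["flat", "shifted"])
        ph = classify_phenotype(["A"] * 3 + ["B"] * 3, "g")
        res = de_test(layer, ph, "parametric")
        kept = filter_by_significance(res, 1.0, None)
        assert 1 in kept  # zero-variance row is testable-with-flag p=1, still p<=1
        # insufficient-data rows stay out
        vals2 = np.array([[np.nan, np.nan, np.nan, 1.0, 2.0, 3.0]])
        layer2 = make_layer(vals2, ["sparse"])
        res2 = de_test(layer2, ph, "parametric")
        assert filter_by_significance(res2, 1.0) == []


# ---------------------------------------------------------------------------
# enrichment


class TestEnrichment:
    def test_direct_combinatorial_example(self):
        # N=10, K=4, n=3, k=3 -> C(4,3)/C(10,3) = 4/120
        bg = {f"g{i}" for i in range(10)}
        group = {"g0", "g1", "g2", "g3"}
        de = {"g0", "g1", "g2"}
        res = enrichment_test(de, group, bg)
        assert res.p_value == pytest.approx(4 / 120, rel=1e-12)
        assert (res.overlap_count, res.group_size, res.de_count, res.background_size) == (3, 4, 3, 10)

    def test_zero_overlap_tail_is_one(self):
        bg = {str(i) for i in range(8)}
        res = enrichment_test({"0", "1"}, {"6", "7"}, bg)
        assert res.p_value <= 1.0
        assert hypergeom_tail_oracle(res.overlap_count, 8, 2, 2) == pytest.approx(res.p_value)

    def test_matches_exact_enumeration_all_small_configs(self):
        for N in range(1, 13):
            bg = {str(i) for i in range(N)}
            for K in range(N + 1):
                group = {str(i) for i in range(K)}
                for n in range(N + 1):
                    de = {str(i) for i in range(n)}
                    res = enrichment_test(de, group, bg)
                    expect = hypergeom_tail_oracle(res.overlap_count, N, K, n)
                    assert res.p_value == pytest.approx(expect, rel=1e-10, abs=1e-12)

    def test_empty_background_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_test(set(), {"a"}, set())

    def test_de_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_test({"x"}, {"a"}, {"a", "b"})

    def test_report_sorted_ascending_p_with_filters(self, kb):
        de = {str(1000 + i) for i in range(10)}          # the UPR gene-set anchors
        bg = {str(1000 + i) for i in range(50)}
        report = enrich(kb, de, bg, min_group_size=2, min_de_members=1)
        assert report, "at least one group passes the size filters"
        ps = [r.p_value for r in report]
        assert ps == sorted(ps)
        assert report[0].group_id == "GO:0030968"        # fully-DE group ranks first
        assert all(r.group_size >= 2 for r in report)
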