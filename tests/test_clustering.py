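"""Ordering: hierarchical clustering, synchronization, nesting, sorts."""

import numpy as np
import pytest

from omiclink.clustering import (
    ClusterConfig,
    OrderingResult,
    cluster_samples,
    hcluster,
    nested_hcluster,
    pairwise_complete_distances,
    sort_features,
    sort_samples,
    synchronize,
    to_newick,
)
from omiclink.errors import ValidationError
from omiclink.linking import LinkEdge, LinkMap, detect_nesting
from omiclink.stats import TestResult as DEResult

from .conftest import make_layer, make_samples

CFG = ClusterConfig()


class TestDistances:
    def test_euclidean_matches_scipy_when_complete(self):
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(0)
        m = rng.standard_normal((6, 5))
        assert np.allclose(pairwise_complete_distances(m, "euclidean"), pdist(m))

    def test_correlation_self_zero_negation_two(self):
        rng = np.random.default_rng(1)
        row = rng.standard_normal(8)
        m = np.vstack([row, row, -row])
        d = pairwise_complete_distances(m, "correlation")
        assert d[0] == pytest.approx(0.0, abs=1e-12)      # row vs itself
        assert d[1] == pytest.approx(2.0, abs=1e-12)      # row vs negation

    def test_pairwise_complete_rescaling(self):
        m = np.array([[0.0, 0.0, np.nan, np.nan], [3.0, 4.0, 1.0, 1.0]])
        d = pairwise_complete_distances(m, "euclidean")
        # shared coords (0,0) vs (3,4): sq dist 25 over 2 of 4 coords -> sqrt(25*4/2)
        assert d[0] == pytest.approx(np.sqrt(50))

    def test_all_missing_row_names_row(self):
        m = np.array([[np.nan, np.nan], [1.0, 2.0]])
        with pytest.raises(ValidationError, match="row 0"):
            pairwise_complete_distances(m, "euclidean")

    def test_too_few_shared_gets_maximal_distance(self):
        m = np.array([[1.0, np.nan, np.nan, 2.0],
                      [np.nan, 1.0, 2.0, np.nan],
                      [0.0, 1.0, 2.0, 3.0],
                      [3.0, 2.0, 1.0, 0.0]])
        d = pairwise_complete_distances(m, "correlation")
        defined = [d[k] for k in (1, 2, 3, 4, 5)]
        assert d[0] == pytest.approx(max(defined))


class TestHcluster:
    def test_two_rows_single_merge(self):
        res = hcluster(np.array([[0.0, 1.0], [5.0, 5.0]]), CFG)
        assert sorted(res.order) == [0, 1]
        assert res.linkage_matrix.shape == (1, 4)

    def test_duplicated_rows_adjacent(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((4, 6))
        m = np.vstack([base, base[1]])      # row 4 duplicates row 1
        res = hcluster(m, CFG)
        pos = {r: i for i, r in enumerate(res.order)}
        assert abs(pos[1] - pos[4]) == 1

    def test_top_split_recovers_planted_two_clusters(self):
        rng = np.random.default_rng(3)
        m = np.vstack([rng.standard_normal((3, 5)) + 10.0, rng.standard_normal((3, 5))])
        res = hcluster(m, CFG)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(res.linkage_matrix, 2, criterion="maxclust")
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        # brute force: planted split has the best between/within separation
        best = None
        import itertools

        for combo in itertools.combinations(range(6), 3):
            a = set(combo)
            b = set(range(6)) - a
            within = max(np.linalg.norm(m[i] - m[j]) for s in (a, b)
                         for i in s for j in s if i < j)
            between = min(np.linalg.norm(m[i] - m[j]) for i in a for j in b)
            score = between - within
            if best is None or score > best[0]:
                best = (score, a)
        assert best[1] in ({0, 1, 2}, {3, 4, 5})

    def test_permutation_equivariance_of_merge_tree(self):
        from scipy.cluster.hierarchy import cut_tree

        rng = np.random.default_rng(4)
        m = rng.standard_normal((7, 5))
        perm = rng.permutation(7)
        res = hcluster(m, CFG)
        res_p = hcluster(m[perm], CFG)

        def clusters(z, relabel):
            """Every merge as a frozenset of original row ids, plus its height."""
            cuts = cut_tree(z)
            out = set()
            for col in range(cuts.shape[1]):
                labels = cuts[:, col]
                for lab in np.unique(labels):
                    out.add(frozenset(relabel[i] for i in np.where(labels == lab)[0]))
            return out

        assert clusters(res.linkage_matrix, list(range(7))) == \
            clusters(res_p.linkage_matrix, [int(perm[i]) for i in range(7)])
        # merge heights are permutation-invariant too
        assert np.allclose(sorted(res.linkage_matrix[:, 2]),
                           sorted(res_p.linkage_matrix[:, 2]))

    def test_optimal_leaf_order_is_a_permutation_of_plain(self):
        rng = np.random.default_rng(5)
        m = rng.standard_normal((9, 4))
        plain = hcluster(m, CFG)
        opt = hcluster(m, ClusterConfig(leaf_order="optimal"))
        assert sorted(opt.order) == sorted(plain.order) == list(range(9))

    def test_single_row_rejected(self):
        with pytest.raises(ValidationError, match="2 rows"):
            hcluster(np.zeros((1, 4)), CFG)

    def test_deterministic_across_calls(self):
        rng = np.random.default_rng(6)
        m = rng.standard_normal((8, 5))
        a, b = hcluster(m, CFG), hcluster(m, CFG)
        assert a.order == b.order
        assert np.array_equal(a.linkage_matrix, b.linkage_matrix)


class TestSynchronize:
    def one_to_one_map(self, n, perm_b):
        edges = frozenset(LinkEdge(i, perm_b[i]) for i in range(n))
        return LinkMap(("A", "B"), edges, "inferred")

    def test_one_to_one_transport_is_order_isomorphism(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(2, 10))
            perm_b = list(rng.permutation(n))
            anchor = OrderingResult("A", tuple(range(n)), tuple(rng.permutation(n)))
            links = self.one_to_one_map(n, perm_b)
            res = synchronize(anchor, "B", list(range(n)), links)
            a_rows = anchor.ordered_rows()
            b_rows = res.ordered_rows()
            assert [perm_b[r] for r in a_rows] == b_rows

    def test_one_anchor_to_three_targets_contiguous(self):
        # anchor display order: 2, 0, 1 ; anchor row 0 links to targets 1,3,4
        anchor = OrderingResult("A", (0, 1, 2), (2, 0, 1))
        edges = frozenset({LinkEdge(0, 1), LinkEdge(0, 3), LinkEdge(0, 4),
                           LinkEdge(2, 0), LinkEdge(1, 2)})
        links = LinkMap(("A", "B"), edges, "inferred")
        res = synchronize(anchor, "B", [0, 1, 2, 3, 4], links)
        assert res.ordered_rows() == [0, 1, 3, 4, 2]

    def test_unlinked_targets_appended_in_original_order(self):
        anchor = OrderingResult("A", (0, 1), (0, 1))
        links = LinkMap(("A", "B"), frozenset({LinkEdge(0, 2)}), "inferred")
        res = synchronize(anchor, "B", [0, 1, 2, 3], links)
        assert res.ordered_rows() == [2, 0, 1, 3]
        assert res.mode == "synchronized" and res.anchor_layer == "A"

    def test_empty_map_rejected(self):
        anchor = OrderingResult("A", (0, 1), (0, 1))
        with pytest.raises(ValidationError, match="independent"):
            synchronize(anchor, "B", [0], LinkMap(("A", "B"), frozenset(), "inferred"))

    def test_transport_through_transposed_orientation(self):
        anchor = OrderingResult("B", (0, 1, 2), (1, 2, 0))
        links = LinkMap(("A", "B"), frozenset({LinkEdge(i, i) for i in range(3)}), "inferred")
        res = synchronize(anchor, "A", [0, 1, 2], links)   # anchor on the b-side
        assert res.ordered_rows() == [1, 2, 0]


class TestNestedHcluster:
    def test_all_singletons_equals_plain_hcluster_bitwise(self):
        rng = np.random.default_rng(8)
        layer = make_layer(rng.standard_normal((6, 5)), [f"p{i}" for i in range(6)],
                           id_column="parent")
        nesting = detect_nesting(layer, "parent")
        for summary in ("average", "maximum", "minimum", "sum"):
            nested = nested_hcluster(layer, nesting, CFG, summary=summary)
            plain = hcluster(layer.matrix(), CFG)
            assert nested.order == plain.order
            assert np.array_equal(nested.linkage_matrix, plain.linkage_matrix)

    def test_parent_blocks_contiguous(self):
        rng = np.random.default_rng(9)
        parents = ["P1"] * 3 + ["P2"] * 2 + ["P3"] * 4
        layer = make_layer(rng.standard_normal((9, 6)), [f"s{i}" for i in range(9)],
                           id_column="site", extra_meta={"parent": parents})
        nesting = detect_nesting(layer, "parent")
        res = nested_hcluster(layer, nesting, CFG)
        shown_parents = [parents[r] for r in res.ordered_rows()]
        # each parent appears in exactly one contiguous run
        runs = [p for k, p in enumerate(shown_parents) if k == 0 or shown_parents[k - 1] != p]
        assert sorted(runs) == ["P1", "P2", "P3"]

    def test_two_stage_manual_computation(self):
        # 5 rows x 4 samples, parents X(3 rows) and Y(2 rows)
        m = np.array([
            [0.0, 0.0, 0.0, 0.0],
            [1.0, 1.0, 1.0, 1.0],
            [10.0, 10.0, 10.0, 10.0],
            [20.0, 20.0, 20.0, 20.0],
            [21.0, 21.0, 21.0, 21.0],
        ])
        layer = make_layer(m, ["a", "b", "c", "d", "e"], id_column="site",
                           extra_meta={"parent": ["X", "X", "X", "Y", "Y"]})
        nesting = detect_nesting(layer, "parent")
        res = nested_hcluster(layer, nesting, CFG, summary="average")
        rows = res.ordered_rows()
        # X block (mean ~3.67) and Y block (mean 20.5); within X, rows 0,1 merge first
        x_block, y_block = rows[:3], rows[3:]
        assert set(x_block) == {0, 1, 2} and set(y_block) == {3, 4}
        assert {x_block[0], x_block[1]} == {0, 1} or {x_block[1], x_block[2]} == {0, 1}

    def test_singleton_summaries_coincide(self):
        rng = np.random.default_rng(10)
        layer = make_layer(rng.standard_normal((4, 5)), list("abcd"), id_column="p")
        nesting = detect_nesting(layer, "p")
        orders = {s: nested_hcluster(layer, nesting, CFG, summary=s).order
                  for s in ("average", "maximum", "minimum", "sum")}
        assert len(set(orders.values())) == 1

    def test_unknown_summary_rejected(self):
        layer = make_layer(np.zeros((2, 2)), ["a", "b"], id_column="p")
        with pytest.raises(ValidationError, match="summary"):
            nested_hcluster(layer, detect_nesting(layer, "p"), CFG, summary="median")


class TestSorts:
    def test_significance_sort_ascending_p(self):
        results = [DEResult(0, 0.0, 0.5, "t"), DEResult(1, 0.0, 0.01, "t"),
                   DEResult(2, 0.0, 0.2, "t")]
        res = sort_features([0, 1, 2], "significance", test_results=results)
        assert res.ordered_rows() == [1, 2, 0]

    def test_group_sort_two_disjoint_blocks(self):
        res = sort_features([0, 1, 2, 3], "group-membership",
                            group_rows=[{2, 3}, {0, 1}])
        assert res.ordered_rows() == [2, 3, 0, 1]

    def test_feature_in_two_groups_goes_to_first_selected_block(self):
        res = sort_features([0, 1, 2], "group-membership",
                            group_rows=[{0, 1}, {1, 2}])
        assert res.ordered_rows() == [0, 1, 2]   # row 1 stays in the first group's block

    def test_significance_without_results_rejected(self):
        with pytest.raises(ValidationError):
            sort_features([0], "significance")

    def test_sample_sort_time_then_replicate(self, cs1):
        perm = sort_samples(cs1["samples"], ["time", "replicate"])
        names = [cs1["samples"].sample_names[i] for i in perm]
        assert names[:4] == ["T0h_r1", "T0h_r2", "T0.5h_r1", "T0.5h_r2"]

    def test_single_binary_phenotype_two_blocks(self):
        table = make_samples([f"s{i}" for i in range(6)], g=["b", "a", "b", "a", "b", "a"])
        perm = sort_samples(table, ["g"])
        labels = [table.phenotypes["g"][i] for i in perm]
        assert labels == ["a", "a", "a", "b", "b", "b"]

    def test_six_phenotypes_rejected(self, cs1):
        with pytest.raises(ValidationError, match="at most 5"):
            sort_samples(cs1["samples"], ["time"] * 6)

    def test_sample_axis_clustering(self, cs1):
        res = cluster_samples(cs1["layers"][0], CFG)
        assert sorted(res.order) == list(range(16))


def test_every_ordering_is_a_bijection_checked():
    with pytest.raises(ValidationError, match="permutation"):
        OrderingResult("x", (0, 1, 2), (0, 0, 2))


def test_newick_export_parses(cs1):
    import io

    from Bio import Phylo

    res = hcluster(cs1["layers"][0].matrix(), CFG)
    nwk = to_newick(res, labels=cs1["genes"])
    tree = Phylo.read(io.StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == sorted(cs1["genes"])
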