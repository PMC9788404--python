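import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.stats import norm

from ihcsubtype.clustering import (
    DEFAULT_R_GRID,
    ClusterNode,
    ClusterTree,
    attach_support,
    average_linkage_tree,
    correlation_distance,
    fit_au,
    label_cluster,
    multiscale_bootstrap,
    significant_clusters,
)
from ihcsubtype.datamodel import CohortMatrix


def scipy_member_sets(Z, n):
    """Independent reconstruction of member sets + heights from scipy linkage."""
    members = {i: frozenset([i]) for i in range(n)}
    out = {}
    for k, (a, b, height, _) in enumerate(Z):
        members[n + k] = members[int(a)] | members[int(b)]
        out[members[n + k]] = height
    return out


class TestCorrelationDistance:
    def test_identical_profiles_have_zero_distance(self):
        x = np.array([[10, 20, 30, 40, 50, 60, 70]] * 2, dtype=float)
        assert correlation_distance(x)[0, 1] == pytest.approx(0.0)

    def test_anticorrelated_profiles_have_distance_two(self):
        base = np.array([1, 2, 3, 4, 5, 6, 7], dtype=float)
        x = np.vstack([base, -base])
        assert correlation_distance(x)[0, 1] == pytest.approx(2.0)

    def test_three_patient_hand_computation(self):
        x = np.array([[1, 2, 3], [2, 4, 6], [3, 2, 1]], dtype=float)
        d = correlation_distance(x)
        # rows 0 and 1 are proportional (r = 1); rows 0 and 2 reversed (r = -1)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert d[1, 2] == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_patient_named_in_error(self):
        x = np.array([[5, 5, 5, 5, 5, 5, 5], [1, 2, 3, 4, 5, 6, 7]], dtype=float)
        matrix = CohortMatrix(x, ["FLAT", "OK"])
        with pytest.raises(ValueError, match="FLAT"):
            correlation_distance(matrix)


class TestUPGMA:
    def test_two_patients_single_merge(self):
        tree = average_linkage_tree(np.array([[0.0, 0.7], [0.7, 0.0]]), ["a", "b"])
        assert len(tree.nodes) == 1
        assert tree.nodes[0].height == pytest.approx(0.7)
        assert tree.nodes[0].members == frozenset({0, 1})

    def test_hand_computed_four_point_tree(self):
        # d(a,b)=2 merges first; d(c,d)=3 next; final height is the mean of
        # the four cross distances (6+7+8+9)/4 = 7.5
        d = np.array(
            [
                [0, 2, 6, 7],
                [2, 0, 8, 9],
                [6, 8, 0, 3],
                [7, 9, 3, 0],
            ],
            dtype=float,
        )
        tree = average_linkage_tree(d, list("abcd"))
        merges = [(sorted(tree.member_labels(n)), n.height) for n in tree.nodes]
        assert merges[0] == (["a", "b"], 2.0)
        assert merges[1] == (["c", "d"], 3.0)
        assert merges[2] == (["a", "b", "c", "d"], 7.5)

    def test_two_block_matrix_splits_at_root(self):
        d = np.full((6, 6), 1.8)
        d[:3, :3] = 0.1
        d[3:, 3:] = 0.1
        np.fill_diagonal(d, 0.0)
        tree = average_linkage_tree(d)
        root = tree.root
        children = {
            frozenset(tree.member_labels(n)) for n in tree.nodes
            if n.id in (root.left, root.right)
        }
        assert children == {frozenset({"0", "1", "2"}), frozenset({"3", "4", "5"})}

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage_tree(d)

    def test_matches_scipy_average_linkage_on_random_matrices(self):
        """Independent oracle: scipy's average-linkage agrees on member sets
        and merge heights for 100 random small matrices."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(3, 7))
            x = rng.random((n, 7))
            d = correlation_distance(x)
            ours = average_linkage_tree(d)
            theirs = scipy_member_sets(linkage(d[np.triu_indices(n, 1)], "average"), n)
            assert len(ours.nodes) == len(theirs)
            for node in ours.nodes:
                assert node.members in theirs
                assert node.height == pytest.approx(theirs[node.members], abs=1e-9)

    def test_deterministic_tie_break(self):
        # equilateral triangle: every pair ties; the (a, b) pair must merge first
        d = np.full((3, 3), 1.0)
        np.fill_diagonal(d, 0.0)
        tree = average_linkage_tree(d, ["c", "a", "b"])
        assert sorted(tree.member_labels(tree.nodes[0])) == ["a", "b"]


@pytest.fixture(scope="module")
def planted(three_block_matrix):
    matrix, blocks = three_block_matrix
    tree = average_linkage_tree(correlation_distance(matrix), matrix.patient_ids)
    bp = multiscale_bootstrap(matrix, tree, nboot=200, seed=11)
    return matrix, blocks, tree, bp


class TestMultiscaleBootstrap:
    def test_root_always_recovered(self, planted):
        _, _, tree, bp = planted
        assert (bp.loc[tree.root.id] == 1.0).all()

    def test_well_separated_blocks_have_high_scale1_bp(self):
        """Two anti-correlated gradient profiles (every marker informative,
        structured variance under any marker resample): the block nodes are
        recovered by essentially every naive (scale-1) bootstrap tree."""
        rng = np.random.default_rng(2)
        gradient = np.array([90, 75, 60, 45, 30, 15, 5], dtype=float)
        rows = [gradient + rng.normal(0, 2, 7) for _ in range(8)]
        rows += [gradient[::-1] + rng.normal(0, 2, 7) for _ in range(8)]
        matrix = CohortMatrix(np.clip(rows, 0, 100), [f"A{i}" for i in range(8)]
                              + [f"B{i}" for i in range(8)])
        tree = average_linkage_tree(correlation_distance(matrix), matrix.patient_ids)
        bp = multiscale_bootstrap(matrix, tree, r_grid=(1.0,), nboot=500, seed=2)
        block_sets = [frozenset(range(8)), frozenset(range(8, 16))]
        found = [n for n in tree.nodes if n.members in block_sets]
        assert len(found) == 2
        for node in found:
            assert bp.loc[node.id, 1.0] >= 0.99

    def test_too_small_resample_rejected(self, planted):
        matrix, _, tree, _ = planted
        with pytest.raises(ValueError, match="fewer than 2"):
            multiscale_bootstrap(matrix, tree, r_grid=(0.1,), nboot=10)

    def test_bp_reproducible_given_seed(self, three_block_matrix):
        matrix, _ = three_block_matrix
        tree = average_linkage_tree(correlation_distance(matrix), matrix.patient_ids)
        a = multiscale_bootstrap(matrix, tree, r_grid=(0.8, 1.0), nboot=50, seed=5)
        b = multiscale_bootstrap(matrix, tree, r_grid=(0.8, 1.0), nboot=50, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestAUFit:
    def test_constant_half_bp_gives_half_au(self):
        """BP flat at 0.5 across scales forces psi = 0, hence v = c = 0 and
        AU = BP = 0.5 by the symmetry of the model."""
        fit = fit_au(np.full(10, 0.5), DEFAULT_R_GRID, nboot=1000)
        assert fit.au == pytest.approx(0.5, abs=1e-9)
        assert fit.bp_smoothed == pytest.approx(0.5, abs=1e-9)
        assert fit.c == pytest.approx(0.0, abs=1e-9)

    def test_all_ones_pins_au_to_one(self):
        fit = fit_au(np.ones(10), DEFAULT_R_GRID, nboot=1000)
        assert fit.au == 1.0
        assert fit.flag == "pinned"

    def test_all_zeros_pins_au_to_zero(self):
        fit = fit_au(np.zeros(10), DEFAULT_R_GRID, nboot=1000)
        assert fit.au == 0.0
        assert fit.flag == "pinned"

    def test_recovers_known_signed_distance_and_curvature(self):
        """Noise-free BP generated from (v, c) = (0.5, 0.3) must give back
        AU = 1 - Phi(v - c) = 1 - Phi(0.2) exactly."""
        v, c = 0.5, 0.3
        r = np.asarray(DEFAULT_R_GRID)
        bp = 1.0 - norm.cdf(v * np.sqrt(r) + c / np.sqrt(r))
        fit = fit_au(bp, DEFAULT_R_GRID, nboot=1000)
        assert fit.v == pytest.approx(v, abs=1e-6)
        assert fit.c == pytest.approx(c, abs=1e-6)
        assert fit.au == pytest.approx(1 - norm.cdf(0.2), abs=1e-6)

    def test_au_equals_bp_when_curvature_is_zero(self):
        v = 0.8
        r = np.asarray(DEFAULT_R_GRID)
        bp = 1.0 - norm.cdf(v * np.sqrt(r))
        fit = fit_au(bp, DEFAULT_R_GRID, nboot=1000)
        assert fit.c == pytest.approx(0.0, abs=1e-8)
        assert fit.au == pytest.approx(fit.bp_smoothed, abs=1e-8)

    def test_au_exceeds_smoothed_bp_under_positive_curvature(self):
        r = np.asarray(DEFAULT_R_GRID)
        bp = 1.0 - norm.cdf(0.5 * np.sqrt(r) + 0.3 / np.sqrt(r))
        fit = fit_au(bp, DEFAULT_R_GRID, nboot=1000)
        assert fit.c > 0
        assert fit.au > fit.bp_smoothed

    def test_degenerate_fit_falls_back_to_scale1_bp(self):
        bp = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.4, 0.0, 0.0, 0.0, 1.0])
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_au(bp, DEFAULT_R_GRID, nboot=100)
        assert fit.flag == "degenerate"
        assert fit.au == pytest.approx(0.4)


class TestSignificantClusters:
    def test_planted_three_blocks_recovered_exactly(self, three_block_matrix):
        matrix, blocks = three_block_matrix
        tree = average_linkage_tree(correlation_distance(matrix), matrix.patient_ids)
        attach_support(tree, matrix, nboot=500, seed=0)
        clusters, unassigned = significant_clusters(tree, alpha=0.95)
        found = {frozenset(tree.member_labels(n)) for n in clusters}
        assert found == {frozenset(m) for m in blocks.values()}
        assert unassigned == []

    def test_no_significant_nodes_means_everyone_unassigned(self, three_block_matrix):
        matrix, _ = three_block_matrix
        tree = average_linkage_tree(correlation_distance(matrix), matrix.patient_ids)
        attach_support(tree, matrix, r_grid=(0.8, 1.0, 1.2), nboot=30, seed=0)
        clusters, unassigned = significant_clusters(tree, alpha=1.1)  # unreachable
        assert clusters == []
        assert sorted(unassigned) == sorted(matrix.patient_ids)

    def test_maximality_drops_nested_significant_nodes(self):
        # hand-built tree: node 4 = {0,1}, node 5 = {0,1,2}, node 6 = root
        nodes = [
            ClusterNode(4, 0, 1, 0.1, frozenset({0, 1})),
            ClusterNode(5, 4, 2, 0.2, frozenset({0, 1, 2})),
            ClusterNode(6, 5, 3, 0.9, frozenset({0, 1, 2, 3})),
        ]
        tree = ClusterTree(labels=["a", "b", "c", "d"], nodes=nodes)
        tree.support = pd.DataFrame(
            {"au": [0.99, 0.97, 1.0]}, index=pd.Index([4, 5, 6], name="node")
        )
        clusters, unassigned = significant_clusters(tree, alpha=0.95)
        assert [c.id for c in clusters] == [5]
        assert unassigned == ["d"]

    def test_selected_clusters_are_laminar_and_partition_leaves(self, three_block_matrix):
        matrix, _ = three_block_matrix
        tree = average_linkage_tree(correlation_distance(matrix), matrix.patient_ids)
        attach_support(tree, matrix, nboot=200, seed=3)
        for alpha in (0.5, 0.8, 0.95):
            clusters, unassigned = significant_clusters(tree, alpha=alpha)
            seen: set[int] = set()
            for node in clusters:
                assert not (node.members & seen)  # maximal => disjoint
                seen |= node.members
            assert len(unassigned) == tree.n_leaves - len(seen)


class TestClusterLabel:
    @pytest.fixture()
    def matrix(self):
        # columns: UPK GATA3 CK5 CK14 CK18 CK20 CD44
        values = np.array(
            [
                [0, 80, 5, 0, 70, 60, 0],  # luminal-like
                [0, 90, 5, 0, 75, 55, 0],
                [0, 85, 60, 0, 70, 5, 0],  # mixed-like
                [0, 80, 55, 0, 65, 0, 0],
                [0, 10, 80, 60, 5, 0, 60],  # basal-like
                [0, 15, 75, 55, 5, 0, 65],
                [0, 80, 0, 0, 5, 60, 0],  # CK20+/CK18- reject pattern
            ],
            dtype=float,
        )
        return CohortMatrix(values, [f"P{i}" for i in range(7)])

    @pytest.mark.parametrize(
        "members,major,sub",
        [
            (["P0", "P1"], "luminal", "CK5-/GATA3+"),
            (["P2", "P3"], "mixed", "CK5+/GATA3+"),
            (["P4", "P5"], "basal", "CK5+/GATA3-"),
        ],
    )
    def test_median_rule(self, matrix, members, major, sub):
        label = label_cluster(members, matrix, cutoff=20)
        assert label.major == major
        assert label.sub == sub

    def test_reject_pattern_warns(self, matrix):
        with pytest.warns(UserWarning, match="CK20"):
            label = label_cluster(["P6"], matrix, cutoff=20)
        assert label.major == "unclassified"

    def test_empty_cluster_rejected(self, matrix):
        with pytest.raises(ValueError):
            label_cluster([], matrix)


class TestNewickExport:
    def test_newick_parses_and_preserves_leaves(self, three_block_matrix):
        import dendropy

        matrix, _ = three_block_matrix
        tree = average_linkage_tree(correlation_distance(matrix), matrix.patient_ids)
        attach_support(tree, matrix, r_grid=(0.8, 1.0), nboot=30, seed=1)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        leaves = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert leaves == set(matrix.patient_ids)
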