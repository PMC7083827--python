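"""Geometric median, minimum-distance superimposition and ancestral
landmark reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tarsomorph import (
    branch_length_for_landmarks,
    geometric_median,
    minimum_distance_align,
    parse_newick,
    reconstruct_ancestral,
)


def rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestGeometricMedian:
    def test_fermat_point_of_equilateral_triangle_is_centroid(self):
        pts = [[0.0, 0.0], [1.0, 0.0], [0.5, 0.866025]]
        np.testing.assert_allclose(
            geometric_median(pts), [0.5, 0.288675], atol=1e-6
        )

    def test_vertex_rule_for_wide_apex(self):
        # apex angle exceeds 120 degrees: the apex itself is optimal
        np.testing.assert_allclose(
            geometric_median([[0.0, 0.0], [1.0, 0.0], [0.5, 0.1]]),
            [0.5, 0.1],
            atol=1e-12,
        )

    def test_collinear_points_give_the_one_dimensional_median(self):
        np.testing.assert_allclose(
            geometric_median([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]]),
            [1.0, 0.0],
            atol=1e-9,
        )

    def test_single_point_returns_itself(self):
        np.testing.assert_array_equal(geometric_median([[3.0, 4.0]]), [3.0, 4.0])

    def test_dominant_weight_pins_the_median(self):
        m = geometric_median([[0.0, 0.0], [1.0, 0.0]], weights=[5.0, 1.0])
        np.testing.assert_allclose(m, [0.0, 0.0], atol=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
            min_size=2,
            max_size=8,
        )
    )
    def test_beats_every_candidate_vertex_and_the_centroid(self, points):
        pts = np.asarray(points)
        m = geometric_median(pts)

        def total(y):
            return np.linalg.norm(pts - y, axis=1).sum()

        best_candidate = min(
            [total(p) for p in pts] + [total(pts.mean(axis=0))]
        )
        assert total(m) <= best_candidate + 1e-7


class TestMinimumDistanceAlign:
    def test_reference_and_self_untouched(self, rng):
        x = rng.normal(size=(5, 2))
        out = minimum_distance_align({"ref": x, "same": x.copy()}, "ref")
        np.testing.assert_array_equal(out.transformed["ref"], x)
        assert out.objective["same"] < 1e-8

    def test_recovers_a_rigid_rotation(self, rng):
        x = rng.normal(size=(6, 2))
        y = x @ rot(0.7).T + [2.0, -1.0]
        out = minimum_distance_align({"ref": x, "moved": y}, "ref")
        assert out.objective["moved"] < 1e-8
        np.testing.assert_allclose(out.transformed["moved"], x, atol=1e-7)

    def test_unknown_reference_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown reference"):
            minimum_distance_align({"a": rng.normal(size=(4, 2))}, "zzz")

    def test_objective_matches_rotation_grid_oracle(self, rng):
        """Brute force: 1e-4 rad rotation grid with the translation refined
        per angle by an (independent, vectorised) Weiszfeld iteration."""
        X = np.array([[0.0, 0.0], [2.0, 0.2], [1.7, 1.5], [0.1, 1.1]])
        Y = X @ rot(0.4).T + rng.normal(scale=0.3, size=X.shape)
        out = minimum_distance_align({"ref": Y, "x": X}, "ref")
        obj = out.objective["x"]

        thetas = np.arange(0.0, 2 * np.pi, 1e-4)
        R = np.stack([rot(t) for t in thetas])  # (T, 2, 2)
        XR = np.einsum("tij,pj->tpi", R, X)  # (T, 4, 2)
        res = Y[None] - XR  # optimal translation = geometric median of res
        t = res.mean(axis=1)  # (T, 2) init
        for _ in range(200):
            d = np.linalg.norm(res - t[:, None], axis=2)
            w = 1.0 / np.maximum(d, 1e-12)
            t = (w[..., None] * res).sum(axis=1) / w.sum(axis=1)[:, None]
        vals = np.linalg.norm(res - t[:, None], axis=2).sum(axis=1)
        oracle = float(vals.min())
        assert obj == pytest.approx(oracle, abs=1e-4)
        assert obj <= oracle + 1e-9


def leaf_map(**kw):
    return {k: np.asarray(v, float).reshape(-1, 2) for k, v in kw.items()}


class TestReconstruction:
    def test_two_leaves_meet_at_the_midpoint(self):
        tree = parse_newick("(A,B);")
        r = reconstruct_ancestral(leaf_map(A=[0.0, 0.0], B=[3.0, 4.0]), tree)
        assert r.tree_length == pytest.approx(5.0, abs=1e-9)
        np.testing.assert_allclose(r.ancestral["N1"][0], [1.5, 2.0], atol=1e-5)

    def test_equilateral_star_attains_the_fermat_length(self):
        tree = parse_newick("(A,B,C);")
        r = reconstruct_ancestral(
            leaf_map(A=[0.0, 0.0], B=[1.0, 0.0], C=[0.5, np.sqrt(3) / 2]), tree
        )
        assert r.tree_length == pytest.approx(np.sqrt(3), abs=1e-6)

    def test_unit_square_realises_the_steiner_tree(self):
        tree = parse_newick("((A,B),(C,D));")
        r = reconstruct_ancestral(
            leaf_map(A=[0.0, 0.0], B=[0.0, 1.0], C=[1.0, 0.0], D=[1.0, 1.0]), tree
        )
        assert r.tree_length == pytest.approx(1 + np.sqrt(3), abs=1e-6)
        xs = sorted(
            r.ancestral[n][0, 0] for n in ("N1", "N2")
        )
        assert xs[0] == pytest.approx(1 / (2 * np.sqrt(3)), abs=1e-6)
        assert xs[1] == pytest.approx(1 - 1 / (2 * np.sqrt(3)), abs=1e-6)
        ys = [r.ancestral[n][0, 1] for n in ("N1", "N2")]
        np.testing.assert_allclose(ys, 0.5, atol=1e-6)

    def test_tree_length_decomposes_over_landmarks_and_branches(self, rng):
        tree = parse_newick("((A,(B,C)),(D,E));")
        leaves = {l: rng.normal(size=(4, 2)) for l in "ABCDE"}
        r = reconstruct_ancestral(leaves, tree)
        assert r.tree_length == pytest.approx(r.per_landmark_lengths.sum(), abs=1e-9)
        assert r.tree_length == pytest.approx(
            r.branch_landmark_lengths.values.sum(), abs=1e-9
        )
        assert (r.branch_landmark_lengths.values >= 0).all()
        total = sum(
            branch_length_for_landmarks(r, b, range(4))
            for b in tree.branches()
        )
        assert total == pytest.approx(r.tree_length, abs=1e-9)
        assert branch_length_for_landmarks(r, tree.branches()[0], []) == 0.0

    def test_length_is_invariant_to_rerooting(self, rng):
        leaves = {l: rng.normal(size=(3, 2)) for l in "ABCD"}
        lengths = [
            reconstruct_ancestral(leaves, parse_newick(s)).tree_length
            for s in ("((A,B),(C,D));", "(A,(B,(C,D)));", "(((A,B),C),D);")
        ]
        assert max(lengths) - min(lengths) < 1e-9

    def test_zero_subgradient_certificate_at_optimum(self, rng):
        tree = parse_newick("((A,(B,C)),(D,E));")
        leaves = {l: rng.uniform(size=(1, 2)) for l in "ABCDE"}
        r = reconstruct_ancestral(leaves, tree)
        pos = {k: v[0] for k, v in r.node_positions.items()}
        for node in tree.internal_nodes():
            neigh = [pos[c.id] for c in node.children]
            if node.parent is not None:
                neigh.append(pos[node.parent.id])
            ds = [np.linalg.norm(p - pos[node.id]) for p in neigh]
            if min(ds) < 1e-7:
                continue  # coincident neighbour: subgradient test not applicable
            pull = sum((p - pos[node.id]) / d for p, d in zip(neigh, ds))
            assert np.linalg.norm(pull) < 1e-6

    def test_grid_search_oracle_on_random_instances(self, rng):
        from oracle_grid import grid_search_tree_length

        topologies = ["(A,(B,C));", "(A,B,C);", "((A,B),(C,D));", "(A,(B,(C,D)));"]
        for i in range(5):
            topo = topologies[i % len(topologies)]
            tree = parse_newick(topo)
            leaves = {l: rng.uniform(size=(1, 2)) for l in tree.leaf_labels()}
            r = reconstruct_ancestral(leaves, tree)
            oracle = grid_search_tree_length(tree, {k: v[0] for k, v in leaves.items()})
            assert r.tree_length <= oracle + 1e-6
            assert oracle - r.tree_length <= 1e-3

    def test_missing_leaf_data_rejected(self, rng):
        tree = parse_newick("(A,(B,C));")
        with pytest.raises(ValueError, match="no configuration.*'C'"):
            reconstruct_ancestral(
                {"A": rng.normal(size=(2, 2)), "B": rng.normal(size=(2, 2))}, tree
            )

    def test_squared_change_option_gives_weighted_means(self):
        tree = parse_newick("(A,B);")
        r = reconstruct_ancestral(
            leaf_map(A=[0.0, 0.0], B=[2.0, 0.0]), tree, squared=True
        )
        # with squared changes the two-leaf total is split into two halves
        assert r.tree_length == pytest.approx(2.0, abs=1e-6)


class TestConsistencyIndex:
    def test_two_leaves_are_always_consistent(self):
        tree = parse_newick("(A,B);")
        r = reconstruct_ancestral(leaf_map(A=[0.0, 0.0], B=[3.0, 4.0]), tree)
        assert r.consistency_index == pytest.approx(1.0, abs=1e-9)

    def test_star_attaining_the_minimum_is_consistent(self):
        tree = parse_newick("(A,B,C);")
        r = reconstruct_ancestral(
            leaf_map(A=[0.0, 0.0], B=[1.0, 0.0], C=[3.0, 0.0]), tree
        )
        assert r.consistency_index == pytest.approx(1.0, abs=1e-6)

    def test_convergent_displacement_lowers_ci(self):
        # A and C, B and D converge pairwise on a tree grouping (A,B) (C,D):
        # MST over terminals is 1, but the topology forces length 2
        tree = parse_newick("((A,B),(C,D));")
        r = reconstruct_ancestral(
            leaf_map(A=[0.0, 0.0], B=[1.0, 0.0], C=[0.0, 0.0], D=[1.0, 0.0]), tree
        )
        assert r.tree_length == pytest.approx(2.0, abs=1e-6)
        assert r.consistency_index == pytest.approx(0.5, abs=1e-4)

    def test_identical_terminals_define_ci_one(self):
        tree = parse_newick("(A,(B,C));")
        r = reconstruct_ancestral(
            leaf_map(A=[1.0, 2.0], B=[1.0, 2.0], C=[1.0, 2.0]), tree
        )
        assert r.tree_length == pytest.approx(0.0, abs=1e-9)
        assert r.consistency_index == 1.0
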