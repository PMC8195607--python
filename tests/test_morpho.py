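"""Sholl analysis, branch-point finding, size measures, SWC round trips."""

import numpy as np
import pytest

from cerebquant import morpho
from cerebquant.exceptions import SWCError
from cerebquant.synth import TreeSimParams, generate_tree

from .oracles import sholl_crossings_bruteforce


def chain_tree(points, types=None):
    n = len(points)
    return morpho.NeuronTree(
        ids=np.arange(1, n + 1),
        types=np.array(types if types is not None else [1] + [3] * (n - 1)),
        xyz=np.asarray(points, dtype=float),
        radius=np.full(n, 0.5),
        parent=np.array([-1] + list(range(1, n))),
    )


def y_tree(trunk=50.0, tip_radius=100.001):
    """Root at origin, 50 µm trunk up the y-axis, then two ~50 µm branches
    running nearly radially so both tips sit at ``tip_radius`` from the
    root (the geometry behind the textbook 1-then-2 crossing profile)."""
    a = 0.001  # rad; tiny splay keeps the two branches distinct
    pts = [
        [0, 0, 0],
        [0, trunk, 0],
        [-tip_radius * np.sin(a), tip_radius * np.cos(a), 0],
        [tip_radius * np.sin(a), tip_radius * np.cos(a), 0],
    ]
    return morpho.NeuronTree(
        ids=np.array([1, 2, 3, 4]),
        types=np.array([1, 3, 3, 3]),
        xyz=np.array(pts, dtype=float),
        radius=np.full(4, 0.5),
        parent=np.array([-1, 1, 2, 2]),
    )


class TestSWC:
    def test_three_node_chain(self, tmp_path):
        p = tmp_path / "chain.swc"
        p.write_text("# comment\n1 1 0 0 0 1 -1\n2 3 0 10 0 0.5 1\n3 3 0 20 0 0.5 2\n")
        tree = morpho.read_swc(p)
        assert tree.n_nodes == 3
        assert tree.root_id == 1
        assert len(tree.children_of()[0]) == 1

    def test_dangling_parent_names_file(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 1 -1\n2 3 0 10 0 0.5 99\n")
        with pytest.raises(SWCError, match="dangling parent id 99"):
            morpho.read_swc(p)

    def test_malformed_line_reports_lineno(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 1 -1\n2 3 0 ten 0 0.5 1\n")
        with pytest.raises(SWCError, match=":2:"):
            morpho.read_swc(p)

    def test_multiple_roots_rejected(self, tmp_path):
        p = tmp_path / "two_roots.swc"
        p.write_text("1 1 0 0 0 1 -1\n2 3 0 10 0 0.5 -1\n")
        with pytest.raises(SWCError, match="exactly one root"):
            morpho.read_swc(p)

    def test_round_trip(self, tmp_path):
        tree = generate_tree(TreeSimParams(seed=2))
        p = tmp_path / "t.swc"
        morpho.write_swc(tree, p)
        back = morpho.read_swc(p)
        assert np.array_equal(back.ids, tree.ids)
        assert np.allclose(back.xyz, tree.xyz, atol=1e-5)
        assert np.array_equal(back.parent, tree.parent)


class TestSholl:
    def test_straight_neurite(self):
        pts = [[0, 10 * k, 0] for k in range(11)]  # 0..100 µm
        tree = chain_tree(pts)
        prof = morpho.sholl(tree, center=[0, 0, 0], radius_step=10.0, mode="2d")
        assert np.array_equal(prof.radii, 10.0 * np.arange(1, 11))
        assert np.all(prof.crossings == 1)
        assert prof.total_intersections == 10

    def test_y_tree_profile(self):
        tree = y_tree()
        prof = morpho.sholl(tree, center=[0, 0, 0], radius_step=10.0, mode="2d")
        # 1 crossing at r=10..50, then 2 at r=60..100: total 15
        assert np.array_equal(prof.crossings[:5], np.ones(5))
        assert np.all(prof.crossings[5:] == 2)
        assert prof.total_intersections == 15

    def test_single_node_tree_all_zero(self):
        tree = chain_tree([[0, 0, 0]])
        prof = morpho.sholl(tree, center=[0, 0, 0], radius_step=5.0)
        assert prof.total_intersections == 0

    def test_matches_bruteforce_on_random_trees(self):
        for seed in range(30):
            params = TreeSimParams(
                branch_prob=0.4, max_depth=6, planar=bool(seed % 2), seed=seed
            )
            tree = generate_tree(params)
            mode = "2d" if params.planar else "3d"
            center = tree.xyz[0] if params.planar else tree.xyz[tree.n_nodes // 2]
            prof = morpho.sholl(tree, center=center, radius_step=7.0, mode=mode)
            oracle = sholl_crossings_bruteforce(tree, center, prof.radii, mode=mode)
            assert np.array_equal(prof.crossings, oracle)

    def test_rotation_invariance_3d(self, rng):
        tree = generate_tree(TreeSimParams(planar=False, branch_prob=0.5, max_depth=6, seed=4))
        prof = morpho.sholl(tree, center=[0, 0, 0], radius_step=5.0, mode="3d")
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        rotated = morpho.NeuronTree(
            tree.ids, tree.types, tree.xyz @ rot.T, tree.radius, tree.parent
        )
        prof_rot = morpho.sholl(rotated, center=[0, 0, 0], radius_step=5.0, mode="3d")
        assert np.array_equal(prof.crossings, prof_rot.crossings)

    def test_translation_invariance(self):
        tree = generate_tree(TreeSimParams(seed=5))
        shift = np.array([12.0, -7.0, 3.0])
        moved = morpho.NeuronTree(
            tree.ids, tree.types, tree.xyz + shift, tree.radius, tree.parent
        )
        a = morpho.sholl(tree, center=tree.xyz[0], radius_step=4.0)
        b = morpho.sholl(moved, center=tree.xyz[0] + shift, radius_step=4.0)
        assert np.array_equal(a.crossings, b.crossings)


class TestFirstBranchPoint:
    def test_y_tree_junction(self):
        bp = morpho.first_branch_point(y_tree())
        assert bp.node_id == 2
        assert bp.path_distance == pytest.approx(50.0)

    def test_unbranched_no_branch_status(self):
        tree = chain_tree([[0, 0, 0], [0, 10, 0], [0, 20, 0]])
        assert morpho.first_branch_point(tree) is None

    def test_nearest_of_two_branch_points(self):
        # branch at path distance 30 and a second at 60
        pts = [
            [0, 0, 0],
            [0, 30, 0],  # first branch point (node 2)
            [-10, 40, 0],
            [10, 40, 0],  # node 4: continues to second branch
            [10, 60, 0],  # second branch point at path distance 30+sqrt(200)+20
            [0, 70, 0],
            [20, 70, 0],
        ]
        tree = morpho.NeuronTree(
            ids=np.arange(1, 8),
            types=np.array([1, 3, 3, 3, 3, 3, 3]),
            xyz=np.array(pts, dtype=float),
            radius=np.full(7, 0.5),
            parent=np.array([-1, 1, 2, 2, 4, 5, 5]),
        )
        bp = morpho.first_branch_point(tree)
        assert bp.node_id == 2
        assert bp.path_distance == pytest.approx(30.0)


class TestSizeMeasures:
    def test_max_radial_length_hand_value(self):
        tree = chain_tree([[0, 0, 0], [30, 40, 5]])
        assert morpho.max_radial_length(tree, [0, 0, 0], mode="2d") == pytest.approx(50.0)

    def test_single_node_zero(self):
        tree = chain_tree([[3, 4, 0]])
        assert morpho.max_radial_length(tree, [3, 4, 0]) == 0.0

    def test_max_length_bounds_sholl_radii(self):
        tree = generate_tree(TreeSimParams(seed=8))
        prof = morpho.sholl(tree, center=tree.xyz[0], radius_step=3.0)
        nonzero = prof.radii[prof.crossings > 0]
        if nonzero.size:
            assert morpho.max_radial_length(tree, tree.xyz[0]) >= nonzero.max()

    def test_square_area(self):
        tree = chain_tree([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]])
        assert morpho.projected_area(tree) == pytest.approx(100.0)

    def test_collinear_zero_with_warning(self):
        tree = chain_tree([[0, 0, 0], [10, 0, 0], [20, 0, 0]])
        with pytest.warns(UserWarning):
            assert morpho.projected_area(tree) == 0.0

    def test_hull_monotonic_under_node_subsets(self, rng):
        tree = generate_tree(TreeSimParams(branch_prob=0.5, seed=9))
        full = morpho.projected_area(tree)
        # hull of any subset cannot exceed the hull of all nodes
        for _ in range(5):
            keep = np.sort(rng.choice(tree.n_nodes, size=max(3, tree.n_nodes // 2), replace=False))
            sub_pts = tree.xyz[keep]
            sub = chain_tree(sub_pts.tolist())
            assert morpho.projected_area(sub) <= full + 1e-9

    def test_summary_conservation(self):
        tree = generate_tree(TreeSimParams(seed=10))
        prof = morpho.sholl(tree, center=tree.soma_position(), radius_step=2.0)
        summ = morpho.summarize(tree, radius_step=2.0)
        assert summ.total_intersections == prof.crossings.sum()
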