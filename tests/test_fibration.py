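"""Balanced colorings, refinement, input trees, base graphs, collapsing, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import symrep as sr
from symrep.fibration import (
    Coloring,
    Connectome,
    build_base,
    collapse_bilateral,
    input_tree,
    input_trees_isomorphic,
    is_balanced,
    minimal_balanced_coloring,
    read_connectome,
    write_connectome,
)
from symrep.oracle import naive_refinement, random_instance_battery
from symrep.partition import Partition


def _cycle(n):
    nodes = tuple(f"v{i}" for i in range(n))
    edges = {(nodes[i], nodes[(i + 1) % n]): 1.0 for i in range(n)}
    return Connectome(nodes, edges)


class TestIsBalanced:
    def test_two_color_example(self):
        # two colors: every red node receives one red input, every green
        # node two red inputs
        g = Connectome(
            ("r1", "r2", "g1", "g2"),
            {("r1", "r2"): 1, ("r2", "r1"): 1,
             ("r1", "g1"): 1, ("r2", "g1"): 1, ("r1", "g2"): 1, ("r2", "g2"): 1},
        )
        col = Partition.from_sets([{"r1", "r2"}, {"g1", "g2"}])
        assert is_balanced(g, col).balanced

    def test_directed_cycle_one_color(self):
        assert is_balanced(_cycle(3), Partition.from_sets([{"v0", "v1", "v2"}])).balanced

    def test_violation_report_names_node_and_cluster(self):
        g = Connectome(("a", "b", "c", "d"),
                       {("a", "b"): 1, ("a", "c"): 1, ("d", "b"): 1})
        col = Partition.from_sets([{"a"}, {"b", "c"}, {"d"}])
        report = is_balanced(g, col)
        assert not report.balanced
        viol = {(v.node, v.source_cluster) for v in report.violations}
        # b and c disagree on how many edges they receive from cluster {d}
        d_idx = [i for i, c in enumerate(col.clusters) if c == frozenset({"d"})][0]
        assert any(node in ("b", "c") and k == d_idx for node, k in viol)


class TestMinimalBalancedColoring:
    def test_cycle_is_one_color(self):
        assert minimal_balanced_coloring(_cycle(5)).partition.n_clusters == 1

    def test_star_splits_center_from_leaves(self):
        g = Connectome(("c", "l1", "l2", "l3"),
                       {("l1", "c"): 1, ("l2", "c"): 1, ("l3", "c"): 1})
        mc = minimal_balanced_coloring(g)
        assert mc.partition.same_partition(
            Partition.from_sets([{"c"}, {"l1", "l2", "l3"}])
        )

    def test_matches_naive_refinement_on_battery(self):
        for g, _ in random_instance_battery(seed=7, n_instances=60, max_nodes=8):
            fast = minimal_balanced_coloring(g).partition
            naive = naive_refinement(g.nodes, g.edges)
            assert fast.same_partition(naive)

    def test_output_is_balanced_and_profile_distinct(self):
        for g, _ in random_instance_battery(seed=8, n_instances=40):
            mc = minimal_balanced_coloring(g)
            assert is_balanced(g, mc).balanced
            from symrep.fibration import in_count_matrix

            P = in_count_matrix(g, mc.partition)
            idx = g.index()
            profiles = [tuple(P[idx[min(c)]]) for c in mc.partition.clusters]
            assert len(set(profiles)) == len(profiles)

    def test_rigid_seed_is_respected(self):
        g = _cycle(4)
        seed = Coloring.from_sets([{"v0"}, {"v1", "v2", "v3"}], rigid_labels={"v0"})
        mc = minimal_balanced_coloring(g, seed)
        assert frozenset({"v0"}) in mc.partition.clusters

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_relabeling_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        g, _ = next(iter(random_instance_battery(int(seed) % 2**31, 1, max_nodes=6)))
        perm = rng.permutation(g.n)
        mapping = {g.nodes[i]: f"w{perm[i]}" for i in range(g.n)}
        g2 = Connectome(
            tuple(mapping[x] for x in g.nodes),
            {(mapping[u], mapping[v]): w for (u, v), w in g.edges.items()},
        )
        p1 = minimal_balanced_coloring(g).partition
        p2 = minimal_balanced_coloring(g2).partition
        relabeled = Partition.from_sets([{mapping[x] for x in c} for c in p1.clusters])
        assert relabeled.same_partition(p2)


class TestInputTrees:
    def test_depth1_is_input_set(self):
        g = Connectome(("a", "b", "c"), {("a", "c"): 1, ("b", "c"): 1})
        t = input_tree(g, "c", 1)
        assert t.encoding == ((), ())

    def test_different_indegree_not_isomorphic(self):
        g = Connectome(("a", "b", "c"), {("a", "c"): 1, ("b", "c"): 1, ("a", "b"): 1})
        assert not input_trees_isomorphic(g, "b", "c", 1)

    def test_fibers_equal_input_tree_classes(self, small_planted):
        g = small_planted.connectome
        mc = minimal_balanced_coloring(g).partition
        enc = {v: input_tree(g, v, g.n).encoding for v in g.nodes}
        classes = {}
        for v, e in enc.items():
            classes.setdefault(e, set()).add(v)
        got = Partition.from_sets(list(classes.values()))
        assert got.same_partition(mc)

    def test_same_fiber_isomorphic_at_all_depths(self, small_planted):
        g = small_planted.connectome
        for fiber in small_planted.fibers:
            u = fiber[0]
            for v in fiber[1:]:
                for depth in (1, 3, g.n):
                    assert input_trees_isomorphic(g, u, v, depth)


class TestBaseGraph:
    def test_two_color_base_has_two_nodes(self):
        g = Connectome(
            ("r1", "r2", "g1", "g2"),
            {("r1", "r2"): 1, ("r2", "r1"): 1,
             ("r1", "g1"): 1, ("r2", "g1"): 1, ("r1", "g2"): 1, ("r2", "g2"): 1},
        )
        base = build_base(g, Partition.from_sets([{"r1", "r2"}, {"g1", "g2"}]))
        assert len(base.base_nodes) == 2
        mults = sorted(base.multi_edges.values())
        assert mults == [1, 2]  # red->red one edge, red->green two edges

    def test_singleton_coloring_gives_isomorphic_base(self):
        g = _cycle(4)
        base = build_base(g, Partition.from_sets([{x} for x in g.nodes]))
        assert len(base.base_nodes) == 4 and len(base.multi_edges) == 4

    def test_lift_round_trip(self, small_planted):
        base = build_base(small_planted.connectome, small_planted.planted_partition)
        fiber_names = {min(f): i for i, f in enumerate(small_planted.fibers)}
        got = {}
        for (bu, bv), m in base.multi_edges.items():
            u = fiber_names[bu.split(":")[1]]
            v = fiber_names[bv.split(":")[1]]
            got[(u, v)] = m
        assert got == small_planted.base_edges

    def test_unbalanced_coloring_rejected(self):
        g = Connectome(("a", "b", "c"), {("a", "b"): 1})
        with pytest.raises(ValueError, match="not balanced"):
            build_base(g, Partition.from_sets([{"a"}, {"b", "c"}]))


class TestCollapse:
    def _worm(self):
        return Connectome(
            ("AVAL", "AVAR", "VA1", "VA2"),
            {("AVAL", "VA1"): 3.0, ("AVAR", "VA1"): 2.0, ("AVAL", "VA2"): 1.0},
            roles={"AVAL": "interneuron", "AVAR": "interneuron"},
        )

    def test_or_topology_and_pre_binarization_weights(self):
        c = collapse_bilateral(self._worm(), {"AVA": ("AVAL", "AVAR")})
        assert c.edges[("AVA", "VA1")] == 1.0  # both present -> binary 1
        assert c.edges[("AVA", "VA2")] == 1.0  # only one present -> binary 1
        assert ("AVA", "VA3") not in c.edges
        assert c.pre_weights[("AVA", "VA1")] == 5.0
        assert c.pre_weights[("AVA", "VA2")] == 1.0
        assert c.collapsed and c.role_of("AVA") == "interneuron"

    def test_within_pair_edge_dropped_with_warning(self):
        g = Connectome(("L", "R", "x"), {("L", "R"): 1.0, ("L", "x"): 1.0})
        with pytest.warns(UserWarning, match="self-loop"):
            c = collapse_bilateral(g, {"P": ("L", "R")})
        assert ("P", "P") not in c.edges

    def test_overlapping_pairs_rejected(self):
        with pytest.raises(ValueError):
            collapse_bilateral(self._worm(), {"A": ("AVAL", "AVAR"), "B": ("AVAR", "VA1")})


class TestIO:
    def test_round_trip(self, tmp_path, small_planted):
        path = tmp_path / "g.csv"
        write_connectome(small_planted.connectome, path)
        g2 = read_connectome(path)
        assert g2 == Connectome(small_planted.connectome.nodes,
                                small_planted.connectome.edges)

    def test_duplicate_edge_named_in_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("source,target,weight\nu,v,1\nu,v,2\n")
        with pytest.raises(ValueError, match=r"duplicate edge \(u, v\)"):
            read_connectome(path)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("source,target,weight\nu,v\n")
        with pytest.raises(ValueError, match=":2"):
            read_connectome(path)

    def test_negative_weight_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("source,target,weight\nu,v,-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_connectome(path)
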