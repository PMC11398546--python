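"""SymRep MILP: model structure, worked examples, oracle equivalence."""

import numpy as np
import pytest

from symrep.fibration import Coloring, Connectome, is_balanced, minimal_balanced_coloring
from symrep.oracle import (
    decomposed_balance_minimum,
    exhaustive_repair_minimum,
    random_instance_battery,
)
from symrep.partition import Partition
from symrep.repair import (
    RepairProblem,
    build_model,
    modification_percentage,
    penalty_sweep,
    repaired_connectome,
    solve_repair,
    verify_solution,
)


def _uvw():
    return Connectome(("u", "v", "w"), {("u", "v"): 1.0})


class TestBuildModel:
    def test_balanced_target_admits_zero_solution(self, small_planted):
        p = RepairProblem(small_planted.connectome, Coloring(small_planted.planted_partition),
                          unbalancing_mode="none")
        sol = solve_repair(p)
        assert sol.objective == 0.0 and sol.removed == () and sol.added == ()

    def test_no_s_variables_without_unbalancing(self):
        p = RepairProblem(_uvw(), Coloring.from_sets([{"u"}, {"v", "w"}]),
                          unbalancing_mode="none")
        m = build_model(p)
        assert len(m.s_index) == 0

    def test_three_node_counts_match_hand_enumeration(self):
        # nodes u,v,w; edge u->v; clusters S0={u}, S1={v,w}
        p = RepairProblem(_uvw(), Coloring.from_sets([{"u"}, {"v", "w"}]),
                          unbalancing_mode="strict")
        m = build_model(p)
        # vars: 1 removable + 5 candidates (6 ordered non-self pairs minus u->v)
        # + s for 2 ordered cluster pairs x 2 clusters = 4
        assert len(m.r_index) == 1
        assert len(m.a_index) == 5
        assert len(m.s_index) == 4
        # balance: 1 consecutive member pair x 2 source clusters = 2 equalities
        assert m.constraint_counts["balance"] == 2
        # one unordered cluster pair: 2x2 surplus rows, 2 exclusivity rows,
        # 2 strict distinctness rows
        assert m.constraint_counts["unbalance_pair"] == 4
        assert m.constraint_counts["s_exclusive"] == 2
        assert m.constraint_counts["distinctness"] == 2

    def test_uncovering_target_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            RepairProblem(_uvw(), Coloring.from_sets([{"u"}, {"v"}]))


class TestWorkedExamples:
    def test_strict_prefers_addition_that_keeps_clusters_distinct(self):
        # removing u->v balances {u},{v,w} but refinement then merges the
        # clusters; the minimal repair is adding u->w
        p = RepairProblem(_uvw(), Coloring.from_sets([{"u"}, {"v", "w"}]),
                          unbalancing_mode="strict")
        sol = solve_repair(p)
        assert sol.objective == 1.0
        assert sol.added == (("u", "w"),) and sol.removed == ()
        assert sol.verification["balanced"] and sol.verification["minimal"]

    def test_balance_only_accepts_cheap_removal(self):
        p = RepairProblem(_uvw(), Coloring.from_sets([{"u"}, {"v", "w"}]),
                          unbalancing_mode="none")
        sol = solve_repair(p)
        assert sol.objective == 1.0  # either removal or addition; balance only

    def test_addition_vs_removals_tradeoff(self):
        # one addition (c->e) or two removals balance the target
        g = Connectome(("a", "b", "e", "c"), {("c", "a"): 1.0, ("c", "b"): 1.0})
        tgt = Coloring.from_sets([{"a", "b", "e"}, {"c"}])
        cheap_add = solve_repair(RepairProblem(g, tgt, alpha=1, beta=1, unbalancing_mode="none"))
        assert cheap_add.objective == 1.0 and cheap_add.added == (("c", "e"),)
        cheap_rem = solve_repair(RepairProblem(g, tgt, alpha=1, beta=3, unbalancing_mode="none"))
        assert cheap_rem.objective == 2.0 and len(cheap_rem.removed) == 2

    def test_verify_rejects_hand_built_non_minimal_solution(self):
        p = RepairProblem(_uvw(), Coloring.from_sets([{"u"}, {"v", "w"}]),
                          unbalancing_mode="strict")
        from symrep.repair import RepairSolution

        hand = RepairSolution((("u", "v"),), (), 1.0, "optimal", {}, "strict")
        v = verify_solution(p, hand)
        assert v["balanced"] and not v["minimal"]

    def test_forbidden_removal_respected(self):
        g = Connectome(("a", "b", "c"), {("a", "b"): 1.0})
        tgt = Coloring.from_sets([{"a"}, {"b", "c"}])
        p = RepairProblem(g, tgt, unbalancing_mode="none",
                          forbidden_removals=frozenset({("a", "b")}))
        sol = solve_repair(p)
        assert ("a", "b") not in sol.removed
        assert is_balanced(repaired_connectome(p, sol), tgt.partition, "binary").balanced

    def test_min_indegree_constraint(self):
        g = Connectome(("a", "b"), {("a", "b"): 1.0})
        tgt = Coloring.from_sets([{"a"}, {"b"}])
        base = solve_repair(RepairProblem(g, tgt, unbalancing_mode="none"))
        assert base.objective == 0.0
        cons = solve_repair(RepairProblem(g, tgt, unbalancing_mode="none",
                                          enforce_min_indegree=True))
        g2 = repaired_connectome(RepairProblem(g, tgt), cons)
        indeg = {x: 0 for x in g2.nodes}
        for (_, v) in g2.edges:
            indeg[v] += 1
        assert min(indeg.values()) >= 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["none", "strict"])
    def test_objective_matches_exhaustive_minimum(self, mode):
        for g, target in random_instance_battery(seed=21, n_instances=25):
            p = RepairProblem(g, target, unbalancing_mode=mode)
            sol = solve_repair(p)
            cost, _, _ = exhaustive_repair_minimum(p, require_minimal=(mode == "strict"))
            assert sol.status == "optimal"
            assert sol.objective == pytest.approx(cost)

    def test_weighted_penalties_against_decomposed_oracle(self):
        for i, (g, target) in enumerate(random_instance_battery(seed=22, n_instances=15)):
            alpha, beta = [(1, 1), (1, 3), (2, 1)][i % 3]
            p = RepairProblem(g, target, alpha=alpha, beta=beta, unbalancing_mode="none")
            sol = solve_repair(p)
            assert sol.objective == pytest.approx(decomposed_balance_minimum(p))

    def test_objective_monotone_in_penalties(self):
        for g, target in random_instance_battery(seed=23, n_instances=8):
            objs = []
            for alpha, beta in [(1, 1), (2, 1), (2, 2), (3, 3)]:
                p = RepairProblem(g, target, alpha=alpha, beta=beta, unbalancing_mode="none")
                objs.append(solve_repair(p).objective)
            assert objs == sorted(objs)

    def test_relabeling_preserves_optimum(self, rng):
        g, target = next(iter(random_instance_battery(seed=31, n_instances=1)))
        p = RepairProblem(g, target, unbalancing_mode="none")
        base_obj = solve_repair(p).objective
        perm = rng.permutation(g.n)
        mapping = {g.nodes[i]: f"w{perm[i]}" for i in range(g.n)}
        g2 = Connectome(tuple(mapping[x] for x in g.nodes),
                        {(mapping[u], mapping[v]): w for (u, v), w in g.edges.items()})
        t2 = Coloring(Partition.from_sets(
            [{mapping[x] for x in c} for c in target.partition.clusters]))
        assert solve_repair(RepairProblem(g2, t2, unbalancing_mode="none")).objective == base_obj


class TestPenaltySweep:
    def test_already_balanced_all_zero(self, small_planted):
        p = RepairProblem(small_planted.connectome, Coloring(small_planted.planted_partition))
        recs = penalty_sweep(p, betas=[1, 2, 3])
        assert all(r["objective"] == 0.0 for r in recs)

    def test_additions_non_increasing_in_beta(self):
        for g, target in random_instance_battery(seed=41, n_instances=10):
            p = RepairProblem(g, target, unbalancing_mode="none")
            recs = penalty_sweep(p, betas=[1, 2, 4, 8])
            adds = [r["n_added"] for r in recs]
            assert all(b <= a for a, b in zip(adds, adds[1:]))

    def test_unit_vs_weighted_percentage(self):
        g = Connectome(("a", "b", "e", "c"), {("c", "a"): 1.0, ("c", "b"): 1.0},
                       pre_weights={("c", "a"): 4.0, ("c", "b"): 1.0})
        tgt = Coloring.from_sets([{"a", "b", "e"}, {"c"}])
        p = RepairProblem(g, tgt, alpha=1, beta=5, unbalancing_mode="none")
        sol = solve_repair(p)  # two removals
        assert len(sol.removed) == 2
        assert modification_percentage(p, sol, "unit") == pytest.approx(100.0)
        assert modification_percentage(p, sol, "weighted") == pytest.approx(250.0)
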