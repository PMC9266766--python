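import random

import pytest
from hypothesis import given, settings, strategies as st

from netcomorbid.crosstalk import (
    FeedbackLoop,
    TargetCategory,
    build_crosstab,
    distinct_gene_count,
    find_feedback_loops,
    interactor_set,
    intersect_sets,
    mutual_inhibition_loops,
    target_relation_categories,
    venn_partition,
)
from netcomorbid.datasets import available_crosstabs, load_crosstab
from netcomorbid.model import (
    ConditionAssociationTable,
    ConditionCategory,
    GeneNetwork,
    NetworkValidationError,
    Relation,
    Sign,
    TypedEdge,
)
from oracles import brute_force_cycles, venn_region_sizes


class TestInteractorSet:
    def test_parallel_edges_deduplicate_to_one_interactor(self):
        net = GeneNetwork("g", edges=[
            TypedEdge("T", "A", Relation.INTERACTION, directed=False),
            TypedEdge("T", "A", Relation.EXPRESSION_UP),
            TypedEdge("T", "B", Relation.INTERACTION, directed=False),
            TypedEdge("C", "T", Relation.ACTIVITY_DOWN),
        ])
        out = interactor_set(net, "T")
        assert set(out) == {"A", "B", "C"}
        assert len(out["A"]) == 2

    def test_isolated_target_has_no_interactors(self):
        net = GeneNetwork("g", nodes=["T", "X"])
        assert interactor_set(net, "T") == {}

    def test_absent_target_errors(self):
        with pytest.raises(NetworkValidationError):
            interactor_set(GeneNetwork("g", nodes=["X"]), "T")

    def test_relation_categories(self):
        net = GeneNetwork("g", edges=[
            TypedEdge("T", "A", Relation.EXPRESSION_UP),
            TypedEdge("T", "B", Relation.ACTIVITY_DOWN),
            TypedEdge("C", "T", Relation.EXPRESSION_UP),
            TypedEdge("D", "T", Relation.EXPRESSION_DOWN),
            TypedEdge("T", "E", Relation.INTERACTION, directed=False),
        ])
        cats = target_relation_categories(net, "T")
        assert cats["A"] == {TargetCategory.UPREGULATED_BY_TARGET}
        assert cats["B"] == {TargetCategory.DOWNREGULATED_BY_TARGET}
        assert cats["C"] == {TargetCategory.UPREGULATES_TARGET}
        assert cats["D"] == {TargetCategory.DOWNREGULATES_TARGET}
        assert cats["E"] == {TargetCategory.OTHER}


class TestCrosstab:
    def test_multicategory_gene_lands_in_two_cells_of_one_row(self):
        cond = ConditionAssociationTable("hg")
        cond.add("STAT3", ConditionCategory.UPREGULATED_BY_CONDITION)
        cond.add("STAT3", ConditionCategory.PRO_CONDITION_ACTIVITY)
        table = build_crosstab(
            cond, {"STAT3": {TargetCategory.DOWNREGULATED_BY_TARGET}}, target="ACE2"
        )
        row = TargetCategory.DOWNREGULATED_BY_TARGET
        assert table.cell(row, ConditionCategory.UPREGULATED_BY_CONDITION) == {"STAT3"}
        assert table.cell(row, ConditionCategory.PRO_CONDITION_ACTIVITY) == {"STAT3"}
        assert distinct_gene_count(table) == 1

    def test_gene_without_condition_entry_falls_into_other_column(self):
        cond = ConditionAssociationTable("hg")
        table = build_crosstab(cond, {"X": {TargetCategory.UPREGULATED_BY_TARGET}})
        assert table.cell(
            TargetCategory.UPREGULATED_BY_TARGET, ConditionCategory.OTHER
        ) == {"X"}

    def test_empty_inputs_give_empty_table(self):
        table = build_crosstab(ConditionAssociationTable("hg"), {})
        assert table.cells == {} and distinct_gene_count(table) == 0

    def test_hand_placed_two_by_two(self):
        cond = ConditionAssociationTable("hg")
        cond.add("A", ConditionCategory.UPREGULATED_BY_CONDITION)
        cond.add("B", ConditionCategory.DOWNREGULATED_BY_CONDITION)
        table = build_crosstab(cond, {
            "A": {TargetCategory.UPREGULATED_BY_TARGET},
            "B": {TargetCategory.UPREGULATED_BY_TARGET},
            "C": {TargetCategory.DOWNREGULATED_BY_TARGET},
        })
        assert table.cell("upregulated_by_target", "upregulated_by_condition") == {"A"}
        assert table.cell("upregulated_by_target", "downregulated_by_condition") == {"B"}
        assert table.cell("downregulated_by_target", "other") == {"C"}

    def test_distinct_count_bounded_by_cell_sum(self):
        table = load_crosstab("ACE2")
        cell_sum = sum(len(g) for g in table.cells.values())
        assert distinct_gene_count(table) <= cell_sum


class TestPublishedCrosstabs:
    """The four bundled condition-vs-entry-protein association grids."""

    @pytest.mark.parametrize(
        "target,expected",
        [("ACE2", 34), ("DPP4", 48), ("CTSB", 48), ("CTSL", 22)],
    )
    def test_distinct_shared_gene_totals(self, target, expected):
        assert distinct_gene_count(load_crosstab(target)) == expected

    def test_stat3_occupies_both_condition_columns(self):
        table = load_crosstab("ACE2")
        row = TargetCategory.DOWNREGULATED_BY_TARGET
        assert "STAT3" in table.cell(row, ConditionCategory.UPREGULATED_BY_CONDITION)
        assert "STAT3" in table.cell(row, ConditionCategory.ANTI_CONDITION_ACTIVITY)

    def test_all_four_targets_available(self):
        assert available_crosstabs() == ["ACE2", "CTSB", "CTSL", "DPP4"]


class TestSetOps:
    def test_intersection_normalizes_symbols(self):
        assert intersect_sets({"hmox1", "PLAT"}, {"HMOX1", "gdf15"}) == {"HMOX1"}

    def test_disjoint_sets_partition_into_single_label_regions(self):
        vp = venn_partition({"a": {"X"}, "b": {"Y", "Z"}})
        assert vp.region("a") == {"X"}
        assert vp.region("b") == {"Y", "Z"}
        assert vp.region("a", "b") == frozenset()

    def test_single_input_rejected(self):
        with pytest.raises(NetworkValidationError):
            venn_partition({"a": {"X"}})

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_regions_match_membership_tally(self, seed):
        rng = random.Random(seed)
        pool = [f"G{i}" for i in range(50)]
        labeled = {
            label: set(rng.sample(pool, rng.randint(0, 30)))
            for label in ("s1", "s2", "s3")
        }
        vp = venn_partition(labeled)
        assert vp.counts() == venn_region_sizes(labeled)
        union = set()
        for genes in labeled.values():
            union |= genes
        assert sum(vp.counts().values()) == len(union)


def loop_net(*arcs):
    """Build a network from (src, tgt, '+'/'-') regulatory arcs."""
    rel = {"+": Relation.ACTIVITY_UP, "-": Relation.ACTIVITY_DOWN}
    return GeneNetwork("loops", edges=[TypedEdge(s, t, rel[x]) for s, t, x in arcs])


class TestFeedbackLoops:
    def test_mutual_downregulation_is_a_positive_two_loop(self):
        # reciprocal inhibition (e.g. two enzymes suppressing each other)
        net = loop_net(("ACE2", "ACE", "-"), ("ACE", "ACE2", "-"))
        loops = find_feedback_loops(net)
        assert len(loops) == 1
        assert loops[0].cycle == ("ACE", "ACE2")
        assert loops[0].loop_sign == "positive"
        assert mutual_inhibition_loops(loops) == loops

    def test_sign_product_rules(self):
        pos = find_feedback_loops(loop_net(("A", "B", "+"), ("B", "A", "+")))[0]
        neg = find_feedback_loops(loop_net(("A", "B", "+"), ("B", "A", "-")))[0]
        assert pos.loop_sign == "positive"
        assert neg.loop_sign == "negative"

    def test_unsigned_step_gives_undetermined(self):
        net = GeneNetwork("g", edges=[
            TypedEdge("A", "B", Relation.TRANSPORT),
            TypedEdge("B", "A", Relation.ACTIVITY_UP),
        ])
        assert find_feedback_loops(net)[0].loop_sign == "undetermined"

    def test_undirected_edges_do_not_form_loops(self):
        net = GeneNetwork("g", edges=[
            TypedEdge("A", "B", Relation.INTERACTION, directed=False),
            TypedEdge("B", "A", Relation.ASSOCIATION, directed=False),
        ])
        assert find_feedback_loops(net) == []

    def test_dag_has_no_loops(self):
        net = loop_net(("A", "B", "+"), ("B", "C", "-"), ("A", "C", "+"))
        assert find_feedback_loops(net) == []

    def test_three_cycle_reported_once_in_canonical_rotation(self):
        net = loop_net(("B", "C", "+"), ("C", "A", "+"), ("A", "B", "-"))
        loops = find_feedback_loops(net)
        assert len(loops) == 1
        assert loops[0].cycle == ("A", "B", "C")
        assert loops[0].loop_sign == "negative"

    def test_max_len_two_excludes_triangles(self):
        net = loop_net(("A", "B", "+"), ("B", "C", "+"), ("C", "A", "+"),
                       ("D", "E", "-"), ("E", "D", "-"))
        loops = find_feedback_loops(net, max_len=2)
        assert [l.cycle for l in loops] == [("D", "E")]

    @pytest.mark.parametrize("seed", range(40))
    def test_cycle_set_matches_exhaustive_enumeration(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 7)
        nodes = [f"N{i}" for i in range(n)]
        arcs = {}
        for u in nodes:
            for v in nodes:
                if u != v and rng.random() < 0.25:
                    arcs[(u, v)] = rng.choice("+-")
        net = loop_net(*[(u, v, s) for (u, v), s in arcs.items()])
        got = {l.cycle for l in find_feedback_loops(net)}
        assert got == brute_force_cycles(arcs)

    def test_sign_flip_parity(self):
        # flipping every edge sign flips odd-length loops, preserves even
        arcs = [("A", "B", "+"), ("B", "A", "-"),
                ("C", "D", "+"), ("D", "E", "-"), ("E", "C", "-")]
        flipped = [(u, v, "-" if s == "+" else "+") for u, v, s in arcs]
        before = {l.cycle: l.loop_sign for l in find_feedback_loops(loop_net(*arcs))}
        after = {l.cycle: l.loop_sign for l in find_feedback_loops(loop_net(*flipped))}
        assert before[("A", "B")] == after[("A", "B")]  # even length
        assert before[("C", "D", "E")] != after[("C", "D", "E")]  # odd length

    def test_relabeling_closure(self):
        arcs = [("A", "B", "+"), ("B", "C", "-"), ("C", "A", "+"),
                ("A", "C", "-"), ("C", "B", "+"), ("B", "A", "-")]
        mapping = {"A": "X", "B": "Y", "C": "Z"}
        relabeled = [(mapping[u], mapping[v], s) for u, v, s in arcs]
        orig = {tuple(mapping[g] for g in l.cycle): l.loop_sign
                for l in find_feedback_loops(loop_net(*arcs))}
        # canonical rotation may differ after relabeling; compare as rotation classes
        def rot_class(cyc):
            i = cyc.index(min(cyc))
            return cyc[i:] + cyc[:i]
        orig_canon = {rot_class(c): s for c, s in orig.items()}
        new = {l.cycle: l.loop_sign for l in find_feedback_loops(loop_net(*relabeled))}
        assert orig_canon == new

    def test_invalid_max_len_rejected(self):
        with pytest.raises(NetworkValidationError):
            find_feedback_loops(GeneNetwork("g"), max_len=4)
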