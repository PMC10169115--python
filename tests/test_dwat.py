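"""Release diffing: node/edge classification, tallies, areas, annotations."""
import pytest
from hypothesis import given, strategies as st

from taxdiff import (
    ChangeTally,
    area_annotation_lines,
    build_dwat,
    build_wat,
    classify_nodes,
    derive_taxonomy,
    diff_wats,
    node_annotation_lines,
    random_release,
    simulate_evolution,
)
from taxdiff.errors import NodeLookupError
from taxdiff.dwat import account_node_changes


@pytest.fixture(scope="module")
def vaccine_dwat(vaccine_pair):
    old, new, _ = vaccine_pair
    return build_dwat(old, new, b_old=10, b_new=10)


class TestVaccineExcerptDiff:
    def test_node_statuses_match_narrative(self, vaccine_dwat):
        statuses = {r: n.status for r, n in vaccine_dwat.nodes.items()}
        assert statuses == {
            "Thing": "modified",
            "organism_substance": "removed",
            "processed_material": "modified",
            "vaccine": "unmodified",
            "viral_vaccine": "modified",
            "covid19_vaccine": "introduced",
        }

    def test_root_node_gains_16_relationshipless_concepts(self, vaccine_dwat):
        assert vaccine_dwat.nodes["Thing"].tally == ChangeTally(modified_in=16)

    def test_processed_material_turnover(self, vaccine_dwat):
        t = vaccine_dwat.nodes["processed_material"].tally
        assert (t.new, t.modified_out, t.modified_in, t.deleted) == (10, 29, 0, 0)

    def test_viral_vaccine_tally_and_parea_loss(self, vaccine_dwat):
        t = vaccine_dwat.nodes["viral_vaccine"].tally
        assert t == ChangeTally(
            new=1, deleted=0, modified_in=30, modified_out=1, aggregated_parea_delta=-1
        )

    def test_introduced_covid_vaccine_node(self, vaccine_dwat):
        node = vaccine_dwat.nodes["covid19_vaccine"]
        assert node.status == "introduced"
        assert node.tally.new == 16 and node.tally.modified_in == 1
        assert node.label_source == "T2"

    def test_removed_organism_substance_empties_out(self, vaccine_dwat):
        # The excerpt is closed, so the arrivals elsewhere (16+30+1) force 17
        # moves plus 1 deletion out of this node's original 18 concepts.
        t = vaccine_dwat.nodes["organism_substance"].tally
        assert (t.modified_out, t.deleted) == (17, 1)
        assert t.modified_in == 0 and t.new == 0

    def test_edge_statuses(self, vaccine_dwat):
        assert ("covid19_vaccine", "viral_vaccine", "introduced") in vaccine_dwat.edges
        assert ("organism_substance", "Thing", "removed") in vaccine_dwat.edges
        assert ("vaccine", "processed_material", "unmodified") in vaccine_dwat.edges
        assert not any(s == "modified" for _, _, s in vaccine_dwat.edges)

    def test_area_deltas_and_suppression(self, vaccine_dwat):
        by_rels = {a.base_rel_set: a for a in vaccine_dwat.areas}
        assert by_rels[frozenset()].concept_delta == 16
        assert by_rels[frozenset({"has function"})].concept_delta == -19
        removed_area = by_rels[frozenset({"derives from"})]
        introduced_area = by_rels[
            frozenset({"has function", "immunizes against", "targets virus",
                       "counteracts disease"})
        ]
        assert removed_area.suppressed and introduced_area.suppressed
        assert not by_rels[frozenset()].suppressed

    def test_labels_come_from_old_release_except_introduced(self, vaccine_dwat):
        assert vaccine_dwat.nodes["viral_vaccine"].display_label == "viral vaccine (12){2}[10]"
        assert vaccine_dwat.nodes["covid19_vaccine"].display_label == "COVID-19 vaccine (17){2}[13]"


class TestAnnotationGrammar:
    def test_node_lines_match_canonical_grammar(self, vaccine_dwat):
        assert node_annotation_lines(vaccine_dwat.nodes["viral_vaccine"]) == (
            "+1 New Concept",
            "-1 Concept Modified",
            "+30 Concepts Modified",
            "-1 Aggregated P-area",
        )
        assert node_annotation_lines(vaccine_dwat.nodes["processed_material"]) == (
            "+10 New Concepts",
            "-29 Concepts Modified",
        )
        assert node_annotation_lines(vaccine_dwat.nodes["Thing"]) == (
            "+16 Concepts Modified",
        )
        assert node_annotation_lines(vaccine_dwat.nodes["vaccine"]) == ()

    def test_area_lines(self, vaccine_dwat):
        by_rels = {a.base_rel_set: a for a in vaccine_dwat.areas}
        assert area_annotation_lines(by_rels[frozenset()]) == ("+16 Concepts",)
        assert area_annotation_lines(by_rels[frozenset({"has function"})]) == (
            "-19 Concepts",
        )
        assert area_annotation_lines(by_rels[frozenset({"derives from"})]) == ()

    def test_relationship_delta_singular(self):
        from taxdiff.dwat import DiffArea

        area = DiffArea(
            base_rel_set=frozenset({"x"}),
            rel_delta=-1,
            concept_delta=0,
            suppressed=False,
            member_root_ids=frozenset({"n"}),
        )
        assert area_annotation_lines(area) == ("-1 Rel",)

    def test_plural_aggregated_pareas(self):
        from taxdiff.dwat import DiffNode

        node = DiffNode(
            root_id="n", label="n", status="modified",
            tally=ChangeTally(aggregated_parea_delta=6),
            label_source="T1", shape_source="T1", is_aggregate=False,
            display_label="n (1)",
        )
        assert node_annotation_lines(node) == ("+6 Aggregated P-areas",)


class TestDiffProperties:
    def test_self_diff_is_neutral(self, vaccine_old):
        dwat = build_dwat(vaccine_old, vaccine_old, b_old=10, b_new=10)
        assert all(n.status == "unmodified" for n in dwat.nodes.values())
        assert all(n.tally.is_zero for n in dwat.nodes.values())
        assert all(s == "unmodified" for _, _, s in dwat.edges)
        assert all(a.concept_delta == 0 and a.rel_delta == 0 for a in dwat.areas)

    def test_swapping_releases_swaps_directions(self, vaccine_pair):
        old, new, _ = vaccine_pair
        fwd = build_dwat(old, new, b_old=10, b_new=10)
        rev = build_dwat(new, old, b_old=10, b_new=10)
        for r, node in fwd.nodes.items():
            mirrored = rev.nodes[r]
            assert {"introduced": "removed", "removed": "introduced"}.get(
                node.status, node.status
            ) == mirrored.status
            assert node.tally.new == mirrored.tally.deleted
            assert node.tally.deleted == mirrored.tally.new
            assert node.tally.modified_in == mirrored.tally.modified_out
            assert node.tally.modified_out == mirrored.tally.modified_in
        fwd_edges = {(c, p): s for c, p, s in fwd.edges}
        for (c, p), s in {(c, p): s for c, p, s in rev.edges}.items():
            assert fwd_edges[(c, p)] == {
                "introduced": "removed", "removed": "introduced"
            }.get(s, s)

    def test_lookup_error_when_root_in_neither_wat(self, vaccine_pair):
        old, new, _ = vaccine_pair
        T1 = build_wat(derive_taxonomy(old), 10)
        T2 = build_wat(derive_taxonomy(new), 10)
        with pytest.raises(NodeLookupError):
            account_node_changes("nope", T1, T2, old, new)

    def test_classify_self_is_all_unmodified(self, vaccine_old):
        T = build_wat(derive_taxonomy(vaccine_old), 10)
        assert set(classify_nodes(T, T).values()) == {"unmodified"}

    @given(seed=st.integers(0, 10_000))
    def test_tally_balance_on_simulated_pairs(self, seed):
        base = random_release(n_concepts=45, multi_parent_p=0.1, seed=seed)
        spec = {
            "add_subtree": [{"target": "c0000", "count": 1 + seed % 5}],
            "delete_concepts": [{"target": "Thing", "count": 1 + seed % 3}],
        }
        evolved, _ = simulate_evolution(base, spec, seed=seed)
        T1 = build_wat(derive_taxonomy(base), 3)
        T2 = build_wat(derive_taxonomy(evolved), 3)
        dwat = diff_wats(T1, T2, base, evolved)
        for r, node in dwat.nodes.items():
            n1 = T1.nodes[r].concepts_after if r in T1.nodes else 0
            n2 = T2.nodes[r].concepts_after if r in T2.nodes else 0
            t = node.tally
            if node.status == "unmodified":
                assert n1 == n2 and t.is_zero
            else:
                assert n2 - n1 == t.new - t.deleted + t.modified_in - t.modified_out

    def test_worked_balance_check_viral_vaccine(self, vaccine_dwat):
        t = vaccine_dwat.nodes["viral_vaccine"].tally
        assert 42 - 12 == t.new - t.deleted + t.modified_in - t.modified_out


class TestEditLogRecovery:
    def test_added_subtree_recovered_as_new_concepts(self, vaccine_old):
        spec = {"add_subtree": [{"target": "organism_substance", "count": 40}]}
        evolved, log = simulate_evolution(vaccine_old, spec, seed=7)
        dwat = build_dwat(vaccine_old, evolved, b_old=10, b_new=10)
        t = dwat.nodes["organism_substance"].tally
        assert t.new == 40 and t.deleted == 0
        assert log.records[0].count == 40

    def test_deletions_recovered_with_count_drop(self, vaccine_old):
        spec = {"delete_concepts": [{"target": "organism_substance", "count": 7}]}
        evolved, _ = simulate_evolution(vaccine_old, spec, seed=7)
        dwat = build_dwat(vaccine_old, evolved, b_old=10, b_new=10)
        node = dwat.nodes["organism_substance"]
        assert node.tally.deleted == 7
        assert node.n_new == node.n_old - 7 == 11

    def test_moves_recovered_as_in_and_out(self, vaccine_old):
        spec = {
            "move_concepts": [
                {"source": "organism_substance", "target": "viral_vaccine", "count": 3}
            ]
        }
        evolved, _ = simulate_evolution(vaccine_old, spec, seed=7)
        dwat = build_dwat(vaccine_old, evolved, b_old=10, b_new=10)
        assert dwat.nodes["organism_substance"].tally.modified_out == 3
        assert dwat.nodes["viral_vaccine"].tally.modified_in == 3
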