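"""Release model invariants and concept-table / OWL reading."""
import textwrap

import pytest
from hypothesis import given, strategies as st

from taxdiff import (
    Concept,
    OntologyRelease,
    VIRTUAL_ROOT,
    random_release,
    read_concept_table,
    read_owl,
    write_concept_table,
)
from taxdiff.errors import (
    CycleError,
    DuplicateIdError,
    FormatError,
    ReferentialIntegrityError,
)


class TestReleaseModel:
    def test_parentless_concepts_attach_to_virtual_root(self):
        r = OntologyRelease("v1", [Concept("a", "a"), Concept("b", "b", {"a"})])
        assert r.concepts["a"].parent_ids == {VIRTUAL_ROOT}
        assert r.root_id == VIRTUAL_ROOT and VIRTUAL_ROOT in r

    def test_cyclic_hierarchy_rejected_naming_a_member(self):
        with pytest.raises(CycleError) as exc:
            OntologyRelease("v1", [Concept("a", "a", {"b"}), Concept("b", "b", {"a"})])
        assert exc.value.member in {"a", "b"}

    def test_unknown_parent_rejected(self):
        with pytest.raises(ReferentialIntegrityError) as exc:
            OntologyRelease("v1", [Concept("a", "a", {"ghost"})])
        assert "ghost" in str(exc.value)

    def test_self_parent_rejected(self):
        with pytest.raises(ValueError):
            Concept("a", "a", {"a"})

    def test_deprecated_concepts_dropped_with_links_pruned(self):
        r = OntologyRelease(
            "v1",
            [
                Concept("a", "a"),
                Concept("old", "old", {"a"}, deprecated=True),
                Concept("b", "b", {"old"}),
            ],
        )
        assert "old" not in r
        assert r.n_deprecated_dropped == 1
        # b lost its only parent and was re-attached to the root
        assert r.concepts["b"].parent_ids == {VIRTUAL_ROOT}


class TestConceptTable:
    def test_empty_table_yields_root_only_release(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("#version=e\nid\tlabel\tparents\trels\tdeprecated\n")
        r = read_concept_table(p)
        assert set(r.concepts) == {VIRTUAL_ROOT}

    def test_root_only_release_writes_header_plus_root_row(self, tmp_path):
        p = tmp_path / "root.tsv"
        write_concept_table(OntologyRelease("r", []), p)
        lines = p.read_text().splitlines()
        assert lines[1].startswith("id\t") and len(lines) == 3
        assert lines[2].split("\t")[0] == VIRTUAL_ROOT

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "id\tlabel\tparents\trels\tdeprecated\n"
            "a\tA\t\t\tfalse\n"
            "a\tA2\t\t\tfalse\n"
        )
        with pytest.raises(DuplicateIdError):
            read_concept_table(p)

    def test_unknown_parent_lists_offender(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "id\tlabel\tparents\trels\tdeprecated\na\tA\tmissing\t\tfalse\n"
        )
        with pytest.raises(ReferentialIntegrityError) as exc:
            read_concept_table(p)
        assert "missing" in str(exc.value)

    def test_deprecated_rows_dropped(self, tmp_path):
        p = tmp_path / "dep.tsv"
        p.write_text(
            "id\tlabel\tparents\trels\tdeprecated\n"
            "a\tA\t\t\tfalse\n"
            "b\tB\ta\t\ttrue\n"
        )
        r = read_concept_table(p)
        assert "b" not in r and r.n_deprecated_dropped == 1

    def test_bad_header_is_format_error(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("identifier\tname\n1\tx\n")
        with pytest.raises(FormatError):
            read_concept_table(p)

    @given(seed=st.integers(0, 10_000))
    def test_round_trip_identity_on_random_releases(self, tmp_path_factory, seed):
        release = random_release(n_concepts=40, seed=seed)
        path = tmp_path_factory.mktemp("rt") / "r.tsv"
        write_concept_table(release, path)
        assert read_concept_table(path) == release

    def test_vaccine_excerpt_table_has_91_concepts(self, tmp_path, vaccine_old):
        p = tmp_path / "old.tsv"
        write_concept_table(vaccine_old, p)
        rows = p.read_text().splitlines()[2:]  # version comment + header
        assert len(rows) == 91
        assert read_concept_table(p) == vaccine_old

    def test_process_excerpt_table_round_trips_19_concepts(self, tmp_path, process_excerpt):
        p = tmp_path / "fig1.tsv"
        write_concept_table(process_excerpt, p)
        back = read_concept_table(p)
        assert len(back) == 19 and back == process_excerpt


OWL_TTL = textwrap.dedent(
    """
    @prefix : <http://example.org/onto#> .
    @prefix owl: <http://www.w3.org/2002/07/owl#> .
    @prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
    @prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

    :A a owl:Class ; rdfs:label "A" ;
        rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :p1 ; owl:someValuesFrom :B ] .
    :B a owl:Class ; rdfs:label "B" ; rdfs:subClassOf :A ;
        rdfs:subClassOf [ owl:intersectionOf ( :A
            [ a owl:Restriction ; owl:onProperty :p2 ; owl:allValuesFrom
                [ a owl:Restriction ; owl:onProperty :p3 ; owl:someValuesFrom :A ] ] ) ] .
    :C a owl:Class ; rdfs:label "C" ;
        owl:equivalentClass [ owl:unionOf (
            [ a owl:Restriction ; owl:onProperty :p4 ; owl:hasValue :x ]
            [ a owl:Restriction ; owl:onProperty :p1 ;
              owl:minQualifiedCardinality "1"^^xsd:nonNegativeInteger ; owl:onClass :B ] ) ] .
    :D a owl:Class ; rdfs:label "D" ; rdfs:subClassOf :C ; owl:deprecated true .
    :E a owl:Class ; rdfs:label "E" ;
        rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :dp ; owl:someValuesFrom xsd:string ] .
    :p1 a owl:ObjectProperty ; rdfs:domain :A .
    :p5 a owl:ObjectProperty ; rdfs:domain :B .
    :dp a owl:DatatypeProperty .
    """
)

NS = "http://example.org/onto#"


@pytest.fixture(scope="module")
def owl_path(tmp_path_factory):
    p = tmp_path_factory.mktemp("owl") / "onto.ttl"
    p.write_text(OWL_TTL)
    return p


class TestReadOwl:
    def test_restriction_mode_matches_hand_enumerated_axioms(self, owl_path):
        # Oracle: walk each class's own subclass/equivalence expressions by hand.
        expected = {
            f"{NS}A": {f"{NS}p1"},
            f"{NS}B": {f"{NS}p2", f"{NS}p3"},
            f"{NS}C": {f"{NS}p4", f"{NS}p1"},
            f"{NS}E": set(),  # datatype-property restrictions are not lateral rels
        }
        r = read_owl(owl_path, mode="restriction")
        for cid, rels in expected.items():
            assert r.concepts[cid].explicit_rels == rels, cid

    def test_named_superclasses_become_parents_rest_attach_to_root(self, owl_path):
        r = read_owl(owl_path)
        assert r.concepts[f"{NS}B"].parent_ids == {f"{NS}A"}
        assert r.concepts[f"{NS}A"].parent_ids == {VIRTUAL_ROOT}

    def test_deprecated_class_excluded(self, owl_path):
        r = read_owl(owl_path)
        assert f"{NS}D" not in r and r.n_deprecated_dropped == 1

    def test_domain_mode_is_superset_of_restriction_mode(self, owl_path):
        restr = read_owl(owl_path, mode="restriction")
        union = read_owl(owl_path, mode="domain_union_restriction")
        for cid in restr.concepts:
            assert restr.concepts[cid].explicit_rels <= union.concepts[cid].explicit_rels
        assert f"{NS}p5" in union.concepts[f"{NS}B"].explicit_rels

    def test_single_class_file_yields_two_concepts(self, tmp_path):
        p = tmp_path / "one.ttl"
        p.write_text(
            "@prefix : <http://x.org/> . "
            "@prefix owl: <http://www.w3.org/2002/07/owl#> . "
            ":Only a owl:Class ."
        )
        r = read_owl(p)
        assert len(r) == 2
        assert r.concepts["http://x.org/Only"].parent_ids == {VIRTUAL_ROOT}
        assert r.concepts["http://x.org/Only"].explicit_rels == frozenset()

    def test_unparseable_file_is_format_error(self, tmp_path):
        p = tmp_path / "junk.ttl"
        p.write_text("this is not turtle {{{{")
        with pytest.raises(FormatError):
            read_owl(p)

    def test_cyclic_subclass_axioms_rejected(self, tmp_path):
        p = tmp_path / "cycle.ttl"
        p.write_text(
            "@prefix : <http://x.org/> . "
            "@prefix owl: <http://www.w3.org/2002/07/owl#> . "
            "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> . "
            ":X a owl:Class ; rdfs:subClassOf :Y . :Y a owl:Class ; rdfs:subClassOf :X ."
        )
        with pytest.raises(CycleError):
            read_owl(p)
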