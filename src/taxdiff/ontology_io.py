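"""Reading and writing ontology releases.

Two input routes exist: OWL files (RDF/XML, Turtle, N-Triples via rdflib) and
a plain concept-table TSV.  The TSV dialect is UTF-8, LF line endings, a
``#version=`` comment line, then a header ``id/label/parents/rels/deprecated``
with pipe-separated multi-valued cells; it round-trips losslessly and is the
format the fixture and simulation modules emit.

For OWL input, lateral relationship types are extracted in one of two modes:

``restriction``
    Object-property IRIs collected from each class's own ``subClassOf`` /
    ``equivalentClass`` restrictions, recursing through intersections, unions,
    complements and nested ``someValuesFrom`` / ``allValuesFrom`` /
    cardinality expressions.
``domain_union_restriction``
    Additionally, a property whose declared ``rdfs:domain`` is a named class
    contributes itself to that class (and thereby, through inheritance, to all
    its descendants).
"""
from __future__ import annotations

import csv
import logging
from pathlib import Path

import rdflib
from rdflib import OWL, RDF, RDFS, BNode, URIRef

from .errors import DuplicateIdError, FormatError, ReferentialIntegrityError
from .model import VIRTUAL_ROOT, Concept, OntologyRelease

logger = logging.getLogger(__name__)

_TABLE_COLUMNS = ["id", "label", "parents", "rels", "deprecated"]

PARSING_MODES = ("restriction", "domain_union_restriction")


def read_concept_table(path: str | Path) -> OntologyRelease:
    """Read a release from the concept-table TSV format."""
    path = Path(path)
    version = path.stem
    concepts: dict[str, Concept] = {}
    n_deprecated = 0
    with path.open(encoding="utf-8", newline="") as fh:
        first = fh.readline()
        if first.startswith("#version="):
            version = first[len("#version=") :].strip()
        else:
            fh.seek(0)
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _TABLE_COLUMNS:
            raise FormatError(
                f"{path}: expected header {_TABLE_COLUMNS}, got {reader.fieldnames}"
            )
        for row in reader:
            cid = row["id"]
            if cid in concepts:
                raise DuplicateIdError(f"{path}: duplicate concept id {cid!r}")
            deprecated = row["deprecated"].strip().lower() in {"true", "1", "yes"}
            if deprecated:
                n_deprecated += 1
                continue
            parents = frozenset(p for p in row["parents"].split("|") if p)
            rels = frozenset(r for r in row["rels"].split("|") if r)
            if cid == VIRTUAL_ROOT:
                parents = frozenset()
                rels = frozenset()
            concepts[cid] = Concept(cid, row["label"] or cid, parents, rels)
    if n_deprecated:
        logger.info("%s: dropped %d deprecated concept(s)", path, n_deprecated)
    missing = {
        p for c in concepts.values() for p in c.parent_ids
    } - set(concepts) - {VIRTUAL_ROOT}
    if missing:
        raise ReferentialIntegrityError(missing)
    release = OntologyRelease(version, concepts)
    release.n_deprecated_dropped = n_deprecated
    return release


def write_concept_table(release: OntologyRelease, path: str | Path) -> None:
    """Write a release as a concept table; rows sorted by id for determinism."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#version={release.version_id}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for cid in sorted(release.concepts):
            c = release.concepts[cid]
            writer.writerow(
                [
                    c.id,
                    c.label,
                    "|".join(sorted(c.parent_ids)),
                    "|".join(sorted(c.explicit_rels)),
                    "false",
                ]
            )


def _expression_properties(graph: rdflib.Graph, node, acc: set[str], seen: set) -> None:
    """Collect object-property IRIs from a class expression, recursively."""
    if node in seen or not isinstance(node, BNode):
        return
    seen.add(node)
    prop = graph.value(node, OWL.onProperty)
    if isinstance(prop, URIRef):
        # Datatype properties restrict literals, not lateral relationships.
        if (prop, RDF.type, OWL.DatatypeProperty) not in graph:
            acc.add(str(prop))
    for pred in (
        OWL.someValuesFrom,
        OWL.allValuesFrom,
        OWL.hasValue,
        OWL.onClass,
        OWL.complementOf,
    ):
        _expression_properties(graph, graph.value(node, pred), acc, seen)
    for pred in (OWL.intersectionOf, OWL.unionOf, OWL.oneOf):
        lst = graph.value(node, pred)
        if lst is not None:
            for item in graph.items(lst):
                _expression_properties(graph, item, acc, seen)


def read_owl(
    path: str | Path, mode: str = "restriction", merge_imports: bool = False
) -> OntologyRelease:
    """Read an OWL file into a release.

    Only the given file's triples are parsed unless ``merge_imports`` is set
    (BioPortal distributions are typically already merged; silently resolving
    imports would change concept counts).
    """
    if mode not in PARSING_MODES:
        raise ValueError(f"mode must be one of {PARSING_MODES}, got {mode!r}")
    path = Path(path)
    graph = rdflib.Graph()
    fmt = {
        ".ttl": "turtle",
        ".nt": "nt",
        ".owl": "xml",
        ".rdf": "xml",
        ".xml": "xml",
    }.get(path.suffix.lower())
    try:
        graph.parse(path, format=fmt)
    except Exception as exc:  # rdflib raises assorted parser exceptions
        raise FormatError(f"{path}: not parseable as RDF/OWL ({exc})") from exc
    if merge_imports:
        for _, _, imported in graph.triples((None, OWL.imports, None)):
            try:
                graph.parse(imported)
            except Exception as exc:
                raise FormatError(f"cannot resolve import {imported}: {exc}") from exc

    classes = {s for s in graph.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)}

    def local(iri: URIRef) -> str:
        text = str(iri)
        for sep in ("#", "/"):
            if sep in text:
                text = text.rsplit(sep, 1)[1]
        return text or str(iri)

    concepts: dict[str, Concept] = {}
    for cls in sorted(classes):
        cid = str(cls)
        label = graph.value(cls, RDFS.label)
        deprecated = any(
            str(v).lower() == "true" for v in graph.objects(cls, OWL.deprecated)
        )
        parents = frozenset(
            str(o)
            for o in graph.objects(cls, RDFS.subClassOf)
            if isinstance(o, URIRef) and o in classes
        )
        rels: set[str] = set()
        seen: set = set()
        for pred in (RDFS.subClassOf, OWL.equivalentClass):
            for expr in graph.objects(cls, pred):
                _expression_properties(graph, expr, rels, seen)
        concepts[cid] = Concept(
            cid, str(label) if label else local(cls), parents, frozenset(rels), deprecated
        )

    if mode == "domain_union_restriction":
        for prop in graph.subjects(RDF.type, OWL.ObjectProperty):
            if not isinstance(prop, URIRef):
                continue
            for domain in graph.objects(prop, RDFS.domain):
                if isinstance(domain, URIRef) and str(domain) in concepts:
                    c = concepts[str(domain)]
                    concepts[str(domain)] = Concept(
                        c.id,
                        c.label,
                        c.parent_ids,
                        c.explicit_rels | {str(prop)},
                        c.deprecated,
                    )

    release = OntologyRelease(path.stem, concepts)
    if release.n_deprecated_dropped:
        logger.info(
            "%s: dropped %d deprecated class(es)", path, release.n_deprecated_dropped
        )
    return release
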