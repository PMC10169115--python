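"""Area taxonomy and partial-area taxonomy derivation.

Concepts with the same *effective* set of lateral relationship types (explicit
plus inherited along is-a) form an **area**.  Concepts with no parent in their
own area are the **roots** of the area, and each root seeds one
**partial-area**: the root plus all its descendants reachable inside the area.
Roots' is-a links induce hierarchical *child-of* edges between partial-areas
and between areas, yielding the partial-area taxonomy (PAT) — the input to
weighted aggregation (:mod:`taxdiff.wat`).
"""
from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field

import networkx as nx

from .model import OntologyRelease

RelSet = frozenset[str]


@dataclass(frozen=True)
class Area:
    """A maximal group of concepts sharing one effective relationship set."""

    rel_set: RelSet
    introduced_rels: RelSet
    concept_ids: frozenset[str]
    root_ids: frozenset[str]

    @property
    def color_rank(self) -> int:
        """Number of relationship types, used for color coding in layouts."""
        return len(self.rel_set)


@dataclass(frozen=True)
class PartialArea:
    """One root concept plus its within-area descendants."""

    root_id: str
    concept_ids: frozenset[str]
    area_rel_set: RelSet


@dataclass
class PartialAreaTaxonomy:
    """The partial-area taxonomy (PAT) of one release (or of a drill-down scope).

    ``hierarchy`` retains the underlying is-a DAG restricted to the taxonomy's
    scope so that partial-area weights (descendant counts) can be computed
    without going back to the release.  ``root_parea_id`` names the
    partial-area that acts as the taxonomy root (the virtual root for a full
    release; the major-subject root for a drill-down sub-taxonomy).
    """

    release_version: str
    root_parea_id: str
    areas: list[Area]
    pareas: dict[str, PartialArea]
    parea_child_of: frozenset[tuple[str, str]]
    area_child_of: frozenset[tuple[RelSet, RelSet]]
    hierarchy: nx.DiGraph = field(repr=False)
    labels: dict[str, str] = field(repr=False)
    depth: int = 1

    @property
    def concept_ids(self) -> frozenset[str]:
        return frozenset().union(*(a.concept_ids for a in self.areas))

    def area_of(self, rel_set: RelSet) -> Area:
        for a in self.areas:
            if a.rel_set == rel_set:
                return a
        raise KeyError(rel_set)


def effective_relationships(release: OntologyRelease) -> dict[str, RelSet]:
    """Effective lateral relationship set of every concept.

    ``eff(c) = explicit(c) ∪ ⋃ eff(parent)`` over all asserted parents; the
    virtual root maps to the empty set.
    """
    eff: dict[str, RelSet] = {}
    for cid in nx.topological_sort(release.hierarchy):
        c = release.concepts[cid]
        acc = set(c.explicit_rels)
        for p in c.parent_ids:
            acc |= eff[p]
        eff[cid] = frozenset(acc)
    return eff


def _derive(
    hierarchy: nx.DiGraph,
    eff: dict[str, RelSet],
    labels: dict[str, str],
    version: str,
    root_parea_id: str,
    depth: int = 1,
) -> PartialAreaTaxonomy:
    """Shared derivation core, also used on restricted drill-down hierarchies."""
    by_rels: dict[RelSet, set[str]] = defaultdict(set)
    for cid, rels in eff.items():
        by_rels[rels].add(cid)

    def parents(cid: str) -> list[str]:
        return list(hierarchy.predecessors(cid))

    roots_by_area: dict[RelSet, set[str]] = {}
    for rels, members in by_rels.items():
        roots_by_area[rels] = {
            c for c in members if not any(eff[p] == rels for p in parents(c))
        }

    # Partial-areas: root + descendants along within-area is-a paths.  A
    # concept descending from two roots of its area joins both partial-areas.
    pareas: dict[str, PartialArea] = {}
    for rels, roots in roots_by_area.items():
        members = by_rels[rels]
        for r in roots:
            seen = {r}
            queue = deque([r])
            while queue:
                cur = queue.popleft()
                for child in hierarchy.successors(cur):
                    if child in members and child not in seen:
                        seen.add(child)
                        queue.append(child)
            pareas[r] = PartialArea(r, frozenset(seen), rels)

    concept_pareas: dict[str, set[str]] = defaultdict(set)
    for r, pa in pareas.items():
        for cid in pa.concept_ids:
            concept_pareas[cid].add(r)

    parea_child_of = set()
    area_child_of = set()
    for rels, roots in roots_by_area.items():
        for r in roots:
            for p in parents(r):
                area_child_of.add((rels, eff[p]))
                for parent_parea in concept_pareas[p]:
                    parea_child_of.add((r, parent_parea))

    area_parents: dict[RelSet, set[RelSet]] = defaultdict(set)
    for child, parent in area_child_of:
        area_parents[child].add(parent)

    areas = []
    for rels, members in by_rels.items():
        inherited = frozenset().union(*area_parents[rels]) if area_parents[rels] else frozenset()
        areas.append(
            Area(
                rel_set=rels,
                introduced_rels=rels - inherited,
                concept_ids=frozenset(members),
                root_ids=frozenset(roots_by_area[rels]),
            )
        )
    areas.sort(key=lambda a: (a.color_rank, tuple(sorted(a.rel_set))))

    return PartialAreaTaxonomy(
        release_version=version,
        root_parea_id=root_parea_id,
        areas=areas,
        pareas=pareas,
        parea_child_of=frozenset(parea_child_of),
        area_child_of=frozenset(area_child_of),
        hierarchy=hierarchy,
        labels=labels,
        depth=depth,
    )


def derive_taxonomy(release: OntologyRelease) -> PartialAreaTaxonomy:
    """Derive the partial-area taxonomy of a release.

    Concepts are grouped into areas by identical effective relationship sets;
    each area is split into partial-areas seeded by its roots; child-of edges
    at both levels follow the is-a links emanating from roots.
    """
    eff = effective_relationships(release)
    labels = {cid: c.label for cid, c in release.concepts.items()}
    return _derive(release.hierarchy, eff, labels, release.version_id, release.root_id)


def taxonomy_to_json(taxonomy: PartialAreaTaxonomy) -> str:
    """Serialize a PAT (areas, partial-areas, child-of edges) as JSON."""
    import json

    doc = {
        "type": "pat",
        "release_version": taxonomy.release_version,
        "root_parea_id": taxonomy.root_parea_id,
        "depth": taxonomy.depth,
        "areas": [
            {
                "rel_set": sorted(a.rel_set),
                "introduced_rels": sorted(a.introduced_rels),
                "concept_ids": sorted(a.concept_ids),
                "root_ids": sorted(a.root_ids),
                "color_rank": a.color_rank,
            }
            for a in taxonomy.areas
        ],
        "pareas": {
            r: {
                "concept_ids": sorted(p.concept_ids),
                "area_rel_set": sorted(p.area_rel_set),
            }
            for r, p in sorted(taxonomy.pareas.items())
        },
        "parea_child_of": sorted(map(list, taxonomy.parea_child_of)),
        "area_child_of": sorted(
            [sorted(c), sorted(p)] for c, p in taxonomy.area_child_of
        ),
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def introduced_relationships(area: Area, taxonomy: PartialAreaTaxonomy) -> RelSet:
    """Relationship types newly introduced in ``area``.

    Equal to the area's relationship set minus everything carried by the areas
    it is child-of; already stored on ``area.introduced_rels`` at derivation.
    """
    inherited: set[str] = set()
    for child, parent in taxonomy.area_child_of:
        if child == area.rel_set:
            inherited |= parent
    return area.rel_set - frozenset(inherited)
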