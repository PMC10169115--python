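"""Diff Weighted Aggregate Taxonomy (DWAT) between two releases.

Nodes of the two WATs are matched by root concept identifier and classified
as *introduced* (only in the newer WAT), *removed* (only in the older),
*modified* (both, different summarized concept sets) or *unmodified*
(identical sets).  Each node carries a concept-level change tally, child-of
edges are classified introduced/removed/unmodified, and areas report global
concept/relationship deltas — suppressed when everything in the area is
introduced-only or removed-only, since the node tallies already say it all.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Literal, Optional

from .errors import NodeLookupError
from .model import OntologyRelease
from .taxonomy import RelSet, derive_taxonomy
from .wat import WAT, build_wat, find_smallest_b, format_node_label

NodeStatus = Literal["introduced", "removed", "modified", "unmodified"]
EdgeStatus = Literal["introduced", "removed", "unmodified"]


@dataclass(frozen=True)
class ChangeTally:
    """Concept-level changes of one diff node.

    ``new``: concepts in the node's newer set absent from the old release;
    ``deleted``: in the older set, absent from the new release;
    ``modified_in``/``modified_out``: concepts existing in both releases that
    entered/left the node's summarized set; ``aggregated_parea_delta``: change
    in the number of absorbed partial-areas (reported on modified nodes).
    The balance ``n2 - n1 = new - deleted + modified_in - modified_out`` holds
    by construction.
    """

    new: int = 0
    deleted: int = 0
    modified_in: int = 0
    modified_out: int = 0
    aggregated_parea_delta: int = 0

    @property
    def is_zero(self) -> bool:
        return not (
            self.new
            or self.deleted
            or self.modified_in
            or self.modified_out
            or self.aggregated_parea_delta
        )


@dataclass(frozen=True)
class DiffNode:
    root_id: str
    label: str
    status: NodeStatus
    tally: ChangeTally
    label_source: Literal["T1", "T2"]
    shape_source: Literal["T1", "T2"]
    is_aggregate: bool
    display_label: str
    n_old: Optional[int] = None
    n_new: Optional[int] = None


@dataclass(frozen=True)
class DiffArea:
    """Area-level (global) change summary for one group of diff nodes."""

    base_rel_set: RelSet
    rel_delta: int
    concept_delta: int
    suppressed: bool
    member_root_ids: frozenset[str]


@dataclass(frozen=True)
class DWAT:
    old_version: str
    new_version: str
    b_old: int
    b_new: int
    root_id: str
    nodes: dict[str, DiffNode]
    edges: frozenset[tuple[str, str, EdgeStatus]]
    areas: tuple[DiffArea, ...]


def classify_nodes(T1: WAT, T2: WAT) -> dict[str, NodeStatus]:
    """Status of every major subject, matched across releases by root id."""
    statuses: dict[str, NodeStatus] = {}
    for r in set(T1.nodes) | set(T2.nodes):
        if r not in T1.nodes:
            statuses[r] = "introduced"
        elif r not in T2.nodes:
            statuses[r] = "removed"
        elif T1.nodes[r].concept_ids == T2.nodes[r].concept_ids:
            statuses[r] = "unmodified"
        else:
            statuses[r] = "modified"
    return statuses


def account_node_changes(
    root_id: str,
    T1: WAT,
    T2: WAT,
    O1: OntologyRelease,
    O2: OntologyRelease,
) -> ChangeTally:
    """Concept-level change tally for one diff node.

    The summarized sets are the post-aggregation sets of the matched WAT
    nodes; a side where the root is not a major subject contributes the empty
    set.
    """
    n1 = T1.nodes.get(root_id)
    n2 = T2.nodes.get(root_id)
    if n1 is None and n2 is None:
        raise NodeLookupError(f"{root_id!r} is a node of neither WAT")
    s1 = n1.concept_ids if n1 else frozenset()
    s2 = n2.concept_ids if n2 else frozenset()
    o1 = O1.concept_ids
    o2 = O2.concept_ids
    return ChangeTally(
        new=len(s2 - o1),
        deleted=len(s1 - o2),
        modified_in=len((s2 & o1) - s1),
        modified_out=len((s1 & o2) - s2),
        aggregated_parea_delta=(n2.aggregated_count if n2 else 0)
        - (n1.aggregated_count if n1 else 0),
    )


def diff_child_of(T1: WAT, T2: WAT) -> frozenset[tuple[str, str, EdgeStatus]]:
    """Classify child-of edges; an edge either exists or not, so there is no
    'modified' edge status."""
    out: set[tuple[str, str, EdgeStatus]] = set()
    for edge in T1.child_of | T2.child_of:
        if edge not in T1.child_of:
            status: EdgeStatus = "introduced"
        elif edge not in T2.child_of:
            status = "removed"
        else:
            status = "unmodified"
        out.add((*edge, status))
    return frozenset(out)


def diff_areas(
    statuses: dict[str, NodeStatus], T1: WAT, T2: WAT
) -> tuple[DiffArea, ...]:
    """Area-level deltas.

    Nodes surviving from the older release group by their old-release area,
    introduced nodes by their new-release area.  Per group, the concept delta
    counts distinct summarized concepts (newer minus older) and the
    relationship delta compares matched nodes' area relationship-set sizes.
    Groups whose members are all introduced (or all removed) are suppressed.
    """
    groups: dict[RelSet, list[str]] = defaultdict(list)
    for r, status in statuses.items():
        key = T2.nodes[r].area_rel_set if status == "introduced" else T1.nodes[r].area_rel_set
        groups[key].append(r)

    areas = []
    for rel_set in sorted(groups, key=lambda s: (len(s), tuple(sorted(s)))):
        members = groups[rel_set]
        old_concepts: set[str] = set()
        new_concepts: set[str] = set()
        rel_delta = 0
        for r in members:
            if r in T1.nodes:
                old_concepts |= T1.nodes[r].concept_ids
            if r in T2.nodes:
                new_concepts |= T2.nodes[r].concept_ids
            if r in T1.nodes and r in T2.nodes:
                rel_delta = len(T2.nodes[r].area_rel_set) - len(T1.nodes[r].area_rel_set)
        member_statuses = {statuses[r] for r in members}
        suppressed = member_statuses == {"introduced"} or member_statuses == {"removed"}
        areas.append(
            DiffArea(
                base_rel_set=rel_set,
                rel_delta=rel_delta,
                concept_delta=len(new_concepts) - len(old_concepts),
                suppressed=suppressed,
                member_root_ids=frozenset(members),
            )
        )
    return tuple(areas)


def diff_wats(T1: WAT, T2: WAT, O1: OntologyRelease, O2: OntologyRelease) -> DWAT:
    """Derive the DWAT of two already-built WATs."""
    statuses = classify_nodes(T1, T2)
    nodes: dict[str, DiffNode] = {}
    for r, status in statuses.items():
        tally = account_node_changes(r, T1, T2, O1, O2)
        if status == "unmodified":
            tally = ChangeTally()
        elif status != "modified":
            # The absorbed-partial-area delta is only meaningful when the node
            # survives on both sides.
            tally = ChangeTally(
                tally.new, tally.deleted, tally.modified_in, tally.modified_out, 0
            )
        source: Literal["T1", "T2"] = "T2" if status == "introduced" else "T1"
        src_node = (T2 if source == "T2" else T1).nodes[r]
        nodes[r] = DiffNode(
            root_id=r,
            label=src_node.label,
            status=status,
            tally=tally,
            label_source=source,
            shape_source=source,
            is_aggregate=src_node.is_aggregate,
            display_label=format_node_label(src_node),
            n_old=T1.nodes[r].concepts_after if r in T1.nodes else None,
            n_new=T2.nodes[r].concepts_after if r in T2.nodes else None,
        )
    return DWAT(
        old_version=T1.source_version,
        new_version=T2.source_version,
        b_old=T1.b,
        b_new=T2.b,
        root_id=T1.root_id if T1.nodes else T2.root_id,
        nodes=nodes,
        edges=diff_child_of(T1, T2),
        areas=diff_areas(statuses, T1, T2),
    )


def build_dwat(
    O1: OntologyRelease,
    O2: OntologyRelease,
    b_old: int | None = None,
    b_new: int | None = None,
    max_nodes: int | None = None,
) -> DWAT:
    """End-to-end DWAT derivation from two releases.

    When ``max_nodes`` is given, each release's ``b`` is chosen as the
    smallest value keeping its WAT at or under that many nodes and the
    explicit ``b`` arguments are ignored.
    """
    tax1 = derive_taxonomy(O1)
    tax2 = derive_taxonomy(O2)
    if max_nodes is not None:
        b_old = find_smallest_b(tax1, max_nodes)
        b_new = find_smallest_b(tax2, max_nodes)
    if b_old is None or b_new is None:
        raise ValueError("either both b values or max_nodes must be given")
    T1 = build_wat(tax1, b_old)
    T2 = build_wat(tax2, b_new)
    return diff_wats(T1, T2, O1, O2)


def _plural(n: int, noun: str) -> str:
    return noun if n == 1 else noun + "s"


def node_annotation_lines(node: DiffNode) -> tuple[str, ...]:
    """Canonical change annotations printed under a diff node's label."""
    t = node.tally
    lines = []
    if t.new:
        lines.append(f"+{t.new} New {_plural(t.new, 'Concept')}")
    if t.modified_out:
        lines.append(f"-{t.modified_out} {_plural(t.modified_out, 'Concept')} Modified")
    if t.modified_in:
        lines.append(f"+{t.modified_in} {_plural(t.modified_in, 'Concept')} Modified")
    if t.deleted:
        lines.append(f"-{t.deleted} {_plural(t.deleted, 'Concept')} Deleted")
    if t.aggregated_parea_delta and node.status == "modified":
        d = t.aggregated_parea_delta
        sign = "+" if d > 0 else "-"
        lines.append(f"{sign}{abs(d)} Aggregated {_plural(abs(d), 'P-area')}")
    return tuple(lines)


def area_annotation_lines(area: DiffArea) -> tuple[str, ...]:
    """Bold area-level annotations; empty for suppressed areas."""
    if area.suppressed:
        return ()
    lines = []
    if area.rel_delta:
        sign = "+" if area.rel_delta > 0 else "-"
        lines.append(f"{sign}{abs(area.rel_delta)} {_plural(abs(area.rel_delta), 'Rel')}")
    if area.concept_delta:
        sign = "+" if area.concept_delta > 0 else "-"
        lines.append(
            f"{sign}{abs(area.concept_delta)} {_plural(abs(area.concept_delta), 'Concept')}"
        )
    return tuple(lines)
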