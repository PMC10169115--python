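"""Weighted aggregate taxonomy (WAT) construction.

The weight of a partial-area is the number of concepts that are its root or
descendants of its root in the whole hierarchy.  Under an integer threshold
``b``, partial-areas of weight >= b are *large* (major subjects) and become
WAT nodes; the rest are *small* and have their concepts absorbed into every
closest large ancestor along partial-area child-of paths.  Aggregate nodes are
labeled ``name (n){m}[o]``: ``n`` concepts summarized after aggregation, ``m``
small partial-areas absorbed, ``o`` concepts before aggregation.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .errors import InfeasibleTargetError, ParameterError
from .taxonomy import PartialAreaTaxonomy, RelSet


@dataclass(frozen=True)
class WATNode:
    """One major-subject node of a WAT."""

    root_id: str
    label: str
    area_rel_set: RelSet
    area_intro_rels: RelSet
    concept_ids: frozenset[str]
    original_count: int
    aggregated_count: int
    weight: int
    absorbed_roots: frozenset[str] = field(default_factory=frozenset)

    @property
    def concepts_after(self) -> int:
        """n — distinct concepts summarized after aggregation."""
        return len(self.concept_ids)

    @property
    def is_aggregate(self) -> bool:
        return self.aggregated_count > 0


@dataclass(frozen=True)
class WAT:
    """Weighted aggregate taxonomy of one release under threshold ``b``."""

    b: int
    source_version: str
    root_id: str
    nodes: dict[str, WATNode]
    child_of: frozenset[tuple[str, str]]
    depth: int = 1

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, WAT)
            and self.b == other.b
            and self.source_version == other.source_version
            and self.root_id == other.root_id
            and self.nodes == other.nodes
            and self.child_of == other.child_of
        )


def compute_weights(taxonomy: PartialAreaTaxonomy) -> dict[str, int]:
    """Weight of every partial-area: root plus all its descendants, each
    distinct concept counted once under multiple inheritance."""
    return {
        r: 1 + len(nx.descendants(taxonomy.hierarchy, r)) for r in taxonomy.pareas
    }


def build_wat(
    taxonomy: PartialAreaTaxonomy, b: int, single_ancestor: bool = False
) -> WAT:
    """Aggregate small partial-areas into their closest large ancestors.

    Parameters
    ----------
    taxonomy:
        The PAT to summarize.
    b:
        Integer weight threshold (>= 1).
    single_ancestor:
        When a small partial-area has several closest large ancestors (diamond
        child-of patterns), its concepts are added to all of them by default;
        with ``single_ancestor=True`` only the lexicographically smallest root
        receives them, keeping summarized counts disjoint.
    """
    if b < 1:
        raise ParameterError(f"threshold b must be >= 1, got {b}")
    weights = compute_weights(taxonomy)
    root = taxonomy.root_parea_id
    large = {r for r, w in weights.items() if w >= b} | {root}

    parents_of: dict[str, set[str]] = defaultdict(set)
    for child, parent in taxonomy.parea_child_of:
        parents_of[child].add(parent)

    # Closest large ancestor(s) of a small partial-area: first large node on
    # each upward child-of path.
    targets_memo: dict[str, frozenset[str]] = {}

    def targets(small: str) -> frozenset[str]:
        if small in targets_memo:
            return targets_memo[small]
        acc: set[str] = set()
        for p in parents_of[small]:
            if p in large:
                acc.add(p)
            else:
                acc |= targets(p)
        result = frozenset(acc)
        targets_memo[small] = result
        return result

    absorbed: dict[str, set[str]] = defaultdict(set)
    for small in set(taxonomy.pareas) - large:
        tg = sorted(targets(small))
        if single_ancestor and tg:
            tg = tg[:1]
        for t in tg:
            absorbed[t].add(small)

    nodes: dict[str, WATNode] = {}
    for r in large:
        pa = taxonomy.pareas[r]
        area = taxonomy.area_of(pa.area_rel_set)
        concept_ids = set(pa.concept_ids)
        for s in absorbed[r]:
            concept_ids |= taxonomy.pareas[s].concept_ids
        nodes[r] = WATNode(
            root_id=r,
            label=taxonomy.labels[r],
            area_rel_set=pa.area_rel_set,
            area_intro_rels=area.introduced_rels,
            concept_ids=frozenset(concept_ids),
            original_count=len(pa.concept_ids),
            aggregated_count=len(absorbed[r]),
            weight=weights[r],
            absorbed_roots=frozenset(absorbed[r]),
        )

    # Child-of between WAT nodes: a PAT child-of path whose interior nodes are
    # all small contracts to one edge.
    edges: set[tuple[str, str]] = set()
    for x in large:
        seen: set[str] = set()
        stack = list(parents_of[x])
        while stack:
            p = stack.pop()
            if p in seen:
                continue
            seen.add(p)
            if p in large:
                if p != x:
                    edges.add((x, p))
            else:
                stack.extend(parents_of[p])

    return WAT(
        b=b,
        source_version=taxonomy.release_version,
        root_id=root,
        nodes=nodes,
        child_of=frozenset(edges),
        depth=taxonomy.depth,
    )


def find_smallest_b(taxonomy: PartialAreaTaxonomy, max_nodes: int) -> int:
    """Smallest ``b`` whose WAT has at most ``max_nodes`` nodes.

    The node count is non-increasing in ``b`` (large partial-areas only drop
    out as the threshold grows), so the answer can be read off the sorted
    weight sequence without rebuilding WATs.
    """
    if max_nodes < 1:
        raise InfeasibleTargetError(
            f"max_nodes must be >= 1 (the root node is always shown), got {max_nodes}"
        )
    weights = compute_weights(taxonomy)
    if len(weights) <= max_nodes:
        return 1
    ws = sorted(weights.values(), reverse=True)
    return ws[max_nodes] + 1


def format_node_label(node: WATNode) -> str:
    """Canonical display label: ``name (n)`` or ``name (n){m}[o]``."""
    base = f"{node.label} ({node.concepts_after})"
    if node.is_aggregate:
        base += f"{{{node.aggregated_count}}}[{node.original_count}]"
    return base
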