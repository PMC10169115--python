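"""Core release model: concepts, their is-a hierarchy and lateral relationship types.

A release is a rooted DAG of concepts.  Every concept may carry *explicit*
lateral (non-hierarchical) relationship types, introduced directly on it;
further types are inherited along is-a and become visible only through
:func:`taxdiff.taxonomy.effective_relationships`.  A virtual root named
``Thing`` closes the hierarchy: concepts asserted without a named parent are
attached to it, and it carries no lateral relationship types itself.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping

import networkx as nx

from .errors import CycleError, ReferentialIntegrityError

#: Identifier and label of the virtual root closing every release hierarchy.
VIRTUAL_ROOT = "Thing"


@dataclass(frozen=True)
class Concept:
    """One named concept of a release.

    Parameters
    ----------
    id:
        Opaque identifier (IRI or token), unique within a release.
    label:
        Human-readable name, used in taxonomy node labels.
    parent_ids:
        Asserted is-a parents (named concepts only).
    explicit_rels:
        Lateral relationship types introduced directly on this concept.
    deprecated:
        Obsolete flag; deprecated concepts are dropped before any taxonomy
        derivation.
    """

    id: str
    label: str
    parent_ids: frozenset[str] = field(default_factory=frozenset)
    explicit_rels: frozenset[str] = field(default_factory=frozenset)
    deprecated: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent_ids", frozenset(self.parent_ids))
        object.__setattr__(self, "explicit_rels", frozenset(self.explicit_rels))
        if self.id in self.parent_ids:
            raise ValueError(f"concept {self.id!r} lists itself as a parent")


class OntologyRelease:
    """One release of an ontology: a validated, rooted, acyclic concept DAG.

    Construction normalizes the input: deprecated concepts are dropped (the
    count is kept on :attr:`n_deprecated_dropped`), a virtual root is added if
    absent, and parentless concepts become children of the root.  Validation
    then guarantees the invariants every downstream module relies on: all
    parents exist, the is-a graph is acyclic, and the root carries no parents
    and no lateral relationship types.
    """

    def __init__(
        self,
        version_id: str,
        concepts: Iterable[Concept] | Mapping[str, Concept],
        root_id: str = VIRTUAL_ROOT,
    ):
        self.version_id = version_id
        self.root_id = root_id
        if isinstance(concepts, Mapping):
            concepts = concepts.values()
        raw = list(concepts)
        deprecated_ids = {c.id for c in raw if c.deprecated}
        self.n_deprecated_dropped = len(deprecated_ids)
        kept = {c.id: c for c in raw if not c.deprecated}
        if root_id not in kept:
            kept[root_id] = Concept(root_id, root_id)
        root = kept[root_id]
        if root.parent_ids or root.explicit_rels:
            raise ValueError(
                f"virtual root {root_id!r} must have no parents and no relationship types"
            )
        # Attach parentless non-root concepts to the virtual root.
        normalized: dict[str, Concept] = {}
        for cid, c in kept.items():
            # Links to dropped (deprecated) parents are pruned before validation.
            parents = c.parent_ids - deprecated_ids
            if cid != root_id and not parents:
                c = Concept(c.id, c.label, frozenset({root_id}), c.explicit_rels)
            elif parents != c.parent_ids:
                c = Concept(c.id, c.label, parents, c.explicit_rels)
            normalized[cid] = c
        missing = {
            p for c in normalized.values() for p in c.parent_ids if p not in normalized
        }
        if missing:
            raise ReferentialIntegrityError(missing)
        self.concepts: dict[str, Concept] = dict(sorted(normalized.items()))
        if not nx.is_directed_acyclic_graph(self.hierarchy):
            cycle = nx.find_cycle(self.hierarchy)
            raise CycleError(cycle[0][0])

    @cached_property
    def hierarchy(self) -> nx.DiGraph:
        """Is-a hierarchy as a DiGraph with edges parent -> child."""
        g = nx.DiGraph()
        g.add_nodes_from(self.concepts)
        for c in self.concepts.values():
            for p in c.parent_ids:
                g.add_edge(p, c.id)
        return g

    @property
    def concept_ids(self) -> frozenset[str]:
        return frozenset(self.concepts)

    def parents(self, cid: str) -> frozenset[str]:
        return self.concepts[cid].parent_ids

    def children(self, cid: str) -> set[str]:
        return set(self.hierarchy.successors(cid))

    def descendants(self, cid: str) -> set[str]:
        """Strict descendants of ``cid`` under is-a (each counted once)."""
        return nx.descendants(self.hierarchy, cid)

    def label(self, cid: str) -> str:
        return self.concepts[cid].label

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, cid: str) -> bool:
        return cid in self.concepts

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, OntologyRelease)
            and self.version_id == other.version_id
            and self.root_id == other.root_id
            and self.concepts == other.concepts
        )

    def __repr__(self) -> str:
        return f"OntologyRelease({self.version_id!r}, {len(self)} concepts)"
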