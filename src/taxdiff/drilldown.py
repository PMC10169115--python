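"""Drill-down: expand a major-subject node into its secondary-subject taxonomy.

A WAT node hides the small partial-areas it absorbed.  Drilling down restores
them: the node's own partial-area plus everything it absorbed form a
sub-taxonomy rooted at the major subject, which can itself be aggregated (a
secondary WAT) and diffed across releases (a secondary DWAT).  The same
operations recurse to tertiary and deeper layers.
"""
from __future__ import annotations

from .dwat import DWAT, diff_wats
from .errors import NodeLookupError
from .model import OntologyRelease
from .taxonomy import PartialAreaTaxonomy, _derive, derive_taxonomy
from .wat import WAT, build_wat


def default_secondary_b(b_major: int) -> int:
    """Default drill-down threshold: one fifth of the major-subject threshold,
    floored at 1 (the scale ratio used for the top level vs drill-down views)."""
    return max(1, b_major // 5)


def subtaxonomy(
    taxonomy: PartialAreaTaxonomy, wat: WAT, root_id: str
) -> PartialAreaTaxonomy:
    """Restrict the PAT to a WAT node's own partial-area plus everything it
    absorbed; the major-subject root becomes the sub-taxonomy root."""
    node = wat.nodes.get(root_id)
    if node is None:
        raise NodeLookupError(f"{root_id!r} is not a node of this WAT")
    members = {root_id} | set(node.absorbed_roots)
    scope = set().union(*(taxonomy.pareas[r].concept_ids for r in members))
    hierarchy = taxonomy.hierarchy.subgraph(scope).copy()
    # Effective relationship sets are inherited from the full taxonomy: each
    # scope concept keeps the rel set of the partial-area(s) it belongs to.
    eff_map: dict[str, frozenset[str]] = {}
    for r in members:
        pa = taxonomy.pareas[r]
        for cid in pa.concept_ids:
            eff_map[cid] = pa.area_rel_set
    labels = {cid: taxonomy.labels[cid] for cid in scope}
    sub = _derive(
        hierarchy,
        eff_map,
        labels,
        taxonomy.release_version,
        root_parea_id=root_id,
        depth=taxonomy.depth + 1,
    )
    return sub


def secondary_wat(
    taxonomy: PartialAreaTaxonomy, wat: WAT, root_id: str, b2: int | None = None
) -> WAT:
    """Aggregate a major subject's sub-taxonomy with its own threshold."""
    if b2 is None:
        b2 = default_secondary_b(wat.b)
    return build_wat(subtaxonomy(taxonomy, wat, root_id), b2)


def _empty_wat(b: int, version: str, root_id: str, depth: int) -> WAT:
    return WAT(b=b, source_version=version, root_id=root_id, nodes={}, child_of=frozenset(), depth=depth)


def secondary_dwat(
    O1: OntologyRelease,
    O2: OntologyRelease,
    root_id: str,
    b_old: int,
    b_new: int,
    b2: int | None = None,
) -> DWAT:
    """DWAT between the two secondary-subject taxonomies of one major subject.

    If the major subject is a WAT node in only one release, the missing side
    is treated as an empty WAT, so every node on the present side classifies
    as introduced (or removed) accordingly.
    """
    if b2 is None:
        b2 = default_secondary_b(b_old)
    tax1 = derive_taxonomy(O1)
    tax2 = derive_taxonomy(O2)
    wat1 = build_wat(tax1, b_old)
    wat2 = build_wat(tax2, b_new)
    if root_id not in wat1.nodes and root_id not in wat2.nodes:
        raise NodeLookupError(f"{root_id!r} is a major subject in neither release")
    sub1 = (
        build_wat(subtaxonomy(tax1, wat1, root_id), b2)
        if root_id in wat1.nodes
        else _empty_wat(b2, O1.version_id, root_id, 2)
    )
    sub2 = (
        build_wat(subtaxonomy(tax2, wat2, root_id), b2)
        if root_id in wat2.nodes
        else _empty_wat(b2, O2.version_id, root_id, 2)
    )
    return diff_wats(sub1, sub2, O1, O2)
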