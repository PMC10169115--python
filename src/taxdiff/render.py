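"""Layered layout and export of WATs and DWATs as DOT and JSON.

Levels follow the child-of-based layout: a node's level is the length of its
longest child-of path to the root node, so every child-of edge points from a
strictly deeper level to a shallower one.  DOT output groups nodes into area
clusters, fills nodes by diff status (yellow/white/green/red for
modified/unmodified/introduced/removed), draws aggregate nodes with rounded
corners and colors edges green/red/black for introduced/removed/unmodified.
Output is deterministic: identical inputs yield identical bytes.
"""
from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass

from .dwat import (
    DWAT,
    ChangeTally,
    DiffArea,
    DiffNode,
    area_annotation_lines,
    node_annotation_lines,
)
from .errors import CycleError
from .wat import WAT, WATNode, format_node_label

NODE_FILL = {
    "introduced": "green",
    "removed": "red",
    "modified": "yellow",
    "unmodified": "white",
}
EDGE_COLOR = {"introduced": "green", "removed": "red", "unmodified": "black"}


@dataclass(frozen=True)
class LayoutAssignment:
    """Level per node plus the grouping of nodes into labeled area boxes."""

    levels: dict[str, int]
    area_boxes: tuple[tuple[str, tuple[str, ...]], ...]


def _edges_of(network: WAT | DWAT) -> set[tuple[str, str]]:
    if isinstance(network, WAT):
        return set(network.child_of)
    return {(c, p) for c, p, _ in network.edges}


def _pretty_rel(rel: str) -> str:
    for sep in ("#", "/"):
        if sep in rel:
            rel = rel.rsplit(sep, 1)[1]
    return rel


def assign_levels(network: WAT | DWAT) -> LayoutAssignment:
    """Longest child-of path length from every node to the root node."""
    edges = _edges_of(network)
    nodes = set(network.nodes)
    parents: dict[str, set[str]] = defaultdict(set)
    for child, parent in edges:
        parents[child].add(parent)

    levels: dict[str, int] = {}
    in_progress: set[str] = set()

    def level(n: str) -> int:
        if n in levels:
            return levels[n]
        if n in in_progress:
            raise CycleError(n)
        in_progress.add(n)
        if n == network.root_id or not parents[n]:
            result = 0 if n == network.root_id else 1
        else:
            result = max(level(p) + 1 for p in sorted(parents[n]))
        in_progress.discard(n)
        levels[n] = result
        return result

    for n in sorted(nodes):
        level(n)

    # Area boxes: group by area relationship set (DWAT groups come from its
    # DiffArea partition, keeping introduced nodes with their new-release area).
    boxes: list[tuple[str, tuple[str, ...]]] = []
    if isinstance(network, WAT):
        by_area: dict[frozenset, list[str]] = defaultdict(list)
        for r, node in network.nodes.items():
            by_area[node.area_rel_set].append(r)
        for rel_set in sorted(by_area, key=lambda s: (len(s), tuple(sorted(s)))):
            members = tuple(sorted(by_area[rel_set]))
            intro = network.nodes[members[0]].area_intro_rels
            label = ", ".join(sorted(_pretty_rel(r) for r in intro)) or "(no relationships)"
            boxes.append((label, members))
    else:
        for area in network.areas:
            label = ", ".join(sorted(_pretty_rel(r) for r in area.base_rel_set)) or "(no relationships)"
            for extra in area_annotation_lines(area):
                label += "\n" + extra
            boxes.append((label, tuple(sorted(area.member_root_ids))))
    return LayoutAssignment(levels=levels, area_boxes=tuple(boxes))


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def to_dot(network: WAT | DWAT, layout: LayoutAssignment | None = None) -> str:
    """Emit a deterministic Graphviz DOT document for a WAT or DWAT."""
    if layout is None:
        layout = assign_levels(network)
    lines = [
        "digraph taxonomy {",
        "  rankdir=BT;",
        '  node [shape=box, style=filled, fillcolor=white, fontname="Helvetica"];',
    ]
    for i, (label, members) in enumerate(layout.area_boxes):
        lines.append(f"  subgraph cluster_{i} {{")
        cluster_label = _dot_escape(label).replace("\n", r"\n")
        lines.append(f'    label="{cluster_label}";')
        for r in members:
            node = network.nodes[r]
            if isinstance(node, WATNode):
                text = format_node_label(node)
                fill = "white"
                rounded = node.is_aggregate
            else:
                text = node.display_label
                for ann in node_annotation_lines(node):
                    text += "\n" + ann
                fill = NODE_FILL[node.status]
                rounded = node.is_aggregate
            style = '"rounded,filled"' if rounded else "filled"
            text = _dot_escape(text).replace("\n", r"\n")
            lines.append(
                f'    "{_dot_escape(r)}" [label="{text}", style={style}, '
                f"fillcolor={fill}, level={layout.levels[r]}];"
            )
        lines.append("  }")
    if isinstance(network, WAT):
        for child, parent in sorted(network.child_of):
            lines.append(f'  "{_dot_escape(child)}" -> "{_dot_escape(parent)}";')
    else:
        for child, parent, status in sorted(network.edges):
            lines.append(
                f'  "{_dot_escape(child)}" -> "{_dot_escape(parent)}" '
                f"[color={EDGE_COLOR[status]}];"
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_json(network: WAT | DWAT) -> str:
    """Lossless, deterministic JSON export of a WAT or DWAT."""
    if isinstance(network, WAT):
        doc = {
            "type": "wat",
            "b": network.b,
            "source_version": network.source_version,
            "root_id": network.root_id,
            "depth": network.depth,
            "nodes": {
                r: {
                    "label": n.label,
                    "display_label": format_node_label(n),
                    "area_rel_set": sorted(n.area_rel_set),
                    "area_intro_rels": sorted(n.area_intro_rels),
                    "concept_ids": sorted(n.concept_ids),
                    "original_count": n.original_count,
                    "aggregated_count": n.aggregated_count,
                    "weight": n.weight,
                    "absorbed_roots": sorted(n.absorbed_roots),
                }
                for r, n in sorted(network.nodes.items())
            },
            "child_of": sorted(map(list, network.child_of)),
        }
    else:
        doc = {
            "type": "dwat",
            "old_version": network.old_version,
            "new_version": network.new_version,
            "b_old": network.b_old,
            "b_new": network.b_new,
            "root_id": network.root_id,
            "nodes": {
                r: {
                    "label": n.label,
                    "display_label": n.display_label,
                    "status": n.status,
                    "label_source": n.label_source,
                    "shape_source": n.shape_source,
                    "is_aggregate": n.is_aggregate,
                    "n_old": n.n_old,
                    "n_new": n.n_new,
                    "tally": {
                        "new": n.tally.new,
                        "deleted": n.tally.deleted,
                        "modified_in": n.tally.modified_in,
                        "modified_out": n.tally.modified_out,
                        "aggregated_parea_delta": n.tally.aggregated_parea_delta,
                    },
                    "annotations": list(node_annotation_lines(n)),
                }
                for r, n in sorted(network.nodes.items())
            },
            "edges": sorted(map(list, network.edges)),
            "areas": [
                {
                    "base_rel_set": sorted(a.base_rel_set),
                    "rel_delta": a.rel_delta,
                    "concept_delta": a.concept_delta,
                    "suppressed": a.suppressed,
                    "member_root_ids": sorted(a.member_root_ids),
                    "annotations": list(area_annotation_lines(a)),
                }
                for a in network.areas
            ],
        }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def wat_from_json(text: str) -> WAT:
    """Rebuild a WAT from its JSON export (inverse of :func:`to_json`)."""
    doc = json.loads(text)
    if doc.get("type") != "wat":
        raise ValueError("not a WAT document")
    nodes = {
        r: WATNode(
            root_id=r,
            label=d["label"],
            area_rel_set=frozenset(d["area_rel_set"]),
            area_intro_rels=frozenset(d["area_intro_rels"]),
            concept_ids=frozenset(d["concept_ids"]),
            original_count=d["original_count"],
            aggregated_count=d["aggregated_count"],
            weight=d["weight"],
            absorbed_roots=frozenset(d["absorbed_roots"]),
        )
        for r, d in doc["nodes"].items()
    }
    return WAT(
        b=doc["b"],
        source_version=doc["source_version"],
        root_id=doc["root_id"],
        nodes=nodes,
        child_of=frozenset(tuple(e) for e in doc["child_of"]),
        depth=doc.get("depth", 1),
    )


def dwat_from_json(text: str) -> DWAT:
    """Rebuild a DWAT from its JSON export (inverse of :func:`to_json`)."""
    doc = json.loads(text)
    if doc.get("type") != "dwat":
        raise ValueError("not a DWAT document")
    nodes = {
        r: DiffNode(
            root_id=r,
            label=d["label"],
            status=d["status"],
            tally=ChangeTally(**d["tally"]),
            label_source=d["label_source"],
            shape_source=d["shape_source"],
            is_aggregate=d["is_aggregate"],
            display_label=d["display_label"],
            n_old=d["n_old"],
            n_new=d["n_new"],
        )
        for r, d in doc["nodes"].items()
    }
    areas = tuple(
        DiffArea(
            base_rel_set=frozenset(a["base_rel_set"]),
            rel_delta=a["rel_delta"],
            concept_delta=a["concept_delta"],
            suppressed=a["suppressed"],
            member_root_ids=frozenset(a["member_root_ids"]),
        )
        for a in doc["areas"]
    )
    return DWAT(
        old_version=doc["old_version"],
        new_version=doc["new_version"],
        b_old=doc["b_old"],
        b_new=doc["b_new"],
        root_id=doc["root_id"],
        nodes=nodes,
        edges=frozenset(tuple(e) for e in doc["edges"]),
        areas=areas,
    )
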