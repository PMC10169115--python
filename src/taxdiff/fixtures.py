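"""Worked-example releases, edit logs and synthetic release generation.

Two hand-built excerpts mirror the figures used throughout the package
documentation: an 18-concept process hierarchy whose taxonomy has four areas
and six partial-areas, and a paired pair of vaccine-centered releases (91
concepts growing to 117) whose diff exercises every node status and change
tally.  On top of those, :func:`simulate_evolution` applies seeded random
edits to any base release and returns the exact :class:`EditLog`, which is
the ground truth for change-recovery tests, and :func:`random_release` grows
synthetic rooted DAGs with configurable multi-parent and
relationship-introduction probabilities.

The pair of excerpt releases realizes the published per-node tallies with one
exception: the printed per-node moves do not balance across the closed
excerpt (46 concepts leave nodes but 47 arrive), so the removed 'organism
substance' node absorbs the one-concept difference (17 modified out, 1
deleted).  All other counts — including every externally checked one — are
realized exactly.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .errors import FeasibilityError
from .model import VIRTUAL_ROOT, Concept, OntologyRelease
from .ontology_io import write_concept_table

EditKind = Literal[
    "add_subtree", "delete_concepts", "move_concepts", "add_rel_type", "remove_rel_type"
]


@dataclass(frozen=True)
class EditRecord:
    """One concrete edit.  ``payload`` fixes the affected concepts exactly so
    that replay is deterministic:

    - ``add_subtree``: tuples ``(id, label, parents, rels)`` of new concepts;
    - ``delete_concepts``: deleted concept ids;
    - ``move_concepts``: tuples ``(id, new_parents, new_rels)``;
    - ``add_rel_type`` / ``remove_rel_type``: tuples ``(id, rel)``.
    """

    kind: EditKind
    target: str
    count: int
    payload: tuple = ()


@dataclass(frozen=True)
class EditLog:
    """Ordered ground-truth record of edits between a release pair."""

    records: tuple[EditRecord, ...]
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "records": [
                    {
                        "kind": r.kind,
                        "target": r.target,
                        "count": r.count,
                        "payload": [list(map(_jsonable, p)) for p in r.payload],
                    }
                    for r in self.records
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EditLog":
        doc = json.loads(text)
        records = []
        for r in doc["records"]:
            payload = tuple(
                tuple(frozenset(x) if isinstance(x, list) else x for x in p)
                for p in r["payload"]
            )
            records.append(EditRecord(r["kind"], r["target"], r["count"], payload))
        return cls(tuple(records), doc.get("seed", 0))


def _jsonable(x):
    return sorted(x) if isinstance(x, frozenset) else x


def replay_edit_log(
    base: OntologyRelease, log: EditLog, version_id: str | None = None
) -> OntologyRelease:
    """Apply an edit log to a base release; the result is exact."""
    concepts = dict(base.concepts)
    for rec in log.records:
        if rec.kind == "add_subtree":
            for cid, label, parents, rels in rec.payload:
                if cid in concepts:
                    raise FeasibilityError(f"add_subtree: id {cid!r} already exists")
                concepts[cid] = Concept(cid, label, frozenset(parents), frozenset(rels))
        elif rec.kind == "delete_concepts":
            for (cid,) in rec.payload:
                if cid not in concepts:
                    raise FeasibilityError(f"delete_concepts: unknown id {cid!r}")
                del concepts[cid]
        elif rec.kind == "move_concepts":
            for cid, new_parents, new_rels in rec.payload:
                c = concepts[cid]
                concepts[cid] = Concept(
                    cid, c.label, frozenset(new_parents), frozenset(new_rels)
                )
        elif rec.kind == "add_rel_type":
            for cid, rel in rec.payload:
                c = concepts[cid]
                concepts[cid] = Concept(
                    cid, c.label, c.parent_ids, c.explicit_rels | {rel}
                )
        elif rec.kind == "remove_rel_type":
            for cid, rel in rec.payload:
                c = concepts[cid]
                if rel not in c.explicit_rels:
                    raise FeasibilityError(f"{cid!r} has no relationship {rel!r}")
                concepts[cid] = Concept(
                    cid, c.label, c.parent_ids, c.explicit_rels - {rel}
                )
        else:  # pragma: no cover - guarded by EditKind typing
            raise ValueError(f"unknown edit kind {rec.kind!r}")
    # Deleting a concept orphans its children onto the deleted concept's id;
    # prune dangling parent links so the result is a valid release.
    deleted = {cid for rec in log.records if rec.kind == "delete_concepts" for (cid,) in rec.payload}
    if deleted:
        concepts = {
            cid: Concept(c.id, c.label, c.parent_ids - deleted, c.explicit_rels)
            for cid, c in concepts.items()
            if cid not in deleted
        }
    return OntologyRelease(version_id or base.version_id + "+edits", concepts)


# ---------------------------------------------------------------------------
# Worked-example excerpt 1: 18 process concepts, four areas, six partial-areas
# ---------------------------------------------------------------------------

def fig1_excerpt() -> OntologyRelease:
    """18-concept process-hierarchy excerpt plus the virtual root.

    A gray group of eight concepts shares {realizes}; a left green group of
    two adds {achieves planned objective}; a right green group of three adds
    {caused by infection with}; a red group of five — with three separate
    roots — adds {has specified input} on top of the left-green set.
    """
    R, APO, CBI, HSI = (
        "realizes",
        "achieves planned objective",
        "caused by infection with",
        "has specified input",
    )

    def c(cid, label, parents, rels=()):
        return Concept(cid, label, frozenset(parents), frozenset(rels))

    concepts = [
        # gray area: {realizes}
        c("process", "process", [VIRTUAL_ROOT], [R]),
        c("disease_process", "disease process", ["process"]),
        c("planned_process", "planned process", ["process"]),
        c("infection_process", "infection process", ["process"]),
        c("diagnostic_process", "diagnostic process", ["planned_process"]),
        c("immunization", "immunization", ["planned_process"]),
        c("active_immunization", "active immunization", ["immunization"]),
        c("passive_immunization", "passive immunization", ["immunization"]),
        # left green area: {realizes, achieves planned objective}
        c("covid19_diagnostic_process", "COVID-19 diagnostic process",
          ["diagnostic_process"], [APO]),
        c("covid19_lab_diagnostic_process", "COVID-19 laboratory diagnostic process",
          ["covid19_diagnostic_process"]),
        # right green area: {realizes, caused by infection with}
        c("coronavirus_infectious_disease_process", "coronavirus infectious disease process",
          ["disease_process"], [CBI]),
        c("covid19_disease_process", "COVID-19 disease process",
          ["coronavirus_infectious_disease_process"]),
        c("sars_disease_process", "SARS disease process",
          ["coronavirus_infectious_disease_process"]),
        # red area: {realizes, achieves planned objective, has specified input}
        c("vaccine_immunization", "vaccine immunization",
          ["active_immunization"], [APO, HSI]),
        c("covid19_diag_nucleic_acid", "COVID-19 diagnostic process using nucleic acid detection",
          ["covid19_diagnostic_process"], [HSI]),
        c("covid19_rtpcr_testing", "COVID-19 RT-PCR testing",
          ["covid19_diag_nucleic_acid"]),
        c("covid19_diag_serological", "COVID-19 diagnostic process by serological assay",
          ["covid19_diagnostic_process"], [HSI]),
        c("covid19_antibody_testing", "COVID-19 antibody testing",
          ["covid19_diag_serological"]),
    ]
    return OntologyRelease("excerpt-18", concepts)


# ---------------------------------------------------------------------------
# Worked-example excerpt 2: paired vaccine-centred releases (91 -> 117)
# ---------------------------------------------------------------------------

_OLD_VERSION = "1.0.108-excerpt"
_NEW_VERSION = "1.0.337-excerpt"


def _fig2_old_release() -> OntologyRelease:
    def c(cid, label, parents, rels=()):
        return Concept(cid, label, frozenset(parents), frozenset(rels))

    top_labels = [
        "material entity", "quality", "information content entity",
        "role", "function", "plan specification",
    ]
    concepts = [
        c(f"top_{i:02d}", lbl, [VIRTUAL_ROOT]) for i, lbl in enumerate(top_labels, 1)
    ]
    concepts.append(
        c("organism_substance", "organism substance", [VIRTUAL_ROOT], ["derives from"])
    )
    concepts += [
        c(f"os_c{i:02d}", f"organism substance member {i}", ["organism_substance"])
        for i in range(1, 18)
    ]
    concepts.append(
        c("processed_material", "processed material", [VIRTUAL_ROOT], ["has function"])
    )
    concepts += [
        c(f"pm_c{i:02d}", f"processed material member {i}", ["processed_material"])
        for i in range(1, 48)
    ]
    concepts.append(c("device", "device", ["processed_material"], ["has role"]))
    concepts += [
        c(f"dv_c{i:02d}", f"device member {i}", ["device"]) for i in range(1, 5)
    ]
    concepts.append(c("vaccine", "vaccine", ["pm_c01"], ["immunizes against"]))
    concepts.append(c("viral_vaccine", "viral vaccine", ["vaccine"], ["targets virus"]))
    concepts += [
        c(f"vv_c{i:02d}", f"viral vaccine member {i}", ["viral_vaccine"])
        for i in range(1, 10)
    ]
    concepts.append(
        c("covid19_vaccine", "COVID-19 vaccine", ["viral_vaccine"], ["counteracts disease"])
    )
    concepts.append(
        c("inactivated_viral_vaccine", "inactivated viral vaccine",
          ["viral_vaccine"], ["has component"])
    )
    return OntologyRelease(_OLD_VERSION, concepts)


def _fig2_fig3_edit_log() -> EditLog:
    records = [
        # 16 organism-substance concepts lose their relationships and sit
        # directly under the root.
        EditRecord(
            "move_concepts", VIRTUAL_ROOT, 16,
            tuple(
                (cid, frozenset({VIRTUAL_ROOT}), frozenset())
                for cid in ["organism_substance"] + [f"os_c{i:02d}" for i in range(1, 16)]
            ),
        ),
        # One remodeled into a viral vaccine, one deleted.
        EditRecord(
            "move_concepts", "viral_vaccine", 1,
            (("os_c16", frozenset({"viral_vaccine"}), frozenset()),),
        ),
        EditRecord("delete_concepts", "organism_substance", 1, (("os_c17",),)),
        # 29 processed materials remodeled as viral vaccines.
        EditRecord(
            "move_concepts", "viral_vaccine", 29,
            tuple(
                (f"pm_c{i:02d}", frozenset({"viral_vaccine"}), frozenset())
                for i in range(19, 48)
            ),
        ),
        EditRecord(
            "add_subtree", "processed_material", 10,
            tuple(
                (f"pm_n{i:02d}", f"new processed material {i}",
                 frozenset({"processed_material"}), frozenset())
                for i in range(1, 11)
            ),
        ),
        EditRecord(
            "add_subtree", "viral_vaccine", 1,
            (("vv_n01", "new viral vaccine", frozenset({"viral_vaccine"}), frozenset()),),
        ),
        # COVID-19 vaccine grows into a major subject of its own ...
        EditRecord(
            "add_subtree", "covid19_vaccine", 12,
            tuple(
                (f"cv_n{i:02d}", f"COVID-19 vaccine {i}",
                 frozenset({"covid19_vaccine"}), frozenset())
                for i in range(1, 13)
            ),
        ),
        # ... with two small child partial-areas of two concepts each.
        EditRecord(
            "add_subtree", "covid19_vaccine", 2,
            (
                ("covid19_mrna_vaccine", "COVID-19 mRNA vaccine",
                 frozenset({"covid19_vaccine"}), frozenset({"has vaccine platform"})),
                ("cv_mrna_c01", "COVID-19 mRNA vaccine member 1",
                 frozenset({"covid19_mrna_vaccine"}), frozenset()),
            ),
        ),
        EditRecord(
            "add_subtree", "covid19_vaccine", 2,
            (
                ("covid19_subunit_vaccine", "COVID-19 subunit vaccine",
                 frozenset({"covid19_vaccine"}), frozenset({"has antigen"})),
                ("cv_sub_c01", "COVID-19 subunit vaccine member 1",
                 frozenset({"covid19_subunit_vaccine"}), frozenset()),
            ),
        ),
    ]
    return EditLog(tuple(records), seed=0)


def fig2_fig3_pair() -> tuple[OntologyRelease, OntologyRelease, EditLog]:
    """Paired vaccine-centred excerpt releases and the edit log relating them.

    The older release has 91 concepts in eight partial-areas (root 7, organism
    substance 18, processed material 48 with a small device child of 5,
    vaccine 1, viral vaccine 10 with two absorbed singletons).  The newer
    release realizes the narrative diff: concepts without relationships
    accumulate at the root, organism substance disappears, processed material
    turns over, and COVID-19 vaccine emerges as a new aggregate major subject.
    """
    old = _fig2_old_release()
    log = _fig2_fig3_edit_log()
    new = replay_edit_log(old, log, version_id=_NEW_VERSION)
    return old, new, log


# ---------------------------------------------------------------------------
# Synthetic releases and seeded evolution
# ---------------------------------------------------------------------------

_REL_POOL = [
    "has function", "has role", "derives from", "realizes",
    "has participant", "located in", "has component", "targets organism",
]


def random_release(
    n_concepts: int = 60,
    multi_parent_p: float = 0.1,
    rel_p: float = 0.2,
    n_rel_types: int = 6,
    seed: int = 0,
    version: str | None = None,
) -> OntologyRelease:
    """Grow a random rooted concept DAG.

    Concepts are added one at a time under a uniformly chosen existing parent;
    with probability ``multi_parent_p`` a second parent is attached (creating
    multiple inheritance and, downstream, partial-area overlap and diamond
    aggregation paths), and with probability ``rel_p`` the concept introduces
    one lateral relationship type from a pool of ``n_rel_types``.
    """
    rng = random.Random(seed)
    pool = _REL_POOL[:n_rel_types]
    existing = [VIRTUAL_ROOT]
    concepts = []
    for i in range(n_concepts):
        cid = f"c{i:04d}"
        parents = {rng.choice(existing)}
        if len(existing) > 1 and rng.random() < multi_parent_p:
            parents.add(rng.choice(existing))
        rels = frozenset({rng.choice(pool)}) if rng.random() < rel_p else frozenset()
        concepts.append(Concept(cid, f"concept {i}", frozenset(parents), rels))
        existing.append(cid)
    return OntologyRelease(version or f"synthetic-s{seed}", concepts)


def simulate_evolution(
    base: OntologyRelease,
    edit_spec: dict | None,
    seed: int,
) -> tuple[OntologyRelease, EditLog]:
    """Apply seeded random edits of each requested kind to ``base``.

    ``edit_spec`` maps edit kinds to lists of operation dicts, e.g.::

        {"add_subtree": [{"target": "c0003", "count": 40}],
         "delete_concepts": [{"target": "c0007", "count": 7}],
         "move_concepts": [{"source": "c0001", "target": "c0002", "count": 3}],
         "add_rel_type": [{"target": "c0004", "rel": "has role"}],
         "remove_rel_type": [{"target": "c0004", "rel": "has role"}]}

    Concrete affected concepts are drawn with a :class:`random.Random` seeded
    by ``seed``; the returned log pins them exactly, so the same
    ``(base, edit_spec, seed)`` always yields identical outputs and replaying
    the log on ``base`` reproduces the evolved release.
    """
    rng = random.Random(seed)
    edit_spec = edit_spec or {}
    records: list[EditRecord] = []
    current = base
    counter = 0

    def fresh_ids(k: int) -> list[str]:
        nonlocal counter
        out = []
        while len(out) < k:
            cid = f"sim{seed}_{counter:04d}"
            counter += 1
            if cid not in current.concepts:
                out.append(cid)
        return out

    def leaves_under(target: str) -> list[str]:
        desc = current.descendants(target)
        return sorted(d for d in desc if not current.children(d))

    for op in edit_spec.get("add_subtree", []):
        target, count = op["target"], op["count"]
        if target not in current.concepts:
            raise FeasibilityError(f"add_subtree: unknown target {target!r}")
        ids = fresh_ids(count)
        payload = []
        attachable = [target]
        for cid in ids:
            parent = rng.choice(attachable)
            payload.append((cid, f"synthetic {cid}", frozenset({parent}), frozenset()))
            attachable.append(cid)
        records.append(EditRecord("add_subtree", target, count, tuple(payload)))
        current = replay_edit_log(current, EditLog((records[-1],)), current.version_id)

    for op in edit_spec.get("delete_concepts", []):
        target, count = op["target"], op["count"]
        candidates = leaves_under(target)
        if len(candidates) < count:
            raise FeasibilityError(
                f"delete_concepts: only {len(candidates)} deletable leaves under "
                f"{target!r}, requested {count}"
            )
        chosen = rng.sample(candidates, count)
        records.append(
            EditRecord("delete_concepts", target, count, tuple((c,) for c in sorted(chosen)))
        )
        current = replay_edit_log(current, EditLog((records[-1],)), current.version_id)

    for op in edit_spec.get("move_concepts", []):
        source, target, count = op["source"], op["target"], op["count"]
        candidates = [c for c in leaves_under(source) if c != target]
        if len(candidates) < count:
            raise FeasibilityError(
                f"move_concepts: only {len(candidates)} movable leaves under "
                f"{source!r}, requested {count}"
            )
        chosen = rng.sample(candidates, count)
        payload = tuple(
            (c, frozenset({target}), frozenset()) for c in sorted(chosen)
        )
        records.append(EditRecord("move_concepts", target, count, payload))
        current = replay_edit_log(current, EditLog((records[-1],)), current.version_id)

    for op in edit_spec.get("add_rel_type", []):
        records.append(
            EditRecord("add_rel_type", op["target"], 1, ((op["target"], op["rel"]),))
        )
        current = replay_edit_log(current, EditLog((records[-1],)), current.version_id)

    for op in edit_spec.get("remove_rel_type", []):
        records.append(
            EditRecord("remove_rel_type", op["target"], 1, ((op["target"], op["rel"]),))
        )
        current = replay_edit_log(current, EditLog((records[-1],)), current.version_id)

    log = EditLog(tuple(records), seed=seed)
    evolved = replay_edit_log(base, log, version_id=base.version_id + "-evolved")
    return evolved, log


def write_fixture_tables(out_dir: str | Path) -> list[Path]:
    """Write the worked-example releases as concept tables; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    old, new, _ = fig2_fig3_pair()
    written = []
    for name, release in [
        ("process_excerpt.tsv", fig1_excerpt()),
        ("vaccine_excerpt_old.tsv", old),
        ("vaccine_excerpt_new.tsv", new),
    ]:
        path = out_dir / name
        write_concept_table(release, path)
        written.append(path)
    return written
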