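# taxdiff

Summarize the content of a biomedical ontology release as a compact network
of major subjects, and visualize how that content **changed** between two
releases.

Curators and users of fast-moving ontologies (CIDO-scale and up: thousands of
concepts, frequent releases) cannot read a release diff concept by concept.
`taxdiff` implements the abstraction-network route to the "big picture":

1. **Partial-area taxonomy (PAT).** Concepts sharing an identical *effective*
   set of lateral (non-hierarchical) relationship types — explicit plus
   inherited along is-a — form an *area*; each concept with no parent in its
   own area roots a *partial-area* (the root plus its within-area
   descendants). Roots' is-a links induce hierarchical *child-of* edges.
2. **Weighted aggregate taxonomy (WAT).** The *weight* of a partial-area is
   the number of concepts that are its root or the root's descendants in the
   whole release. Under an integer threshold *b*, partial-areas with weight
   ≥ *b* are shown as major-subject nodes; smaller ones are absorbed into
   their closest large ancestor(s) along child-of paths. Aggregate nodes are
   labeled `name (n){m}[o]`: *n* concepts summarized after aggregation, *m*
   partial-areas absorbed, *o* concepts before aggregation.
3. **Diff WAT (DWAT).** Given two releases O₁ (older) and O₂ and their WATs
   T₁, T₂, nodes matched by root concept are classified *introduced* /
   *removed* / *modified* / *unmodified*; each node carries a tally of new,
   deleted and moved-in/out concepts satisfying
   `n₂ − n₁ = new − deleted + in − out`; child-of edges are classified
   introduced/removed/unmodified; areas report global concept and
   relationship deltas (suppressed when redundant).
4. **Drill-down.** Any major-subject node expands into the taxonomy of its
   absorbed partial-areas (secondary subjects), which can be aggregated and
   diffed again, recursively.

Everything exports as deterministic Graphviz DOT (status colors
yellow/white/green/red, colored edges, area clusters) and lossless JSON.

## Input formats

- **OWL** (RDF/XML, Turtle) via `read_owl(path, mode=...)`. In
  `restriction` mode, a concept's explicit relationship types are the object
  properties appearing in its own subclass/equivalence restrictions
  (recursing through nested expressions); `domain_union_restriction`
  additionally assigns each object property to its declared domain class.
  Deprecated classes are dropped (and logged); imports are not resolved
  unless requested.
- **Concept table** (TSV: `id  label  parents  rels  deprecated`, pipe
  separators, `#version=` header) via `read_concept_table` /
  `write_concept_table`; round-trips losslessly.

A virtual root `Thing` closes every hierarchy.

## Worked example

The package ships a 91-concept vaccine-centred excerpt that evolves into a
117-concept release (`taxdiff.fig2_fig3_pair()`), plus an 18-concept process
excerpt (`taxdiff.fig1_excerpt()`):

```python
from taxdiff import *

old, new, log = fig2_fig3_pair()
tax = derive_taxonomy(old)
wat = build_wat(tax, b=10)
for r, lvl in sorted(assign_levels(wat).levels.items(), key=lambda kv: kv[1]):
    print(lvl, format_node_label(wat.nodes[r]), wat.nodes[r].weight)

dwat = build_dwat(old, new, b_old=10, b_new=10)
for r, n in sorted(dwat.nodes.items()):
    print(n.display_label, n.status, "; ".join(node_annotation_lines(n)))
```

prints

```
level 0: Thing (7)                        weight=91
level 1: organism substance (18)          weight=18
level 1: processed material (53){1}[48]   weight=66
level 2: vaccine (1)                      weight=13
level 3: viral vaccine (12){2}[10]        weight=12

Thing (7)                      modified    +16 Concepts Modified
COVID-19 vaccine (17){2}[13]   introduced  +16 New Concepts; +1 Concept Modified
organism substance (18)        removed     -17 Concepts Modified; -1 Concept Deleted
processed material (53){1}[48] modified    +10 New Concepts; -29 Concepts Modified
vaccine (1)                    unmodified
viral vaccine (12){2}[10]      modified    +1 New Concept; -1 Concept Modified; +30 Concepts Modified; -1 Aggregated P-area
```

Reading: `vaccine (1)` summarizes one concept but has weight 13 (its three
descendant partial-areas sum to 12 more), so it stays a major subject at
b=10. In the newer release, 16 concepts lost all relationships and moved to
the root node, `organism substance` stopped being a major subject, 29
processed materials were remodeled as viral vaccines, and `COVID-19 vaccine`
emerged as a new aggregate major subject of 17 concepts (16 of them new).

## Command line

```bash
taxdiff fixtures --out-dir fx                      # write the example tables
taxdiff wat  --in fx/vaccine_excerpt_old.tsv --b 10 --dot wat.dot
taxdiff wat  --in release.owl --format owl --max-nodes 25 --json wat.json
taxdiff dwat --old fx/vaccine_excerpt_old.tsv --new fx/vaccine_excerpt_new.tsv \
             --b 10 --dot diff.dot --json diff.json
taxdiff drill --old fx/vaccine_excerpt_old.tsv --new fx/vaccine_excerpt_new.tsv \
             --root covid19_vaccine --b 10 --b2 2 --json drill.json
taxdiff simulate --in base.tsv --edits edits.json --seed 7 \
             --out evolved.tsv --log-out log.json
```

`--max-nodes N` picks the smallest *b* whose WAT has at most N nodes (default
budget 25 when neither is given). Logs (node/area counts, chosen *b*) go to
stderr; identical invocations produce byte-identical outputs.

## Layout

- `src/taxdiff/model.py` — concepts and validated releases
- `src/taxdiff/ontology_io.py` — OWL and concept-table reading/writing
- `src/taxdiff/taxonomy.py` — areas, partial-areas, child-of derivation
- `src/taxdiff/wat.py` — weights, aggregation under *b*, smallest-*b* search
- `src/taxdiff/dwat.py` — node/edge classification, tallies, area deltas
- `src/taxdiff/drilldown.py` — secondary/tertiary subject taxonomies
- `src/taxdiff/render.py` — levels, DOT, JSON round-trip
- `src/taxdiff/fixtures.py` — worked examples, edit logs, synthetic releases
- `src/taxdiff/cli.py` — the `taxdiff` command

See `docs/methods.md` for the model details, parameter semantics and known
limitations.
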