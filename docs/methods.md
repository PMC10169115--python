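# Methods

## Model

A release is a rooted DAG of concepts under a virtual root `Thing`.  Each
concept carries *explicit* lateral relationship types; its *effective* set is
the union of its explicit types with those of all its ancestors.  Derivation
proceeds in three stages:

**Areas and partial-areas.**  Areas group concepts by identical effective
sets.  A concept with no parent in its own area is a root; its partial-area
is the root plus every concept reachable from it along is-a paths that stay
inside the area.  The within-area-path reading is deliberate: a concept that
is a descendant of a root only via a path leaving the area does *not* join
that root's partial-area (it will belong to whichever root reaches it inside
the area).  A concept descending from two roots of its area belongs to both
partial-areas; partial-area counts count their own members, while area-level
and aggregate counts always count distinct concepts.  Child-of edges are
induced by roots' is-a links: partial-area A is child-of B when a parent of
A's root lies in B, and analogously for areas.  Both child-of graphs are
acyclic by construction (a child root is a strict descendant of the parent
partial-area's root).

**Weighted aggregation.**  `weight(r)` is the number of distinct concepts
that are `r` or descendants of `r` in the whole hierarchy.  Given integer
`b ≥ 1`, partial-areas of weight ≥ b become WAT nodes (the root partial-area
is always retained, as every layout shows the root node); each small
partial-area's concepts are added to *every* closest large ancestor — the
first large node on each upward child-of path.  Under diamond child-of
patterns this means the summarized counts can sum to more than the release
total; the counts stay honest per node (each node's `n` is a set
cardinality), and a `single_ancestor` option routes the concepts to the
lexicographically smallest target instead when disjoint totals are needed.
Weight is monotone along child-of edges (a parent's root dominates the
child's subtree), so surviving nodes are never separated by small interior
nodes and WAT edges are exactly the direct large-to-large child-of links;
interior-small traversal matters only when chasing absorption targets
through chains of small partial-areas.

**Smallest b.**  The node count at threshold `b` is the number of
partial-area weights ≥ b, which is non-increasing in `b`; the smallest `b`
with at most `max_nodes` nodes is therefore read directly off the sorted
weight sequence (`ws[max_nodes] + 1` when there are more partial-areas than
the budget).  The tests verify this against an exhaustive linear scan.

**Diffing.**  Nodes of two WATs are matched by root concept identifier —
labels play no role in identity, so a re-labeled concept is still the same
subject and a re-identified concept counts as delete-plus-add.  Statuses:
present only in the newer WAT → introduced; only in the older → removed;
both with identical summarized concept sets → unmodified; otherwise
modified.  With S₁, S₂ the post-aggregation summarized sets and O₁, O₂ the
release concept sets, the tally is

```
new          = |S₂ \ O₁|          deleted      = |S₁ \ O₂|
modified_in  = |(S₂ ∩ O₁) \ S₁|   modified_out = |(S₁ ∩ O₂) \ S₂|
```

so `n₂ − n₁ = new − deleted + modified_in − modified_out` holds identically.
Note the semantics: a concept "moves" whenever its node membership changes,
including when the only cause is aggregation (e.g. a node that vanished
because `b` grew reports its surviving concepts as modified-out even though
the concepts themselves are untouched).  The absorbed-partial-area delta
(m₂ − m₁) is reported on modified nodes only.  Edges are introduced /
removed / unmodified — never modified, since an edge either exists or not.
Area-level deltas follow node matching (a surviving node's old-release area
versus its new-release area, so a relationship lost by a surviving subject
shows up as a `-1 Rel` annotation): surviving nodes group by their
old-release area, introduced nodes by their new-release area; concept deltas
count distinct concepts across the group; groups that are entirely
introduced or entirely removed are suppressed as redundant with the node
annotations.

**Annotation grammar** (bit-exact in exports): node lines in the order new,
moved-out, moved-in, deleted, aggregated-partial-area delta, e.g.
`+1 New Concept`, `-29 Concepts Modified`, `+30 Concepts Modified`,
`-2 Concepts Deleted`, `-1 Aggregated P-area` (nouns singular at count 1);
area lines `+16 Concepts`, `-1 Rel`.

**Drill-down.**  A node's scope is its own partial-area plus all absorbed
partial-areas; the restriction of the PAT to that scope (with the major root
as taxonomy root) is itself a PAT and re-enters the same aggregation/diff
machinery.  Weights inside a drill-down are recomputed on the hierarchy
restricted to the scope: a small partial-area absorbed elsewhere may have
out-of-scope descendants, and counting them would let an invisible subtree
inflate a secondary subject.  The default secondary threshold is
`max(1, b // 5)`, mirroring the scale ratio between the top-level view
(b ≈ 29–55 for a ~10k-concept ontology) and a useful drill-down view
(b ≈ 5); it is overridable everywhere.  When a major subject exists in only
one release, its secondary diff is taken against an empty taxonomy, so the
drill-down is total (everything introduced or everything removed).

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `b` | weight threshold for major subjects (concepts) | — (required) | ontology-size dependent |
| `max_nodes` | node budget for smallest-b search | 25 | comprehension budget for a single view |
| `b2` | drill-down threshold | `max(1, b//5)` | top-level : drill-down scale ratio |
| `mode` | OWL relationship extraction | `restriction` | local restrictions give more informative top areas than global domains |
| `single_ancestor` | diamond absorption routing | off | faithful "all closest ancestors" semantics |
| `multi_parent_p` | generator: second-parent probability | 0.1 | enough multiple inheritance to exercise overlap/diamonds without dominating |
| `rel_p` | generator: relationship-introduction probability | 0.2 | yields several areas per ~50-concept release |

## OWL extraction choices

"Restriction-defined" is read broadly but axiom-locally: object-property
IRIs are collected from each class's own `subClassOf`/`equivalentClass`
expressions, recursing through intersections, unions, complements,
`someValuesFrom`/`allValuesFrom`/`hasValue` and qualified cardinalities;
datatype properties are excluded.  Each property IRI is its own relationship
type (no lifting to super-properties).  Deprecated classes are removed, with
links through them pruned, before any derivation.  Imports are parsed only
on request, since published distributions are usually pre-merged and silent
resolution changes concept counts.  Only the asserted hierarchy is used —
no reasoner classification.

## Synthetic data: what it emulates and what it does not

`random_release` grows a rooted DAG one concept at a time (uniform parent,
optional second parent, optional single introduced relationship type from a
small pool), which reproduces the structural features the pipeline is
sensitive to: multi-rooted areas, overlapping partial-areas, diamond
child-of patterns, and chains of small partial-areas.  `simulate_evolution`
applies seeded edits (subtree additions, leaf deletions, leaf moves,
relationship-type additions/removals) and returns an exact edit log; tests
recover the log's counts from DWAT tallies when edits stay within one
node's scope.  The generator does **not** emulate real ontologies'
heavy-tailed subtree sizes, correlated relationship usage, label semantics,
or annotation churn — so green tests certify the combinatorics of
derivation, aggregation and diffing, not performance or extraction fidelity
on any particular ontology's modeling style.  Typical test problem sizes are
35–200 concepts per release with up to 200 seeded release pairs per
property, sizes at which every brute-force oracle (ancestor closures,
reachability counts, exhaustive threshold scans, longest-path enumeration)
is still exact and cheap.

## Worked-example fixture

The vaccine-excerpt pair (91 → 117 concepts) realizes the published
narrative: 16 concepts losing all relationships and accumulating at the
root, the organism-substance subject disappearing, 29 processed materials
remodeled as viral vaccines plus 10 new ones, and COVID-19 vaccine emerging
as an aggregate major subject (17 concepts, 16 new, absorbing two small
child partial-areas).  One bookkeeping point: summing the narrative's
arrivals (16 + 30 + 1) exceeds its departures (16 + 29 + 1) by one concept,
which is impossible in a closed excerpt without double counting; the fixture
therefore lets the removed organism-substance node emit 17 moved-out
concepts and 1 deletion.  Every other figure — including all externally
checked ones — is realized exactly, and the edit log relating the pair
replays to the newer release byte-for-byte.

## Numerical / determinism choices

Everything is integer counting; there are no tolerances.  Determinism is a
contract: areas sort by (relationship-count, lexicographic relationship
set), partial-areas and nodes by root identifier, exports serialize sorted
collections, and identical inputs yield byte-identical DOT/JSON.  Layout
levels use *longest* child-of path to the root (the standard layered-drawing
choice; it keeps every edge pointing strictly upward even with transitive
edges present).  Degenerate inputs: an empty table yields a root-only
release; `b=1` reproduces the PAT exactly; a one-node network sits at level
0; self-diff yields only unmodified nodes, zero tallies and zero deltas.

## Known limitations

- Area clusters and rank levels cannot always be reconciled in DOT exactly
  as hand-drawn figures interleave them; counts, colors and shapes are the
  contract, visual fidelity is best-effort.
- Concept renames across releases are not detected (identity is the
  identifier).
- Only two releases are diffed at a time; multi-release trajectories are out
  of scope.
- Aggregation is recomputed from the PAT for each `b`; there is no
  incremental re-aggregation.
- The concept-level semantics of "modified" is membership change, which
  conflates remodeling with pure aggregation effects when `b` differs
  between the two sides (documented above).
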