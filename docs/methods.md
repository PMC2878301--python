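# Methods

This note documents the models and procedures implemented in `mepnkit`, the
assumptions behind them, the parameters that matter, and what the test suite
does and does not demonstrate.

## The notation model

An mEPN diagram is modelled as a typed directed graph. Node classes are pairs
`(kind, subclass)` drawn from a glyph registry: components (`protein`,
`protein_complex`, `gene`, `ion_simple_molecule`, `pathogen`, plus a
`generic` fallback for unclassifiable imports), circular process nodes keyed
by a 1–3-character code, Boolean operators (`AND`, `OR`, `NOT`), edge
annotations (`A`, `I`, `C`), energy/molecular transfer, conditional gates,
pathway modules and pathway outputs. Edges are directed interactions or
undirected physical bonds; bonds never carry annotation codes. Compartments
are first-class records forming a forest (one optional parent each).

Two deliberate design choices shape the model:

* **Opaque node ids.** Labels are not unique (a component recurs across
  compartments and states), so identity for the once-per-compartment rule is
  the *derived* key computed by the label grammar — symbol, stoichiometry and
  the sorted multiset of modification tokens, with aliases and generic names
  dropped. The uniqueness rule additionally keys on the component subclass,
  so a gene and the protein it encodes (which legitimately share an official
  symbol) never collide.
* **Explicit compartment membership.** Membership is a semantic attribute,
  never inferred from 2D coordinates; coordinates are layout only. Sibling
  sub-compartments of one parent count as distinct compartments for the
  uniqueness rule. Complexes that visually span several compartments are
  assigned one primary compartment.

## The label grammar

A label is subunits joined by top-level `:`; each subunit is a symbol
followed, in any order, by `(alias)` groups, one `<k>` stoichiometry marker
(`<n>` for unknown copy number) and `[mod]` brackets, one per modification.
In a modification token the part before the first `-` is the code, the rest
the site (`P-L232` → code `P` at site L232). Codes are case-sensitive and
preserved as written (`[t]` stays lowercase). Canonical serialization orders
groups alias → stoichiometry → modifications, drops `<1>`, and is a fixed
point: `format(parse(format(spec))) == format(spec)`. A second label line is
read as a decorative generic complex name. Nested complexes are not
expressible in one label; large assemblies are modelled as physically bonded
nodes instead.

## The glyph registry

The default registry ships exactly 31 process classes. The codes with direct
textual anchors — binding `B` (many-in/one-out), dissociation `D`
(one-in/many-out), cleavage `X`, oligomerisation `O`, the phosphorylation
family `P`/`AP`/`-P`, ubiquitination `Ub`, translocation `T` — are fixed;
the remaining entries cover the common post-translational modifications,
transport and expression steps and are **provisional defaults**: a YAML
override file can rename, restyle, add or disable any of them (code length
and uniqueness are re-validated on merge). Arity bounds beyond the
binding/dissociation conventions default to 1-in/1-out on the component
path for modification-type processes; catalytic (annotated) inputs, Boolean
constructs and energy side conditions never count against arity.

Meaning is never reliant on colour: the pair (shape, printed code) decides a
node's class, and the importer uses fill colour only as a last-resort hint
for shapeless input. The 2D→3D translation maps each class to a solid
(components to spheres/boxes, process and operator nodes to small cubes)
carrying over the 2D fill colour; with z-stacking enabled each compartment
occupies its own z layer (150 layout units apart). The 3D table is style
metadata, configurable like the rest of the registry.

## The validator

Nine rules, each independently testable, each with a stable id, default
severity and a documented rationale (`explain_rule`). Notable decisions:

* R1 exempts ion/simple-molecule nodes (ubiquitous species may repeat) and
  treats distinct modification states as distinct components.
* R7 (genes in the nucleus) is a **warning** by default: the placement is
  stated as a convention and e.g. pathogen or organellar genomes plausibly
  sit elsewhere. Severity is configurable per ruleset.
* A single-input OR (fan-out usage) is legal and reported at info level.
* Unknown edge-annotation codes are warnings, not errors — the code table is
  open-ended by design.

Validation always returns a sorted issue list (rule id, then subject ids);
label parse failures become issues rather than exceptions.

## Petri-net conversion

Components, pathway outputs, pathway modules and energy-transfer nodes map
to places; process nodes to transitions; arcs are `normal` (token-moving),
`read` (required but unconsumed) or `inhibitor` (any token hard-blocks).

* AND folds away: the downstream transition gains one input arc per AND
  input. OR replicates the downstream transition, one copy per branch, all
  feeding the same output place — verified against a brute-force
  reachability oracle on hand-built parallel transitions.
* Under an inhibitory edge the Boolean mapping dualizes (De Morgan): "S1 OR
  S2 inhibits" puts both inhibitor arcs on one transition (either token
  blocks); "S1 AND S2 inhibit" produces one singly-inhibited replica per
  input (blocked only when both are present).
* Edges annotated A or C give the regulator a read arc; annotation I becomes
  an inhibitor arc onto every transition producing into the target place.
  The choice of *hard-block* inhibition (source ≥ 1 token blocks absolutely,
  rather than scaling stochastically) is a documented semantic choice.
* Unannotated component→component edges become an implicit one-in/one-out
  transition; physical bonds contribute no arcs; conditional gates produce
  one transition per outcome branch, grouped; pathway-module places are
  pass-throughs; `NOT` maps to inhibitor arcs and is flagged experimental.

Conversion refuses graphs with error-severity validation issues and is
bipartite by construction (checked structurally and via networkx
two-colouring in the tests). Every net element keeps provenance to its
diagram element.

## Token-flow simulation

The simulator is SPN-style: structure only, no kinetic parameters, unit
weights. Per step, every enabled transition is visited in a seeded random
order and fires at most once, consuming one token per normal input arc and
producing one per output arc; enabledness is re-checked immediately before
each firing, so simultaneously enabled transitions competing for the same
tokens are resolved by the random order (no maximal-parallelism semantics —
the simplest contract that keeps runs reproducible). Within a
conditional-gate group only the first enabled branch in the order fires,
which makes the branch choice uniform among enabled branches. Trajectories
report per-place means over independent runs; row 0 is the initial marking
and row *k* the state after step *k*. Identical `(net, marking, steps,
runs, seed)` give bit-identical trajectories (one `numpy` generator seeded
once drives all runs).

Consequences worth knowing: read-arc-gated transitions with no consumed
input (e.g. transcription-factor activation of a gene) are token *sources*
while the regulator is present — token counts are activity estimates, not
conserved masses, except on nets whose transitions all balance inputs and
outputs, where conservation is exact and asserted per step in the tests.

## Fixtures and the random generator

The worked-example builders encode printed descriptions only: the receptor
complex (4 subunits, stoichiometry 2 each), the proteasome layout (6 rings
of 7 subunits, 2 cap groups), the enhanceosome (4 promoter elements — named
S/X/X2/Y after the MHC class II promoter boxes — with RFX, CREB1, NFY and
one unknown factor bound, all via undirected bonds) and the full IFNγ
pathway narrative. Where the narrative leaves gaps the fixture makes the
conventional biological choice and documents it in its docstring: STAT1
phosphorylation sites are written Y701/S727, the HLA precursor chains are
named HLA-DRA/HLA-DRB1 (the generic complex label keeps the printed
`CD74 (li):HLA-D (alpha):HLA-D (beta)` form, whose alpha/beta alias
distinction carries no identity), `RUNX2/3` is one subunit symbol, and the
long antigen-loading series is a single pathway-module node.

The default simulation marking treats constitutive species (receptor,
STAT1, kinases/phosphatases, the preassembled enhanceosome complex, the ATP
side condition) as present with a few tokens each and induced species as
absent; 6 ligand tokens, 60 steps and 20 runs are the default study
conditions — small enough to run in well under a second, long enough for
the signal to traverse the full chain.

`random_pathway(seed, n_components, n_processes)` builds
conformant-by-construction diagrams (unique symbols, legal arities,
occasional Boolean/annotation/energy elements) for property testing. What
passing these tests shows is that the machinery is sound on diagrams obeying
the notation; it says nothing about the biological accuracy of any real
curated pathway, and the random graphs do not emulate the topology of real
signalling networks (hub structure, feedback density).

## Numerical and formatting choices

* GraphML output is byte-deterministic: elements sorted by id, fixed key
  tables, UTF-8, pretty-printed by `lxml`. Coordinates are written with full
  `repr` precision and round-trip exactly; the coordinate convention is x
  right, y down, arbitrary origin.
* Files written by the package carry typed semantic attributes in both
  dialects, so re-import is lossless and never consults the graphics; shape
  classification and annotation-node collapsing apply only to foreign files.
* Registry override documents are validated with `pydantic`
  (`extra="forbid"`), so typos fail loudly.

## Known limitations

* The shipped process-code table beyond the text-anchored entries, and the
  whole 2D/3D style table, are conventional defaults, not an authoritative
  reproduction of the notation's full published palette.
* Inhibition is absolute; graded or competitive inhibition is out of scope.
* No automatic layout, no rendering, no kinetic/ODE simulation, no
  nomenclature-database verification of symbols (symbols are opaque).
* Editor-dialect fidelity covers shapes, fills, borders, labels, geometry,
  arrows and groups; editor features unrelated to the notation (bends,
  label placement models, SVG icons) are ignored.
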