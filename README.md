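# mepnkit

Tooling for the **modified Edinburgh Pathway Notation (mEPN)** — a graphical
language for drawing biological pathway process diagrams in which every glyph
has defined semantics: components (proteins, complexes, genes, ions,
pathogens), small circular process nodes carrying one-to-three-letter codes,
Boolean AND/OR operators for co-dependencies, in-line edge-annotation nodes
(A activation, I inhibition, C catalysis) in place of arrowhead styles,
energy-transfer side conditions, conditional gates, pathway modules and
pathway outputs, all laid over labelled cellular compartments.

`mepnkit` is for pathway curators and systems biologists who draw such
diagrams (typically in yEd-style editors) and want to treat them as formal
objects: parse their component labels, lint them against the notation's
syntax rules, exchange them as GraphML, translate them into 3D scene
records, and convert them into executable Petri nets.

## What it does

* **Typed graph model** — `PathwayGraph` with nodes classified against a
  glyph registry (31 process classes by default, every code 1–3 characters),
  explicit compartment membership, directed interaction edges and undirected
  physical-bond edges.
* **Label grammar** — complex labels like
  `IFNGR1<2>:IFNGR2<2>:JAK1<2>:JAK2<2>` parse into subunits with aliases
  `(li)`, stoichiometry `<2>` (or `<n>` when unknown) and state modifications
  `[P]`, `[Ub]`, `[P-L232]`; serialization is a grammar fixed point, and a
  canonical identity key (symbol + state, aliases dropped) backs the
  uniqueness rule.
* **Validator** — nine documented rules (`R1_UNIQUE_PER_COMPARTMENT` …
  `R9_OUTPUT_IS_SINK`): one instance per component per compartment (ions
  exempt, states distinct), process arity conventions (binding: many-in /
  one-out; dissociation the reverse), annotation-node degree, bond legality,
  energy-node attachment, Boolean wiring, gene placement, label
  well-formedness, output terminality. Deterministic issue lists, text or
  JSON reports.
* **GraphML interchange** — plain (typed attributes) and editor (yFiles-style
  shapes/colours/geometry/groups) dialects; byte-deterministic writes;
  foreign editor files are classified by shape + printed code (never by
  colour alone), with group nodes becoming compartments and arrowless edges
  physical bonds.
* **Petri-net conversion & token flow** — components become places, process
  nodes transitions, AND folds into multi-input arcs, OR replicates
  transitions per branch, catalysts/activators become read arcs, inhibitors
  become hard-blocking inhibitor arcs, energy nodes read-arc side conditions.
  A seeded, structure-only stochastic token-flow simulator (signalling
  Petri-net style, no kinetic parameters) estimates information flow.
* **Worked-example fixtures** — programmatic reconstructions of the
  notation's published demonstrations, including the complete
  IFNγ → MHC class II antigen-presentation pathway.

## Worked example

The IFNγ pathway fixture encodes, node by node, the signalling chain from
interferon-gamma release to MHC class II antigen presentation: ligand
dimerisation, receptor binding, JAK2 autophosphorylation with SOCS1/SOCS3 OR
feedback inhibition and PTPN2 reversal, STAT1 activation and nuclear
translocation, CIITA induction by the pIV and pIII enhancer complexes, and
expression of the MHC class II gene battery.

```python
from mepnkit import parse_component_label, validate
from mepnkit.fixtures import (build_ifng_mhc2_pathway, ifng_marking,
                              MHC2_OUTPUT_NODE)
from mepnkit.petri import to_petri_net, simulate

spec = parse_component_label("IFNGR1<2>:IFNGR2<2>:JAK1<2>:JAK2<2>")
print([(s.symbol, s.stoichiometry) for s in spec.subunits])
# [('IFNGR1', 2), ('IFNGR2', 2), ('JAK1', 2), ('JAK2', 2)]

graph = build_ifng_mhc2_pathway()
print(len(graph.nodes), len(graph.edges), len(graph.compartments))
# 63 69 4           (nodes, edges, compartments)
print(validate(graph))
# []                (the diagram is conformant)

net = to_petri_net(graph)
print(len(net.places), len(net.transitions), len(net.arcs))
# 41 29 76          (bipartite by construction)

out = f"p:{MHC2_OUTPUT_NODE}"
stim = simulate(net, ifng_marking(net), steps=60, runs=20, seed=1)
print(stim.final_mean(out))
# 49.55             (mean tokens at the antigen-presentation output)

blocked = simulate(net, ifng_marking(net, socs1_tokens=3),
                   steps=60, runs=20, seed=1)
print(blocked.final_mean(out))
# 0.0               (constitutive SOCS1 silences the pathway)
```

The token counts are structure-only activity estimates: with ligand present
the output place steadily accumulates tokens; pre-loading the SOCS1 place
hard-blocks receptor activation through the OR-derived inhibitor arcs, so
the output never fires — mirroring the biology of the feedback loop.

## Command line

```bash
mepn examples --out-dir examples       # write fixture GraphML files
mepn validate examples/ifng_mhc2.graphml
mepn stats examples/ifng_mhc2.graphml --format json
mepn convert examples/ifng_mhc2.graphml petri --out net.graphml
mepn convert examples/ifng_mhc2.graphml layout3d
mepn simulate examples/ifng_mhc2.graphml --steps 60 --runs 20 --seed 1 \
     --ifng-defaults
mepn rules R1_UNIQUE_PER_COMPARTMENT
```

Exit codes: 0 clean, 1 validation errors, 2 usage/I-O errors.

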