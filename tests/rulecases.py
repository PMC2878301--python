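"""Minimal violating / conforming graph pairs, one per validator rule.

Shared between the validator unit tests and the acceptance suite. Each
builder returns a small PathwayGraph; ``VIOLATING[rule_id]`` graphs raise
exactly that rule (at its default severity), ``CONFORMING[rule_id]`` graphs
exercise the same construct legally.
"""

from mepnkit.model import Compartment, NodeClass, PathwayGraph, PathwayNode, create_pathway


def _comp(nid, label, compartment=None, subclass="protein", **kw):
    return PathwayNode(nid, NodeClass("component", subclass), label,
                       compartment=compartment, **kw)


def _node(nid, kind, subclass, **kw):
    return PathwayNode(nid, NodeClass(kind, subclass), **kw)


def _base() -> PathwayGraph:
    g = create_pathway("case")
    g.add_compartment(Compartment("cytoplasm", "cytoplasm"))
    g.add_compartment(Compartment("nucleus", "nucleus"))
    return g


def r1_bad():
    g = _base()
    g.add_node(_comp("a", "STAT1", "cytoplasm"))
    g.add_node(_comp("b", "STAT1", "cytoplasm"))
    return g


def r1_good():
    # distinct states, distinct compartments, and a thrice-repeated ion
    g = _base()
    g.add_node(_comp("a", "STAT1", "cytoplasm"))
    g.add_node(_comp("b", "STAT1 [P]", "cytoplasm"))
    g.add_node(_comp("c", "STAT1", "nucleus"))
    for i in range(3):
        g.add_node(_comp(f"w{i}", "H2O", "cytoplasm", subclass="ion_simple_molecule"))
    return g


def r2_bad():
    # binding node with a single component input
    g = _base()
    g.add_node(_comp("a", "A", "cytoplasm"))
    g.add_node(_comp("ab", "A:B", "cytoplasm", subclass="protein_complex"))
    g.add_node(_node("p", "process", "B"))
    g.connect("a", "p")
    g.connect("p", "ab")
    return g


def r2_good():
    g = _base()
    g.add_node(_comp("a", "A", "cytoplasm"))
    g.add_node(_comp("b", "B", "cytoplasm"))
    g.add_node(_comp("ab", "A:B", "cytoplasm", subclass="protein_complex"))
    g.add_node(_node("p", "process", "B"))
    g.connect("a", "p")
    g.connect("b", "p")
    g.connect("p", "ab")
    return g


def r3_bad():
    # two outputs without the distribution flag
    g = _base()
    g.add_node(_comp("tf", "TF1", "nucleus"))
    g.add_node(_comp("g1", "G1", "nucleus", subclass="gene"))
    g.add_node(_comp("g2", "G2", "nucleus", subclass="gene"))
    g.add_node(_node("ann", "edge_annotation", "A"))
    g.connect("tf", "ann")
    g.connect("ann", "g1")
    g.connect("ann", "g2")
    return g


def r3_good():
    g = r3_bad()
    g.remove_node("ann")
    g.add_node(_node("ann", "edge_annotation", "A", is_distribution=True))
    g.connect("tf", "ann")
    g.connect("ann", "g1")
    g.connect("ann", "g2")
    return g


def r4_bad():
    # a properly wired process that additionally carries an illegal bond
    g = _base()
    g.add_node(_comp("a", "A", "cytoplasm"))
    g.add_node(_comp("ap", "A [P]", "cytoplasm"))
    g.add_node(_node("p", "process", "P"))
    g.connect("a", "p")
    g.connect("p", "ap")
    g.connect("a", "p", directed=False)
    return g


def r4_good():
    g = _base()
    g.add_node(_comp("a", "A", "cytoplasm"))
    g.add_node(_comp("b", "B", "cytoplasm"))
    g.connect("a", "b", directed=False)
    return g


def r5_bad():
    # energy node wired to a component instead of its process
    g = _base()
    g.add_node(_comp("a", "A", "cytoplasm"))
    g.add_node(_node("e", "energy_transfer", "energy_transfer", label="ATP -> ADP"))
    g.connect("e", "a")
    return g


def r5_good():
    g = _base()
    g.add_node(_comp("a", "A", "cytoplasm"))
    g.add_node(_comp("at", "A [t]", "cytoplasm"))
    g.add_node(_node("x", "process", "X"))
    g.add_node(_node("e", "energy_transfer", "energy_transfer", label="ATP -> ADP"))
    g.connect("a", "x")
    g.connect("x", "at")
    g.connect("e", "x")
    return g


def r6_bad():
    # AND with one input
    g = _base()
    g.add_node(_comp("a", "A", "cytoplasm"))
    g.add_node(_comp("b", "B", "cytoplasm"))
    g.add_node(_node("and1", "boolean_operator", "AND"))
    g.add_node(_node("p", "process", "P"))
    g.connect("a", "and1")
    g.connect("and1", "p")
    g.connect("b", "p")
    g.add_node(_comp("bp", "B [P]", "cytoplasm"))
    g.connect("p", "bp")
    return g


def r6_good():
    g = _base()
    g.add_node(_comp("a", "A", "cytoplasm"))
    g.add_node(_comp("a2", "A2", "cytoplasm"))
    g.add_node(_comp("b", "B", "cytoplasm"))
    g.add_node(_comp("bp", "B [P]", "cytoplasm"))
    g.add_node(_node("and1", "boolean_operator", "AND"))
    g.add_node(_node("p", "process", "P"))
    g.connect("a", "and1")
    g.connect("a2", "and1")
    g.connect("and1", "p")
    g.connect("b", "p")
    g.connect("p", "bp")
    return g


def r7_bad():
    g = _base()
    g.add_node(_comp("g1", "IRF1", "cytoplasm", subclass="gene"))
    return g


def r7_good():
    g = _base()
    g.add_node(_comp("g1", "IRF1", "nucleus", subclass="gene"))
    return g


def r8_bad():
    g = _base()
    node = PathwayNode("a", NodeClass("component", "protein"), "A [",
                       parsed_label=None)
    # bypass eager parsing to model a hand-drawn file with a broken label
    g._nodes["a"] = node
    return g


def r8_good():
    g = _base()
    g.add_node(_comp("a", "STAT1 [P] [P-L232]", "cytoplasm"))
    return g


def r9_bad():
    g = _base()
    g.add_node(_comp("a", "A", "cytoplasm"))
    g.add_node(_node("out", "pathway_output", "pathway_output",
                     label="some outcome"))
    g.connect("a", "out")
    g.connect("out", "a")
    return g


def r9_good():
    g = _base()
    g.add_node(_comp("a", "A", "cytoplasm"))
    g.add_node(_node("out", "pathway_output", "pathway_output",
                     label="some outcome"))
    g.connect("a", "out", style="light_blue")
    return g


VIOLATING = {
    "R1_UNIQUE_PER_COMPARTMENT": r1_bad,
    "R2_PROCESS_ARITY": r2_bad,
    "R3_ANNOTATION_DEGREE": r3_bad,
    "R4_PHYSICAL_BONDS": r4_bad,
    "R5_ENERGY_ATTACHMENT": r5_bad,
    "R6_BOOLEAN_WIRING": r6_bad,
    "R7_GENE_IN_NUCLEUS": r7_bad,
    "R8_LABEL_GRAMMAR": r8_bad,
    "R9_OUTPUT_IS_SINK": r9_bad,
}

CONFORMING = {
    "R1_UNIQUE_PER_COMPARTMENT": r1_good,
    "R2_PROCESS_ARITY": r2_good,
    "R3_ANNOTATION_DEGREE": r3_good,
    "R4_PHYSICAL_BONDS": r4_good,
    "R5_ENERGY_ATTACHMENT": r5_good,
    "R6_BOOLEAN_WIRING": r6_good,
    "R7_GENE_IN_NUCLEUS": r7_good,
    "R8_LABEL_GRAMMAR": r8_good,
    "R9_OUTPUT_IS_SINK": r9_good,
}
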