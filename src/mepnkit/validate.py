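"""Rule-based mEPN diagram validator.

Checks a :class:`~mepnkit.model.PathwayGraph` against the notation's syntax
rules and returns structured, deterministic diagnostics. The rule catalogue:

========================  =======================================================
R1_UNIQUE_PER_COMPARTMENT A component appears at most once per compartment,
                          except ions/simple molecules (ubiquitous species may
                          repeat) and except distinct modification states.
R2_PROCESS_ARITY          Process in/out degree on the component path lies in
                          the registry class bounds (binding: many-in/one-out,
                          dissociation the reverse).
R3_ANNOTATION_DEGREE      Edge-annotation nodes have exactly 1 input and 1
                          output unless flagged as distribution nodes.
R4_PHYSICAL_BONDS         Undirected (bond) edges connect component nodes only.
R5_ENERGY_ATTACHMENT      Energy/molecular-transfer nodes attach only to
                          process nodes.
R6_BOOLEAN_WIRING         AND/OR take >=2 inputs and >=1 output; conditional
                          gates have >=2 outcome branches. A fan-out OR with a
                          single input is reported at info level only.
R7_GENE_IN_NUCLEUS        Gene components reside in a nuclear compartment
                          (warning by default — stated as a convention, not an
                          absolute).
R8_LABEL_GRAMMAR          Component labels parse under the grammar; unknown
                          edge-annotation codes are a warning.
R9_OUTPUT_IS_SINK         Pathway-output nodes are terminal (no outgoing edges).
========================  =======================================================

An empty issue list means the diagram is conformant under the active ruleset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .labels import LabelError, canonical_identity, parse_component_label
from .model import PathwayGraph, PathwayNode
from .registry import GlyphRegistry

__all__ = [
    "ValidationIssue",
    "RuleSet",
    "RuleDoc",
    "validate",
    "explain_rule",
    "RULE_IDS",
]

SEVERITIES = ("error", "warning", "info")


@dataclass(frozen=True)
class ValidationIssue:
    rule_id: str
    severity: str
    subject_ids: Tuple[str, ...]
    message: str

    def to_dict(self) -> Dict[str, object]:
        return {
            "rule_id": self.rule_id,
            "severity": self.severity,
            "subjects": list(self.subject_ids),
            "message": self.message,
        }


@dataclass(frozen=True)
class RuleDoc:
    rule_id: str
    text: str
    rationale: str
    default_severity: str


_RULE_DOCS: Dict[str, RuleDoc] = {
    d.rule_id: d
    for d in [
        RuleDoc(
            "R1_UNIQUE_PER_COMPARTMENT",
            "A component (same symbol and modification state) may be drawn at most "
            "once in any one cellular compartment; small ubiquitous ions and simple "
            "molecules are exempt, and distinct states count as distinct components.",
            "Keeping one instance per compartment makes a node's edge count an exact "
            "readout of its known connections, with no need to scan for duplicates.",
            "error",
        ),
        RuleDoc(
            "R2_PROCESS_ARITY",
            "A process node's component-path in/out degree must lie within its "
            "class's arity bounds: a binding node has multiple inputs and one "
            "output, a dissociation node one input and multiple outputs.",
            "Arity conventions are what make process junctions readable and "
            "convertible to transitions.",
            "error",
        ),
        RuleDoc(
            "R3_ANNOTATION_DEGREE",
            "An in-line edge-annotation node has exactly one input and one output, "
            "unless it is deliberately used as a distribution node fanning one "
            "influence out to several targets.",
            "Annotation nodes stand in for arrowhead styles; a stray extra edge "
            "usually signals a drawing slip rather than intent.",
            "warning",
        ),
        RuleDoc(
            "R4_PHYSICAL_BONDS",
            "Undirected edges depict physical covalent or non-covalent bonds and "
            "may only join component nodes.",
            "A bond to a process or operator has no physical meaning.",
            "error",
        ),
        RuleDoc(
            "R5_ENERGY_ATTACHMENT",
            "Energy/molecular-transfer nodes (ATP→ADP, GTP→GDP, …) are linked "
            "directly to the process node they drive, and to nothing else.",
            "They are co-reaction side conditions of a process, not free-standing "
            "components.",
            "error",
        ),
        RuleDoc(
            "R6_BOOLEAN_WIRING",
            "AND and OR operators take two or more inputs and at least one output; "
            "conditional gates offer two or more outcome branches. An OR with one "
            "input (fan-out usage) is noted at info level.",
            "Boolean operators express co-dependency between multiple inputs; with "
            "fewer connections the construct is vacuous.",
            "error",
        ),
        RuleDoc(
            "R7_GENE_IN_NUCLEUS",
            "Gene-class components are expected in a nuclear compartment.",
            "Genes live on chromatin; the rule is a convention (hence a warning by "
            "default) since e.g. pathogen or organellar genomes may appear elsewhere.",
            "warning",
        ),
        RuleDoc(
            "R8_LABEL_GRAMMAR",
            "Every component label must parse under the mEPN label grammar; edge "
            "annotation codes should be registered (unknown codes are a warning, "
            "since the code table is open-ended).",
            "Well-formed labels are what make identity, overlay of data and "
            "conversion to formal models possible.",
            "error",
        ),
        RuleDoc(
            "R9_OUTPUT_IS_SINK",
            "Pathway-output nodes summarise the end of a pathway and must have no "
            "outgoing edges.",
            "An output with successors is not an output.",
            "error",
        ),
    ]
}

RULE_IDS: Tuple[str, ...] = tuple(sorted(_RULE_DOCS))


class UnknownRuleError(KeyError):
    def __init__(self, rule_id: str):
        super().__init__(rule_id)
        self.rule_id = rule_id

    def __str__(self) -> str:
        return f"unknown rule id {self.rule_id!r}"


@dataclass(frozen=True)
class RuleSet:
    """Which rules run, at what severity, with which exemptions.

    ``uniqueness_exempt_classes`` extends the component subclasses R1 skips;
    ``severity_overrides`` maps rule id → severity.
    """

    enabled: Tuple[str, ...] = RULE_IDS
    severity_overrides: Dict[str, str] = field(default_factory=dict)
    uniqueness_exempt_classes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for rid in list(self.enabled) + list(self.severity_overrides):
            if rid not in _RULE_DOCS:
                raise UnknownRuleError(rid)
        for sev in self.severity_overrides.values():
            if sev not in SEVERITIES:
                raise ValueError(f"unknown severity {sev!r}")

    def severity(self, rule_id: str, default: Optional[str] = None) -> str:
        return self.severity_overrides.get(
            rule_id, default or _RULE_DOCS[rule_id].default_severity
        )


def explain_rule(rule_id: str) -> RuleDoc:
    """Documentation record for one rule (used by CLI help and reports)."""
    try:
        return _RULE_DOCS[rule_id]
    except KeyError:
        raise UnknownRuleError(rule_id) from None


# ------------------------------------------------------------------ helpers


def _is_nuclear(graph: PathwayGraph, comp_id: Optional[str]) -> bool:
    seen = set()
    while comp_id is not None and comp_id not in seen:
        seen.add(comp_id)
        comp = graph.compartments.get(comp_id)
        if comp is None:
            return False
        if "nucle" in comp.name.lower() or "nucle" in comp.id.lower():
            return True
        comp_id = comp.parent
    return False


def _component_path_degrees(graph: PathwayGraph, node_id: str) -> Tuple[int, int]:
    """In/out degree of a process node counting only the component path:
    unannotated directed edges whose far end is a component, module or output.
    Catalytic/annotated inputs, Boolean constructs and energy-transfer side
    conditions do not count against arity."""
    path_kinds = {"component", "pathway_module", "pathway_output", "edge_annotation"}
    n_in = 0
    for e in graph.in_edges(node_id):
        src = graph.node(e.source)
        if e.annotation is None and src.node_class.kind in {"component", "pathway_module"}:
            n_in += 1
    n_out = 0
    for e in graph.out_edges(node_id):
        tgt = graph.node(e.target)
        if e.annotation is None and tgt.node_class.kind in path_kinds:
            n_out += 1
    return n_in, n_out


# ------------------------------------------------------------------ rules


def _r1(graph: PathwayGraph, registry: GlyphRegistry, rules: RuleSet):
    exempt = {"ion_simple_molecule", *rules.uniqueness_exempt_classes}
    groups: Dict[Tuple[Optional[str], str], List[str]] = {}
    for node in graph.iter_nodes():
        if node.node_class.kind != "component" or node.node_class.subclass in exempt:
            continue
        if node.parsed_label is None:
            continue  # R8 reports the parse failure
        # the subclass is part of the key: a gene and the protein it encodes
        # legitimately share a symbol without being the same component
        key = (node.compartment, node.node_class.subclass,
               canonical_identity(node.parsed_label))
        groups.setdefault(key, []).append(node.id)
    for (comp, _sub, ident), ids in sorted(groups.items(), key=lambda kv: kv[1]):
        if len(ids) > 1:
            yield ValidationIssue(
                "R1_UNIQUE_PER_COMPARTMENT",
                rules.severity("R1_UNIQUE_PER_COMPARTMENT"),
                tuple(ids),
                f"component {ident!r} appears {len(ids)} times in compartment "
                f"{comp!r}; one instance per compartment is allowed",
            )


def _r2(graph: PathwayGraph, registry: GlyphRegistry, rules: RuleSet):
    for node in graph.iter_nodes():
        if node.node_class.kind != "process":
            continue
        pc = registry.process_classes.get(node.node_class.subclass)
        if pc is None:
            continue  # unregistered code caught at add_node / R8 family
        n_in, n_out = _component_path_degrees(graph, node.id)
        # inputs routed through a Boolean operator satisfy the minimum
        bool_in = any(
            graph.node(e.source).node_class.kind == "boolean_operator"
            for e in graph.in_edges(node.id)
        )
        ok_in = (pc.min_inputs <= n_in <= pc.max_inputs) or (bool_in and n_in <= pc.max_inputs)
        ok_out = pc.min_outputs <= n_out <= pc.max_outputs
        if not (ok_in and ok_out):
            yield ValidationIssue(
                "R2_PROCESS_ARITY",
                rules.severity("R2_PROCESS_ARITY"),
                (node.id,),
                f"process {node.id!r} ({pc.code}, {pc.name}) has {n_in} component "
                f"input(s) and {n_out} output(s); expected "
                f"[{pc.min_inputs},{pc.max_inputs}] in / "
                f"[{pc.min_outputs},{pc.max_outputs}] out",
            )


def _r3(graph: PathwayGraph, registry: GlyphRegistry, rules: RuleSet):
    for node in graph.iter_nodes():
        if node.node_class.kind != "edge_annotation":
            continue
        n_in = len(graph.in_edges(node.id))
        n_out = len(graph.out_edges(node.id))
        if node.is_distribution:
            bad = n_in != 1 or n_out < 1
        else:
            bad = n_in != 1 or n_out != 1
        if bad:
            yield ValidationIssue(
                "R3_ANNOTATION_DEGREE",
                rules.severity("R3_ANNOTATION_DEGREE"),
                (node.id,),
                f"edge-annotation node {node.id!r} has {n_in} input(s) and "
                f"{n_out} output(s); expected exactly 1/1 unless flagged as a "
                "distribution node",
            )


def _r4(graph: PathwayGraph, registry: GlyphRegistry, rules: RuleSet):
    for edge in graph.iter_edges():
        if edge.directed:
            continue
        kinds = {graph.node(edge.source).node_class.kind,
                 graph.node(edge.target).node_class.kind}
        if kinds - {"component"}:
            yield ValidationIssue(
                "R4_PHYSICAL_BONDS",
                rules.severity("R4_PHYSICAL_BONDS"),
                (edge.id,),
                f"physical-bond edge {edge.id!r} touches a non-component node; "
                "bonds join components only",
            )


def _r5(graph: PathwayGraph, registry: GlyphRegistry, rules: RuleSet):
    for node in graph.iter_nodes():
        if node.node_class.kind != "energy_transfer":
            continue
        neighbours = [graph.node(e.target) for e in graph.out_edges(node.id)]
        neighbours += [graph.node(e.source) for e in graph.in_edges(node.id)]
        neighbours += [
            graph.node(e.source if e.target == node.id else e.target)
            for e in graph.bond_edges(node.id)
        ]
        if not neighbours or any(n.node_class.kind != "process" for n in neighbours):
            yield ValidationIssue(
                "R5_ENERGY_ATTACHMENT",
                rules.severity("R5_ENERGY_ATTACHMENT"),
                (node.id,),
                f"energy-transfer node {node.id!r} must connect only to the "
                "process node(s) it drives",
            )


def _r6(graph: PathwayGraph, registry: GlyphRegistry, rules: RuleSet):
    for node in graph.iter_nodes():
        kind, sub = node.node_class.kind, node.node_class.subclass
        if kind == "boolean_operator" and sub in ("AND", "OR"):
            n_in = len(graph.in_edges(node.id))
            n_out = len(graph.out_edges(node.id))
            if sub == "OR" and n_in == 1 and n_out >= 1:
                yield ValidationIssue(
                    "R6_BOOLEAN_WIRING", "info", (node.id,),
                    f"OR node {node.id!r} has a single input (fan-out usage); "
                    "legal but worth a look",
                )
            elif n_in < 2 or n_out < 1:
                yield ValidationIssue(
                    "R6_BOOLEAN_WIRING",
                    rules.severity("R6_BOOLEAN_WIRING"),
                    (node.id,),
                    f"{sub} operator {node.id!r} has {n_in} input(s) and {n_out} "
                    "output(s); expected >=2 inputs and >=1 output",
                )
        elif kind == "conditional_gate":
            n_out = len(graph.out_edges(node.id))
            if n_out < 2:
                yield ValidationIssue(
                    "R6_BOOLEAN_WIRING",
                    rules.severity("R6_BOOLEAN_WIRING"),
                    (node.id,),
                    f"conditional gate {node.id!r} has {n_out} outcome branch(es); "
                    "a gate needs two or more possible outcomes",
                )


def _r7(graph: PathwayGraph, registry: GlyphRegistry, rules: RuleSet):
    for node in graph.iter_nodes():
        if node.node_class.kind == "component" and node.node_class.subclass == "gene":
            if not _is_nuclear(graph, node.compartment):
                yield ValidationIssue(
                    "R7_GENE_IN_NUCLEUS",
                    rules.severity("R7_GENE_IN_NUCLEUS"),
                    (node.id,),
                    f"gene {node.label!r} ({node.id}) sits in compartment "
                    f"{node.compartment!r}; genes are expected in the nucleus",
                )


def _r8(graph: PathwayGraph, registry: GlyphRegistry, rules: RuleSet):
    for node in graph.iter_nodes():
        if node.node_class.kind != "component":
            continue
        if node.parsed_label is not None:
            continue
        try:
            parse_component_label(node.label)
        except LabelError as exc:
            yield ValidationIssue(
                "R8_LABEL_GRAMMAR",
                rules.severity("R8_LABEL_GRAMMAR"),
                (node.id,),
                f"label {node.label!r} does not parse: {exc}",
            )
    known = set(registry.edge_annotations)
    for edge in graph.iter_edges():
        if edge.annotation is not None and edge.annotation not in known:
            yield ValidationIssue(
                "R8_LABEL_GRAMMAR", "warning", (edge.id,),
                f"edge {edge.id!r} carries unregistered annotation code "
                f"{edge.annotation!r}",
            )
    for node in graph.iter_nodes():
        if node.node_class.kind == "edge_annotation" and node.node_class.subclass not in known:
            yield ValidationIssue(
                "R8_LABEL_GRAMMAR", "warning", (node.id,),
                f"annotation node {node.id!r} carries unregistered code "
                f"{node.node_class.subclass!r}",
            )


def _r9(graph: PathwayGraph, registry: GlyphRegistry, rules: RuleSet):
    for node in graph.iter_nodes():
        if node.node_class.kind != "pathway_output":
            continue
        outs = graph.out_edges(node.id)
        if outs:
            yield ValidationIssue(
                "R9_OUTPUT_IS_SINK",
                rules.severity("R9_OUTPUT_IS_SINK"),
                (node.id, *sorted(e.id for e in outs)),
                f"pathway-output node {node.id!r} has outgoing edges; outputs "
                "terminate a pathway",
            )


_RULE_FUNCS = {
    "R1_UNIQUE_PER_COMPARTMENT": _r1,
    "R2_PROCESS_ARITY": _r2,
    "R3_ANNOTATION_DEGREE": _r3,
    "R4_PHYSICAL_BONDS": _r4,
    "R5_ENERGY_ATTACHMENT": _r5,
    "R6_BOOLEAN_WIRING": _r6,
    "R7_GENE_IN_NUCLEUS": _r7,
    "R8_LABEL_GRAMMAR": _r8,
    "R9_OUTPUT_IS_SINK": _r9,
}


def validate(
    graph: PathwayGraph,
    registry: Optional[GlyphRegistry] = None,
    rules: Optional[RuleSet] = None,
) -> List[ValidationIssue]:
    """Run the rule catalogue over a graph.

    Always returns a list (label parse failures become issues, never
    exceptions), deterministically sorted by rule id then subject ids. An
    empty list means the diagram conforms under the given ruleset.
    """
    registry = registry or graph.registry
    rules = rules or RuleSet()
    issues: List[ValidationIssue] = []
    for rid in sorted(rules.enabled):
        issues.extend(_RULE_FUNCS[rid](graph, registry, rules))
    issues.sort(key=lambda i: (i.rule_id, i.subject_ids))
    return issues


def has_errors(issues: Sequence[ValidationIssue]) -> bool:
    return any(i.severity == "error" for i in issues)
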