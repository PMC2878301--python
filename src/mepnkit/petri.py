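"""Conversion of pathway diagrams to Petri nets and token-flow simulation.

An mEPN diagram is drawn so that it can be read as a bipartite net: components
(and pathway outputs/modules) become *places* that hold tokens, process nodes
become *transitions* that move them, and edges become *arcs*. Boolean
constructs translate structurally:

* an AND operator folds away — its downstream transition gains one input arc
  per AND input, so the reaction proceeds only when every input holds a token;
* an OR operator replicates the downstream transition, one copy per input
  branch, all feeding the same output place — any one branch suffices;
* edges annotated A (activation) or C (catalysis) give the regulator a *read*
  arc: its presence is required but its tokens are not consumed;
* edges annotated I (inhibition) give the regulator an *inhibitor* arc onto
  the transition(s) producing the target — any token there hard-blocks firing;
* energy/molecular-transfer nodes become read-arc side conditions of their
  process transition;
* conditional gates become one transition per outcome branch, grouped so that
  exactly one randomly chosen enabled branch fires per step;
* undirected physical bonds are structural only and contribute no arcs.

The simulator implements SPN-style stochastic token flow: no kinetic
parameters, unit-weight firing, outcomes determined by network structure and
a seeded random firing order. Identical inputs and seed give identical
trajectories.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .model import PathwayGraph
from .validate import ValidationIssue, has_errors, validate

__all__ = [
    "PetriNetError",
    "Arc",
    "PetriNet",
    "TokenTrajectory",
    "to_petri_net",
    "simulate",
    "petri_to_graphml",
    "arc_table",
    "trajectory_table",
]

NORMAL, INHIBITOR, READ = "normal", "inhibitor", "read"
_PLACE_KINDS = {"component", "pathway_output", "pathway_module", "energy_transfer"}


class PetriNetError(ValueError):
    """Conversion or simulation contract violation."""

    def __init__(self, message: str, issues: Sequence[ValidationIssue] = ()):
        super().__init__(message)
        self.issues = list(issues)


@dataclass(frozen=True)
class Arc:
    """One arc. ``normal`` arcs run place→transition (consuming) or
    transition→place (producing); ``read`` and ``inhibitor`` arcs always run
    place→transition and never move tokens."""

    source: str
    target: str
    kind: str = NORMAL


@dataclass
class PetriNet:
    """Bipartite place/transition net with provenance back to the diagram."""

    places: Dict[str, str] = field(default_factory=dict)  # place id -> node id
    transitions: Dict[str, str] = field(default_factory=dict)  # trans id -> elem id
    arcs: List[Arc] = field(default_factory=list)
    gate_groups: Dict[str, str] = field(default_factory=dict)  # trans id -> group

    def provenance(self, element_id: str) -> str:
        if element_id in self.places:
            return self.places[element_id]
        if element_id in self.transitions:
            return self.transitions[element_id]
        raise KeyError(element_id)

    def is_bipartite(self) -> bool:
        for a in self.arcs:
            s_place = a.source in self.places
            t_place = a.target in self.places
            if s_place == t_place:
                return False
            if not (a.source in self.places or a.source in self.transitions):
                return False
            if not (a.target in self.places or a.target in self.transitions):
                return False
        return True

    def place_for_node(self, node_id: str) -> str:
        pid = f"p:{node_id}"
        if pid not in self.places:
            raise KeyError(f"no place for node {node_id!r}")
        return pid


@dataclass(frozen=True)
class TokenTrajectory:
    """Per-step, per-place mean token counts over simulation runs.

    ``means`` has shape ``(steps + 1, n_places)``; row 0 is the initial
    marking and row ``k`` the state after step ``k``.
    """

    places: Tuple[str, ...]
    means: np.ndarray
    steps: int
    runs: int
    seed: int

    def final_mean(self, place_id: str) -> float:
        return float(self.means[-1, self.places.index(place_id)])


# ------------------------------------------------------------- conversion


class _Builder:
    def __init__(self, graph: PathwayGraph):
        self.g = graph
        self.net = PetriNet()
        # deferred inhibitions: (regulator place, target) where target is a
        # transition id, a process node id, or a component place id
        self.inhibit_place_targets: List[Tuple[str, str]] = []
        self.inhibit_trans_targets: List[Tuple[str, str]] = []

    # -- helpers

    def place(self, node_id: str) -> str:
        return f"p:{node_id}"

    def _annotation_of(self, edge) -> Optional[str]:
        return edge.annotation

    def _expand_source(self, edge) -> List[List[Tuple[str, str]]]:
        """Resolve one in-edge of a transition-bearing node into alternative
        arc bundles: a list of branches (OR alternatives), each branch a list
        of (place id, arc kind) pairs."""
        src = self.g.node(edge.source)
        kind = src.node_class.kind
        ann = edge.annotation
        arc_kind = {None: NORMAL, "C": READ, "A": READ, "I": INHIBITOR}.get(ann, READ)
        if kind in _PLACE_KINDS:
            if kind == "energy_transfer":
                arc_kind = READ
            return [[(self.place(src.id), arc_kind)]]
        if kind == "boolean_operator":
            inputs = self.g.in_edges(src.id)
            bundles: List[List[Tuple[str, str]]] = []
            sub = src.node_class.subclass
            if sub in ("AND", "OR") and arc_kind == INHIBITOR:
                # De Morgan under hard-block semantics: "SOCS1 OR SOCS3
                # inhibits" blocks on either token, i.e. all inhibitor arcs on
                # one transition; "A AND B inhibit" blocks only when both are
                # present, i.e. one singly-inhibited replica per input.
                sub = "AND" if sub == "OR" else "OR"
            if sub == "AND":
                combo: List[Tuple[str, str]] = []
                for e in inputs:
                    for branch in self._expand_source(e):
                        # ANDs of ORs: flattened conjunction
                        combo.extend(
                            (pid, arc_kind if k == NORMAL else k) for pid, k in branch
                        )
                return [combo]
            if sub == "OR":
                for e in inputs:
                    for branch in self._expand_source(e):
                        bundles.append(
                            [(pid, arc_kind if k == NORMAL else k) for pid, k in branch]
                        )
                return bundles or [[]]
            # NOT: every input becomes an inhibitor side condition
            combo = []
            for e in inputs:
                for branch in self._expand_source(e):
                    combo.extend((pid, INHIBITOR) for pid, _ in branch)
            return [combo]
        if kind == "edge_annotation":
            code = src.node_class.subclass
            inner_kind = INHIBITOR if code == "I" else READ
            combo = []
            for e in self.g.in_edges(src.id):
                for branch in self._expand_source(e):
                    combo.extend((pid, inner_kind) for pid, _ in branch)
            return [combo]
        return [[]]

    def _resolve_targets(self, node_id: str, seen=None) -> List[str]:
        """Follow out-edges through annotation nodes to the final places."""
        seen = seen or set()
        out: List[str] = []
        for e in self.g.out_edges(node_id):
            tgt = self.g.node(e.target)
            if tgt.node_class.kind in _PLACE_KINDS:
                out.append(self.place(tgt.id))
            elif tgt.node_class.kind == "edge_annotation" and tgt.id not in seen:
                out.extend(self._resolve_targets(tgt.id, seen | {tgt.id}))
        return out

    def add_transition(
        self,
        tid: str,
        provenance: str,
        inputs: Iterable[Tuple[str, str]],
        outputs: Iterable[str],
        gate_group: Optional[str] = None,
    ) -> None:
        self.net.transitions[tid] = provenance
        if gate_group:
            self.net.gate_groups[tid] = gate_group
        for pid, kind in inputs:
            if kind == INHIBITOR:
                self.inhibit_trans_targets.append((pid, tid))
            else:
                self.net.arcs.append(Arc(pid, tid, kind))
        for pid in outputs:
            self.net.arcs.append(Arc(tid, pid))

    # -- passes

    def build(self) -> PetriNet:
        for node in self.g.iter_nodes():
            if node.node_class.kind in _PLACE_KINDS:
                self.net.places[self.place(node.id)] = node.id

        for node in self.g.iter_nodes():
            kind = node.node_class.kind
            if kind == "process":
                self._convert_process(node)
            elif kind == "conditional_gate":
                self._convert_gate(node)
            elif kind == "edge_annotation":
                self._convert_annotation_node(node)

        self._convert_plain_and_annotated_edges()
        self._apply_deferred_inhibitions()
        return self.net

    def _convert_process(self, node) -> None:
        branch_sets: List[List[List[Tuple[str, str]]]] = [
            self._expand_source(e) for e in self.g.in_edges(node.id)
        ]
        outputs = self._resolve_targets(node.id)
        alternatives = [list(combo) for combo in itertools.product(*branch_sets)] or [[]]
        multi = len(alternatives) > 1
        for i, combo in enumerate(alternatives):
            inputs = [pair for branch in combo for pair in branch]
            tid = f"t:{node.id}#or{i}" if multi else f"t:{node.id}"
            self.add_transition(tid, node.id, inputs, outputs)

    def _convert_gate(self, node) -> None:
        gate_inputs = [
            pair
            for e in self.g.in_edges(node.id)
            for branch in self._expand_source(e)
            for pair in branch
        ]
        for i, e in enumerate(sorted(self.g.out_edges(node.id), key=lambda e: e.id)):
            tgt = self.g.node(e.target)
            if tgt.node_class.kind not in _PLACE_KINDS:
                continue
            self.add_transition(
                f"t:{node.id}#branch{i}",
                node.id,
                gate_inputs,
                [self.place(tgt.id)],
                gate_group=node.id,
            )

    def _convert_annotation_node(self, node) -> None:
        code = node.node_class.subclass
        regulators = [
            pair
            for e in self.g.in_edges(node.id)
            for branch in self._expand_source(e)
            for pair in branch
        ]
        targets: List[Tuple[str, str]] = []  # (target node id, place or process)
        for e in self.g.out_edges(node.id):
            tgt = self.g.node(e.target)
            if tgt.node_class.kind in _PLACE_KINDS:
                targets.append((tgt.id, "place"))
            elif tgt.node_class.kind == "process":
                targets.append((tgt.id, "process"))
        if code == "I":
            for pid, _ in regulators:
                for tgt_id, tgt_kind in targets:
                    if tgt_kind == "place":
                        self.inhibit_place_targets.append((pid, self.place(tgt_id)))
                    else:
                        self.inhibit_trans_targets.append((pid, f"t:{tgt_id}"))
            return
        # A / C (and any open-ended code): read-gated implicit transitions
        for i, (tgt_id, tgt_kind) in enumerate(sorted(targets)):
            if tgt_kind != "place":
                continue  # regulator of a process: arcs added by the process pass
            self.add_transition(
                f"t:{node.id}#out{i}",
                node.id,
                [(pid, READ) for pid, _ in regulators],
                [self.place(tgt_id)],
            )

    def _convert_plain_and_annotated_edges(self) -> None:
        for edge in self.g.iter_edges():
            if not edge.directed:
                continue  # physical bond: structural only
            src = self.g.node(edge.source)
            tgt = self.g.node(edge.target)
            if src.node_class.kind not in _PLACE_KINDS or tgt.node_class.kind not in _PLACE_KINDS:
                continue
            if src.node_class.kind == "energy_transfer" or tgt.node_class.kind == "energy_transfer":
                continue
            sp, tp = self.place(src.id), self.place(tgt.id)
            if edge.annotation is None:
                # direct flow (e.g. into a pathway output or module)
                self.add_transition(f"t:edge:{edge.id}", edge.id, [(sp, NORMAL)], [tp])
            elif edge.annotation == "I":
                self.inhibit_place_targets.append((sp, tp))
            else:  # A, C and open-ended codes: read-gated production
                self.add_transition(f"t:edge:{edge.id}", edge.id, [(sp, READ)], [tp])

    def _apply_deferred_inhibitions(self) -> None:
        producers: Dict[str, List[str]] = {}
        for a in self.net.arcs:
            if a.kind == NORMAL and a.source in self.net.transitions:
                producers.setdefault(a.target, []).append(a.source)
        seen = set()
        for reg, place in self.inhibit_place_targets:
            for tid in producers.get(place, []):
                if (reg, tid) not in seen:
                    seen.add((reg, tid))
                    self.net.arcs.append(Arc(reg, tid, INHIBITOR))
        for reg, tid in self.inhibit_trans_targets:
            matching = [
                t for t in self.net.transitions
                if t == tid or t.startswith(tid + "#")
            ]
            for t in matching:
                if (reg, t) not in seen:
                    seen.add((reg, t))
                    self.net.arcs.append(Arc(reg, t, INHIBITOR))


def to_petri_net(graph: PathwayGraph, *, skip_validation: bool = False) -> PetriNet:
    """Convert a conformant pathway graph into a bipartite place/transition net.

    Refuses graphs whose validation reports error-severity issues (warnings
    are allowed); the raised :class:`PetriNetError` carries the issue list.
    The result is bipartite by construction and every element maps back to
    the diagram element it came from.
    """
    if not skip_validation:
        issues = validate(graph)
        if has_errors(issues):
            raise PetriNetError(
                f"graph has {sum(i.severity == 'error' for i in issues)} validation "
                "error(s); fix them before conversion",
                issues,
            )
    return _Builder(graph).build()


# ------------------------------------------------------------- simulation


def _compile(net: PetriNet):
    places = tuple(sorted(net.places))
    p_index = {p: i for i, p in enumerate(places)}
    trans = sorted(net.transitions)
    compiled = []
    for tid in trans:
        consume: Dict[int, int] = {}
        produce: Dict[int, int] = {}
        reads: List[int] = []
        inhibits: List[int] = []
        for a in net.arcs:
            if a.target == tid and a.source in p_index:
                if a.kind == NORMAL:
                    consume[p_index[a.source]] = consume.get(p_index[a.source], 0) + 1
                elif a.kind == READ:
                    reads.append(p_index[a.source])
                else:
                    inhibits.append(p_index[a.source])
            elif a.source == tid and a.target in p_index:
                produce[p_index[a.target]] = produce.get(p_index[a.target], 0) + 1
        compiled.append((tid, consume, produce, reads, inhibits, net.gate_groups.get(tid)))
    return places, p_index, compiled


def simulate(
    net: PetriNet,
    initial: Mapping[str, int],
    steps: int,
    runs: int,
    seed: int,
) -> TokenTrajectory:
    """Run seeded stochastic token flow and return mean trajectories.

    At each step the enabled transitions (every normal input place >= 1 token,
    every inhibitor source exactly 0, every read source >= 1) are visited in a
    seeded random order; each fires at most once per step, consuming one token
    per normal input arc and producing one per output arc, and enabledness is
    re-checked just before each firing so earlier firings can disable later
    ones. Within a conditional-gate group only the first enabled branch
    encountered in the random order fires. Trajectories are the per-place
    means over ``runs`` independent runs; the same arguments and seed always
    reproduce the same result.
    """
    if steps < 1 or runs < 1:
        raise PetriNetError("steps and runs must be positive")
    unknown = set(initial) - set(net.places)
    if unknown:
        raise PetriNetError(f"marking references unknown place(s): {sorted(unknown)}")
    for pid, count in initial.items():
        if count < 0:
            raise PetriNetError(f"negative token count for {pid!r}")

    places, p_index, compiled = _compile(net)
    n_places = len(places)
    totals = np.zeros((steps + 1, n_places), dtype=float)
    base = np.zeros(n_places, dtype=np.int64)
    for pid, count in initial.items():
        base[p_index[pid]] = count

    rng = np.random.default_rng(seed)
    n_trans = len(compiled)
    for _ in range(runs):
        marking = base.copy()
        totals[0] += marking
        for step in range(1, steps + 1):
            fired_gates = set()
            order = rng.permutation(n_trans) if n_trans else []
            for ti in order:
                tid, consume, produce, reads, inhibits, gate = compiled[ti]
                if gate is not None and gate in fired_gates:
                    continue
                if any(marking[p] < c for p, c in consume.items()):
                    continue
                if any(marking[p] < 1 for p in reads):
                    continue
                if any(marking[p] > 0 for p in inhibits):
                    continue
                for p, c in consume.items():
                    marking[p] -= c
                for p, c in produce.items():
                    marking[p] += c
                if gate is not None:
                    fired_gates.add(gate)
            totals[step] += marking
    return TokenTrajectory(
        places=places, means=totals / runs, steps=steps, runs=runs, seed=seed
    )


# ---------------------------------------------------------------- exports


def petri_to_graphml(net: PetriNet) -> bytes:
    """Plain bipartite GraphML: places and transitions as typed nodes, arcs
    as edges with a ``kind`` attribute. Deterministic byte output."""
    from lxml import etree

    nsmap = {None: "http://graphml.graphdrawing.org/xmlns"}
    root = etree.Element("graphml", nsmap=nsmap)
    for kid, name in (("d_kind", "element_kind"), ("d_prov", "provenance")):
        k = etree.SubElement(root, "key", id=kid)
        k.set("for", "node" if kid != "d_arc" else "edge")
        k.set("attr.name", name)
        k.set("attr.type", "string")
    ka = etree.SubElement(root, "key", id="d_arc")
    ka.set("for", "edge")
    ka.set("attr.name", "kind")
    ka.set("attr.type", "string")
    graph = etree.SubElement(root, "graph", id="petri", edgedefault="directed")
    for pid in sorted(net.places):
        n = etree.SubElement(graph, "node", id=pid)
        etree.SubElement(n, "data", key="d_kind").text = "place"
        etree.SubElement(n, "data", key="d_prov").text = net.places[pid]
    for tid in sorted(net.transitions):
        n = etree.SubElement(graph, "node", id=tid)
        etree.SubElement(n, "data", key="d_kind").text = "transition"
        etree.SubElement(n, "data", key="d_prov").text = net.transitions[tid]
    for i, a in enumerate(sorted(net.arcs, key=lambda a: (a.source, a.target, a.kind))):
        e = etree.SubElement(graph, "edge", id=f"a{i}", source=a.source, target=a.target)
        etree.SubElement(e, "data", key="d_arc").text = a.kind
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def arc_table(net: PetriNet) -> str:
    """Tab-separated arc list: source, target, kind."""
    lines = ["source\ttarget\tkind"]
    for a in sorted(net.arcs, key=lambda a: (a.source, a.target, a.kind)):
        lines.append(f"{a.source}\t{a.target}\t{a.kind}")
    return "\n".join(lines) + "\n"


def trajectory_table(traj: TokenTrajectory) -> str:
    """Tab-separated long-format trajectory: step, place, mean_tokens."""
    buf = io.StringIO()
    buf.write("step\tplace\tmean_tokens\n")
    for step in range(traj.means.shape[0]):
        for j, pid in enumerate(traj.places):
            buf.write(f"{step}\t{pid}\t{traj.means[step, j]:.6f}\n")
    return buf.getvalue()
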