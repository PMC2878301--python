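"""Typed pathway-graph data model.

A pathway is a directional network of molecular interactions between
components of a biological system. The model keeps the semantics explicit:

* nodes are typed by a :class:`NodeClass` (component, process, Boolean
  operator, edge annotation, energy transfer, conditional gate, pathway
  module, pathway output) validated against a :class:`~mepnkit.registry.GlyphRegistry`;
* edges are directed interactions, undirected physical bonds between complex
  members, or annotated influences (A activation, I inhibition, C catalysis);
* compartments are first-class objects — membership is a semantic attribute
  of the node, never inferred from layout coordinates, and forms a forest
  (a compartment may nest inside one parent).

Node ids are opaque, artifact-generated strings: component identity for the
once-per-compartment rule is the *derived* key (symbol + state), computed by
the label grammar, not the id.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import networkx as nx

from .labels import ComplexSpec, LabelError, canonical_identity, parse_component_label
from .registry import GlyphRegistry, default_registry

__all__ = [
    "ModelError",
    "DuplicateIdError",
    "NodeClass",
    "PathwayNode",
    "PathwayEdge",
    "Compartment",
    "PathwayGraph",
    "create_pathway",
]


class ModelError(ValueError):
    """A structural rule of the pathway model was violated."""


class DuplicateIdError(ModelError):
    """An id already names another element of the graph."""


@dataclass(frozen=True)
class NodeClass:
    """(kind, subclass) pair, e.g. ``component/protein`` or ``process/P``."""

    kind: str
    subclass: str

    def __str__(self) -> str:
        return f"{self.kind}/{self.subclass}"


@dataclass(frozen=True)
class PathwayNode:
    """One glyph in the diagram.

    ``parsed_label`` caches the grammar parse for component nodes;
    ``is_distribution`` marks edge-annotation nodes deliberately used to fan
    an influence out to many targets (e.g. a transcription factor activating
    a battery of genes through one annotation node).
    """

    id: str
    node_class: NodeClass
    label: str = ""
    parsed_label: Optional[ComplexSpec] = field(default=None, compare=False)
    compartment: Optional[str] = None
    position2d: Optional[Tuple[float, float]] = None
    is_distribution: bool = False

    def __post_init__(self) -> None:
        if self.node_class.kind == "component" and not self.label:
            raise ModelError(f"component node {self.id!r} must carry a label")


@dataclass(frozen=True)
class PathwayEdge:
    """One interaction.

    Directed edges convey influence or flow; undirected edges are physical
    covalent or non-covalent bonds between complex members and never carry an
    annotation code. ``style`` holds a colour tag (edges into pathway-output
    nodes are drawn light blue). ``is_distribution`` marks an annotated edge
    that fans out from a distribution reading.
    """

    id: str
    source: str
    target: str
    directed: bool = True
    annotation: Optional[str] = None
    is_distribution: bool = False
    style: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.directed and self.annotation is not None:
            raise ModelError(
                f"edge {self.id!r}: physical-bond (undirected) edges carry no annotation"
            )


@dataclass(frozen=True)
class Compartment:
    """A labelled background region: a cellular location components live in."""

    id: str
    name: str
    fill_colour: str = "light_grey"
    perimeter_colour: str = "black"
    parent: Optional[str] = None


class PathwayGraph:
    """Mutable container of nodes, edges and compartments.

    Nodes and edges are stored in insertion-independent keyed maps, so two
    graphs built in different orders compare equal whenever their id sets,
    element contents and adjacency agree.
    """

    def __init__(self, name: str = "", registry: Optional[GlyphRegistry] = None):
        self.metadata: Dict[str, object] = {"name": name}
        self.registry = registry or default_registry()
        self._nodes: Dict[str, PathwayNode] = {}
        self._edges: Dict[str, PathwayEdge] = {}
        self._compartments: Dict[str, Compartment] = {}
        self._edge_counter = itertools.count(1)

    # -- views ---------------------------------------------------------

    @property
    def name(self) -> str:
        return str(self.metadata.get("name", ""))

    @property
    def nodes(self) -> Dict[str, PathwayNode]:
        return dict(self._nodes)

    @property
    def edges(self) -> Dict[str, PathwayEdge]:
        return dict(self._edges)

    @property
    def compartments(self) -> Dict[str, Compartment]:
        return dict(self._compartments)

    def node(self, node_id: str) -> PathwayNode:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise ModelError(f"no node with id {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def in_edges(self, node_id: str) -> List[PathwayEdge]:
        return [e for e in self.iter_edges() if e.directed and e.target == node_id]

    def out_edges(self, node_id: str) -> List[PathwayEdge]:
        return [e for e in self.iter_edges() if e.directed and e.source == node_id]

    def bond_edges(self, node_id: str) -> List[PathwayEdge]:
        return [
            e for e in self.iter_edges()
            if not e.directed and node_id in (e.source, e.target)
        ]

    def iter_nodes(self) -> Iterator[PathwayNode]:
        return iter(sorted(self._nodes.values(), key=lambda n: n.id))

    def iter_edges(self) -> Iterator[PathwayEdge]:
        return iter(sorted(self._edges.values(), key=lambda e: e.id))

    def iter_compartments(self) -> Iterator[Compartment]:
        return iter(sorted(self._compartments.values(), key=lambda c: c.id))

    # -- construction --------------------------------------------------

    def add_compartment(self, comp: Compartment) -> "PathwayGraph":
        if comp.id in self._compartments:
            raise DuplicateIdError(f"compartment id {comp.id!r} already present")
        if comp.parent is not None:
            seen = {comp.id}
            cur = comp.parent
            while cur is not None:
                if cur in seen:
                    raise ModelError(f"compartment parents form a cycle at {cur!r}")
                seen.add(cur)
                cur = self._compartments[cur].parent if cur in self._compartments else None
        self._compartments[comp.id] = comp
        return self

    def add_node(self, node: PathwayNode) -> "PathwayGraph":
        """Insert a node; component labels are parsed eagerly so that a bad
        label fails at construction rather than at validation time."""
        if node.id in self._nodes:
            raise DuplicateIdError(f"node id {node.id!r} already present")
        nc = node.node_class
        if not self.registry.is_registered(nc.kind, nc.subclass):
            raise ModelError(f"node class {nc} is not in the active glyph registry")
        if node.compartment is not None and node.compartment not in self._compartments:
            raise ModelError(
                f"node {node.id!r} references unknown compartment {node.compartment!r}"
            )
        if nc.kind == "component" and node.parsed_label is None:
            node = replace(node, parsed_label=parse_component_label(node.label))
        self._nodes[node.id] = node
        return self

    def connect(
        self,
        source_id: str,
        target_id: str,
        directed: bool = True,
        annotation: Optional[str] = None,
        *,
        edge_id: Optional[str] = None,
        is_distribution: bool = False,
        style: Optional[str] = None,
    ) -> PathwayEdge:
        """Create an edge between two existing nodes and return it.

        Undirected edges are physical bonds and are rejected if an annotation
        code is supplied.
        """
        for nid in (source_id, target_id):
            if nid not in self._nodes:
                raise ModelError(f"edge endpoint {nid!r} does not resolve to a node")
        if not directed and annotation is not None:
            raise ModelError("physical-bond (undirected) edges carry no annotation")
        eid = edge_id or self._fresh_edge_id()
        if eid in self._edges:
            raise DuplicateIdError(f"edge id {eid!r} already present")
        edge = PathwayEdge(
            id=eid,
            source=source_id,
            target=target_id,
            directed=directed,
            annotation=annotation,
            is_distribution=is_distribution,
            style=style,
        )
        self._edges[eid] = edge
        return edge

    def _fresh_edge_id(self) -> str:
        while True:
            eid = f"e{next(self._edge_counter)}"
            if eid not in self._edges:
                return eid

    def remove_node(self, node_id: str) -> "PathwayGraph":
        """Remove a node and, to keep referential integrity, every incident edge."""
        if node_id not in self._nodes:
            raise ModelError(f"no node with id {node_id!r}")
        del self._nodes[node_id]
        self._edges = {
            eid: e for eid, e in self._edges.items()
            if node_id not in (e.source, e.target)
        }
        return self

    def remove_edge(self, edge_id: str) -> "PathwayGraph":
        if edge_id not in self._edges:
            raise ModelError(f"no edge with id {edge_id!r}")
        del self._edges[edge_id]
        return self

    # -- queries -------------------------------------------------------

    def component_instances(self, identity: str, compartment: Optional[str]) -> List[str]:
        """Ids of component nodes in `compartment` whose canonical identity
        (symbol plus full modification state) equals `identity`.

        The query may be a label or an identity key. Distinct modification
        states are distinct identities — an inactive and a phosphorylated
        form never collide. Backs the validator's once-per-compartment rule.
        """
        try:
            key = canonical_identity(identity)
        except LabelError:
            key = identity
        out = []
        for node in self.iter_nodes():
            if node.node_class.kind != "component" or node.compartment != compartment:
                continue
            if node.parsed_label is None:
                raise ModelError(
                    f"component {node.id!r} has no parsed label; parse labels first"
                )
            if canonical_identity(node.parsed_label) == key:
                out.append(node.id)
        return out

    # -- interop / equality -------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        """Export to a networkx MultiDiGraph (bonds as paired reciprocal
        arcs flagged ``directed=False``) for generic graph algorithms."""
        g = nx.MultiDiGraph(name=self.name)
        for n in self.iter_nodes():
            g.add_node(
                n.id, kind=n.node_class.kind, subclass=n.node_class.subclass,
                label=n.label, compartment=n.compartment,
            )
        for e in self.iter_edges():
            g.add_edge(e.source, e.target, key=e.id, directed=e.directed,
                       annotation=e.annotation)
            if not e.directed:
                g.add_edge(e.target, e.source, key=e.id + "_rev", directed=False,
                           annotation=None)
        return g

    def _signature(self):
        return (
            self.name,
            tuple(self.iter_nodes()),
            tuple(self.iter_edges()),
            tuple(self.iter_compartments()),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayGraph):
            return NotImplemented
        return self._signature() == other._signature()

    def __repr__(self) -> str:
        return (
            f"<PathwayGraph {self.name!r}: {len(self._nodes)} nodes, "
            f"{len(self._edges)} edges, {len(self._compartments)} compartments>"
        )


def create_pathway(name: str = "", registry: Optional[GlyphRegistry] = None) -> PathwayGraph:
    """Create an empty pathway graph with its metadata name set."""
    return PathwayGraph(name=name, registry=registry)
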