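"""GraphML import/export for pathway graphs.

Two dialects are supported:

* ``plain`` — semantics only, encoded as typed GraphML ``<data>`` attributes
  (class, subclass, label, compartment, coordinates, edge annotation);
* ``editor`` — additionally carries yFiles-style graphics (shape, fill,
  border, geometry, label) so files open directly in yEd-compatible editors,
  with compartments written as group nodes.

On import, files written by this package round-trip losslessly via the typed
attributes. Foreign editor files are understood through
:func:`classify_node`: class is resolved from shape and printed label code
first — meaning is never reliant on colour, which serves only as a tie-break
hint — group/background nodes become compartments, edges drawn without an
arrowhead become physical bonds, and in-line annotation nodes with exactly
one input and one output collapse into a single annotated edge. Anything
unclassifiable is imported with the generic component class and reported in
the warning list rather than failing the import.

Coordinates follow the editor convention: x grows rightwards, y downwards,
origin arbitrary. Output is deterministic byte-for-byte: elements are
ordered by id and attributes by a fixed key table.
"""

from __future__ import annotations

import io
from typing import Dict, List, Optional, Tuple, Union

from lxml import etree

from .labels import LabelError, parse_component_label
from .model import Compartment, NodeClass, PathwayEdge, PathwayGraph, PathwayNode
from .registry import COLOUR_TABLE, GlyphRegistry, default_registry

__all__ = ["GraphMLError", "read_graphml", "write_graphml", "classify_node"]

GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"
Y_NS = "http://www.yworks.com/xml/graphml"

_NODE_KEYS = [
    ("mk_kind", "mepn_kind"),
    ("mk_subclass", "mepn_subclass"),
    ("mk_label", "mepn_label"),
    ("mk_compartment", "mepn_compartment"),
    ("mk_x", "mepn_x"),
    ("mk_y", "mepn_y"),
    ("mk_dist", "mepn_distribution"),
    ("mk_comp_name", "mepn_compartment_name"),
    ("mk_comp_fill", "mepn_compartment_fill"),
    ("mk_comp_perimeter", "mepn_compartment_perimeter"),
    ("mk_comp_parent", "mepn_compartment_parent"),
]
_EDGE_KEYS = [
    ("me_annotation", "mepn_annotation"),
    ("me_dist", "mepn_edge_distribution"),
    ("me_style", "mepn_style"),
]

_HEX_TO_TAG = {v: k for k, v in COLOUR_TABLE.items()}


class GraphMLError(ValueError):
    """Malformed or structurally inconsistent GraphML input."""


def _hex(tag: str) -> str:
    return COLOUR_TABLE.get(tag, tag if tag.startswith("#") else "#C0C0C0")


def classify_node(
    shape: Optional[str],
    fill: Optional[str],
    label: str,
    registry: GlyphRegistry,
) -> NodeClass:
    """Resolve a glyph class from visual attributes.

    Shape plus the printed label code decide the class; colour is consulted
    only as a tie-break hint for shapeless input. Never raises — input that
    matches nothing maps to the generic component class (the importer records
    a warning for those).
    """
    text = label.strip().split("\n")[0].strip()
    if shape == "ellipse":
        if text in registry.boolean_ops:
            return NodeClass("boolean_operator", text)
        if text in registry.edge_annotations:
            return NodeClass("edge_annotation", text)
        if text in registry.process_classes:
            return NodeClass("process", text)
        return NodeClass("component", "generic")
    if shape == "roundrectangle":
        try:
            spec = parse_component_label(text) if text else None
        except LabelError:
            spec = None
        if spec and (
            len(spec.subunits) > 1 or spec.subunits[0].stoichiometry not in (None, 1)
        ):
            return NodeClass("component", "protein_complex")
        return NodeClass("component", "protein")
    by_shape = {
        "rectangle": NodeClass("component", "gene"),
        "diamond": NodeClass("component", "ion_simple_molecule"),
        "hexagon": NodeClass("component", "pathogen"),
        "octagon": NodeClass("component", "generic"),
        "parallelogram": NodeClass("energy_transfer", "energy_transfer"),
        "trapezium": NodeClass("conditional_gate", "conditional_gate"),
        "rectangle3d": NodeClass("pathway_module", "pathway_module"),
        "fatarrow": NodeClass("pathway_output", "pathway_output"),
    }
    if shape in by_shape:
        return by_shape[shape]
    if fill:  # colour as a last-resort hint only
        tag = _HEX_TO_TAG.get(fill.upper(), fill)
        for sub in registry.component_classes:
            if registry.styles[("component", sub)].fill == tag:
                return NodeClass("component", sub)
    return NodeClass("component", "generic")


# ----------------------------------------------------------------- writing


def _declare_keys(root) -> None:
    for kid, name in _NODE_KEYS:
        k = etree.SubElement(root, f"{{{GRAPHML_NS}}}key", id=kid)
        k.set("for", "node")
        k.set("attr.name", name)
        k.set("attr.type", "string")
    for kid, name in _EDGE_KEYS:
        k = etree.SubElement(root, f"{{{GRAPHML_NS}}}key", id=kid)
        k.set("for", "edge")
        k.set("attr.name", name)
        k.set("attr.type", "string")


def _data(parent, key: str, value: str) -> None:
    etree.SubElement(parent, f"{{{GRAPHML_NS}}}data", key=key).text = value


def _node_graphics(parent, graph: PathwayGraph, node: PathwayNode) -> None:
    style = graph.registry.style(node.node_class.kind, node.node_class.subclass)
    data = etree.SubElement(parent, f"{{{GRAPHML_NS}}}data", key="yg_node")
    sn = etree.SubElement(data, f"{{{Y_NS}}}ShapeNode")
    x, y = node.position2d or (0.0, 0.0)
    small = node.node_class.kind in ("process", "boolean_operator", "edge_annotation")
    size = "30.0" if small else "80.0"
    geom = etree.SubElement(sn, f"{{{Y_NS}}}Geometry")
    geom.set("x", repr(float(x)))
    geom.set("y", repr(float(y)))
    geom.set("width", size)
    geom.set("height", "30.0")
    etree.SubElement(sn, f"{{{Y_NS}}}Fill", color=_hex(style.fill))
    etree.SubElement(sn, f"{{{Y_NS}}}BorderStyle", color=_hex(style.border), width="1.0")
    label = node.label or node.node_class.subclass
    etree.SubElement(sn, f"{{{Y_NS}}}NodeLabel").text = label
    etree.SubElement(sn, f"{{{Y_NS}}}Shape", type=style.shape2d)


def _write_node(parent, graph: PathwayGraph, node: PathwayNode, editor: bool) -> None:
    el = etree.SubElement(parent, f"{{{GRAPHML_NS}}}node", id=node.id)
    _data(el, "mk_kind", node.node_class.kind)
    _data(el, "mk_subclass", node.node_class.subclass)
    if node.label:
        _data(el, "mk_label", node.label)
    if node.compartment is not None and not editor:
        _data(el, "mk_compartment", node.compartment)
    if node.position2d is not None:
        _data(el, "mk_x", repr(float(node.position2d[0])))
        _data(el, "mk_y", repr(float(node.position2d[1])))
    if node.is_distribution:
        _data(el, "mk_dist", "true")
    if editor:
        _node_graphics(el, graph, node)


def _write_compartment_plain(parent, comp: Compartment) -> None:
    el = etree.SubElement(parent, f"{{{GRAPHML_NS}}}node", id=f"comp:{comp.id}")
    _data(el, "mk_kind", "compartment")
    _data(el, "mk_subclass", "compartment_label")
    _data(el, "mk_comp_name", comp.name)
    _data(el, "mk_comp_fill", comp.fill_colour)
    _data(el, "mk_comp_perimeter", comp.perimeter_colour)
    if comp.parent is not None:
        _data(el, "mk_comp_parent", comp.parent)


def _write_group(parent, graph: PathwayGraph, comp: Compartment,
                 children: Dict[Optional[str], List[Compartment]],
                 members: Dict[Optional[str], List[PathwayNode]]) -> None:
    el = etree.SubElement(parent, f"{{{GRAPHML_NS}}}node", id=f"comp:{comp.id}")
    el.set("yfiles.foldertype", "group")
    _data(el, "mk_kind", "compartment")
    _data(el, "mk_subclass", "compartment_label")
    _data(el, "mk_comp_name", comp.name)
    _data(el, "mk_comp_fill", comp.fill_colour)
    _data(el, "mk_comp_perimeter", comp.perimeter_colour)
    if comp.parent is not None:
        _data(el, "mk_comp_parent", comp.parent)
    data = etree.SubElement(el, f"{{{GRAPHML_NS}}}data", key="yg_node")
    gn = etree.SubElement(data, f"{{{Y_NS}}}GroupNode")
    etree.SubElement(gn, f"{{{Y_NS}}}Fill", color=_hex(comp.fill_colour))
    etree.SubElement(gn, f"{{{Y_NS}}}BorderStyle", color=_hex(comp.perimeter_colour), width="2.0")
    etree.SubElement(gn, f"{{{Y_NS}}}NodeLabel").text = comp.name
    sub = etree.SubElement(el, f"{{{GRAPHML_NS}}}graph",
                           id=f"comp:{comp.id}:g", edgedefault="directed")
    for child in children.get(comp.id, []):
        _write_group(sub, graph, child, children, members)
    for node in members.get(comp.id, []):
        _write_node(sub, graph, node, editor=True)


def write_graphml(graph: PathwayGraph, dialect: str = "plain") -> bytes:
    """Serialize a pathway graph to GraphML bytes.

    ``dialect="plain"`` writes typed semantic attributes only;
    ``dialect="editor"`` additionally writes yFiles graphics per the glyph
    registry's style records, compartments as group nodes, no arrowheads on
    physical bonds, and the light-blue line colour on edges entering
    pathway-output nodes. Output is byte-deterministic.
    """
    if dialect not in ("plain", "editor", "editor_extension"):
        raise GraphMLError(f"unknown dialect {dialect!r}")
    editor = dialect != "plain"
    nsmap = {None: GRAPHML_NS}
    if editor:
        nsmap["y"] = Y_NS
    root = etree.Element(f"{{{GRAPHML_NS}}}graphml", nsmap=nsmap)
    _declare_keys(root)
    if editor:
        k = etree.SubElement(root, f"{{{GRAPHML_NS}}}key", id="yg_node")
        k.set("for", "node")
        k.set("yfiles.type", "nodegraphics")
        k = etree.SubElement(root, f"{{{GRAPHML_NS}}}key", id="yg_edge")
        k.set("for", "edge")
        k.set("yfiles.type", "edgegraphics")
    g = etree.SubElement(root, f"{{{GRAPHML_NS}}}graph",
                         id=graph.name or "pathway", edgedefault="directed")

    comps = list(graph.iter_compartments())
    if editor:
        children: Dict[Optional[str], List[Compartment]] = {}
        for c in comps:
            children.setdefault(c.parent, []).append(c)
        members: Dict[Optional[str], List[PathwayNode]] = {}
        for node in graph.iter_nodes():
            members.setdefault(node.compartment, []).append(node)
        for c in children.get(None, []):
            _write_group(g, graph, c, children, members)
        for node in members.get(None, []):
            _write_node(g, graph, node, editor=True)
    else:
        for c in comps:
            _write_compartment_plain(g, c)
        for node in graph.iter_nodes():
            _write_node(g, graph, node, editor=False)

    outputs = {n.id for n in graph.iter_nodes() if n.node_class.kind == "pathway_output"}
    for edge in graph.iter_edges():
        el = etree.SubElement(g, f"{{{GRAPHML_NS}}}edge", id=edge.id,
                              source=edge.source, target=edge.target)
        el.set("directed", "true" if edge.directed else "false")
        if edge.annotation is not None:
            _data(el, "me_annotation", edge.annotation)
        if edge.is_distribution:
            _data(el, "me_dist", "true")
        if edge.style is not None:
            _data(el, "me_style", edge.style)
        if editor:
            data = etree.SubElement(el, f"{{{GRAPHML_NS}}}data", key="yg_edge")
            pl = etree.SubElement(data, f"{{{Y_NS}}}PolyLineEdge")
            colour = "light_blue" if edge.target in outputs else (edge.style or "black")
            etree.SubElement(pl, f"{{{Y_NS}}}LineStyle", color=_hex(colour), width="1.0")
            arrows = etree.SubElement(pl, f"{{{Y_NS}}}Arrows")
            arrows.set("source", "none")
            arrows.set("target", "standard" if edge.directed else "none")
            if edge.annotation is not None:
                etree.SubElement(pl, f"{{{Y_NS}}}EdgeLabel").text = edge.annotation
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


# ----------------------------------------------------------------- reading


def _parse_keys(root) -> Dict[str, str]:
    """key element id -> attr.name (or yfiles.type marker)."""
    table: Dict[str, str] = {}
    for k in root.findall(f"{{{GRAPHML_NS}}}key"):
        kid = k.get("id")
        name = k.get("attr.name") or k.get("yfiles.type") or kid
        table[kid] = name
    return table


def _data_map(el, keys: Dict[str, str]) -> Dict[str, object]:
    out: Dict[str, object] = {}
    for d in el.findall(f"{{{GRAPHML_NS}}}data"):
        name = keys.get(d.get("key"), d.get("key"))
        if name in ("nodegraphics", "edgegraphics"):
            out[name] = d
        else:
            out[name] = (d.text or "").strip()
    return out


def _graphics_attrs(data_el) -> Tuple[Optional[str], Optional[str], Optional[str],
                                      Optional[Tuple[float, float]], Optional[Tuple[str, str]]]:
    """(shape, fill, label, position, arrows) from a yFiles graphics blob."""
    shape = fill = label = None
    pos = arrows = None
    for el in data_el.iter():
        tag = etree.QName(el).localname
        if tag == "Shape":
            shape = el.get("type")
        elif tag == "Fill":
            fill = el.get("color")
        elif tag in ("NodeLabel", "EdgeLabel") and label is None:
            label = el.text or ""
        elif tag == "Geometry":
            try:
                pos = (float(el.get("x", "0")), float(el.get("y", "0")))
            except (TypeError, ValueError):
                pos = None
        elif tag == "Arrows":
            arrows = (el.get("source", "none"), el.get("target", "standard"))
    return shape, fill, label, pos, arrows


def _is_group(node_el) -> bool:
    return (
        node_el.get("yfiles.foldertype") == "group"
        or node_el.find(f"{{{GRAPHML_NS}}}graph") is not None
    )


def read_graphml(
    stream: Union[bytes, str, io.IOBase],
    registry: Optional[GlyphRegistry] = None,
) -> Tuple[PathwayGraph, List[str]]:
    """Parse GraphML into a pathway graph; returns ``(graph, warnings)``.

    Handles both dialects written by :func:`write_graphml` and foreign
    editor files (see module docstring for the classification rules).
    Raises :class:`GraphMLError` on malformed XML or edges referencing
    undeclared nodes.
    """
    registry = registry or default_registry()
    if isinstance(stream, str):
        stream = stream.encode("utf-8")
    if isinstance(stream, bytes):
        stream = io.BytesIO(stream)
    try:
        tree = etree.parse(stream)
    except etree.XMLSyntaxError as exc:
        raise GraphMLError(f"malformed XML: {exc}") from None
    root = tree.getroot()
    if etree.QName(root).localname != "graphml":
        raise GraphMLError("not a GraphML document (missing <graphml> root)")
    keys = _parse_keys(root)
    top = root.find(f"{{{GRAPHML_NS}}}graph")
    if top is None:
        raise GraphMLError("document contains no <graph> element")

    graph = PathwayGraph(name=top.get("id", ""), registry=registry)
    warnings: List[str] = []
    pending_nodes: List[PathwayNode] = []
    pending_edges: List[dict] = []
    compartments: Dict[str, Compartment] = {}

    def visit(graph_el, compartment: Optional[str]) -> None:
        default_directed = graph_el.get("edgedefault", "directed") == "directed"
        for node_el in graph_el.findall(f"{{{GRAPHML_NS}}}node"):
            data = _data_map(node_el, keys)
            nid = node_el.get("id")
            if nid is None:
                raise GraphMLError("node element without id")
            if _is_group(node_el) or data.get("mepn_kind") == "compartment":
                cid = nid[5:] if nid.startswith("comp:") else nid
                gfx = data.get("nodegraphics")
                glabel = None
                if gfx is not None:
                    _, gfill, glabel, _, _ = _graphics_attrs(gfx)
                comp = Compartment(
                    id=cid,
                    name=str(data.get("mepn_compartment_name") or glabel or cid),
                    fill_colour=str(data.get("mepn_compartment_fill") or "light_grey"),
                    perimeter_colour=str(data.get("mepn_compartment_perimeter") or "black"),
                    parent=str(data["mepn_compartment_parent"])
                    if data.get("mepn_compartment_parent") else compartment,
                )
                compartments[cid] = comp
                for sub in node_el.findall(f"{{{GRAPHML_NS}}}graph"):
                    visit(sub, cid)
                continue

            gfx = data.get("nodegraphics")
            shape = fill = glabel = None
            pos = None
            if gfx is not None:
                shape, fill, glabel, pos, _ = _graphics_attrs(gfx)
            typed = "mepn_kind" in data and "mepn_subclass" in data
            if typed:  # graphics labels are derived; trust the typed attribute
                label = str(data.get("mepn_label", ""))
            else:
                label = str(glabel or "")
            if typed:
                nc = NodeClass(str(data["mepn_kind"]), str(data["mepn_subclass"]))
                if not registry.is_registered(nc.kind, nc.subclass):
                    warnings.append(
                        f"node {nid!r}: class {nc} not in registry; imported as generic"
                    )
                    nc = NodeClass("component", "generic")
            else:
                nc = classify_node(shape, fill, label, registry)
                if nc == NodeClass("component", "generic"):
                    warnings.append(
                        f"node {nid!r} (shape={shape!r}, label={label!r}) could not "
                        "be classified; imported as generic component"
                    )
            if "mepn_x" in data and "mepn_y" in data:
                pos = (float(str(data["mepn_x"])), float(str(data["mepn_y"])))
            elif typed:  # our own files: geometry is derived presentation
                pos = None
            comp_attr = str(data["mepn_compartment"]) if data.get("mepn_compartment") else None
            node = PathwayNode(
                id=nid,
                node_class=nc,
                label=label or (nid if nc.kind == "component" else ""),
                compartment=compartment or comp_attr,  # group nesting wins
                position2d=pos,
                is_distribution=str(data.get("mepn_distribution", "")) == "true",
            )
            pending_nodes.append((node, typed))

        for edge_el in graph_el.findall(f"{{{GRAPHML_NS}}}edge"):
            data = _data_map(edge_el, keys)
            gfx = data.get("edgegraphics")
            arrows = None
            elabel = None
            if gfx is not None:
                _, _, elabel, _, arrows = _graphics_attrs(gfx)
            if "directed" in edge_el.attrib:
                directed = edge_el.get("directed") == "true"
            elif arrows is not None:
                directed = arrows[0] != "none" or arrows[1] != "none"
            else:
                directed = default_directed
            annotation = str(data["mepn_annotation"]) if data.get("mepn_annotation") else None
            pending_edges.append(dict(
                id=edge_el.get("id"),
                source=edge_el.get("source"),
                target=edge_el.get("target"),
                directed=directed,
                annotation=annotation,
                is_distribution=str(data.get("mepn_edge_distribution", "")) == "true",
                style=str(data["mepn_style"]) if data.get("mepn_style") else None,
            ))

    visit(top, None)

    for comp in sorted(compartments.values(), key=lambda c: c.id):
        if comp.parent is not None and comp.parent not in compartments:
            comp = Compartment(comp.id, comp.name, comp.fill_colour,
                               comp.perimeter_colour, None)
        graph.add_compartment(comp)
    typed_any = False
    node_ids = set()
    for node, typed in pending_nodes:
        typed_any = typed_any or typed
        graph.add_node(node)
        node_ids.add(node.id)
    for spec in pending_edges:
        for end in ("source", "target"):
            if spec[end] not in node_ids:
                raise GraphMLError(
                    f"edge {spec['id']!r} references undeclared node {spec[end]!r}"
                )
        graph.connect(
            spec["source"], spec["target"], directed=spec["directed"],
            annotation=spec["annotation"], edge_id=spec["id"],
            is_distribution=spec["is_distribution"], style=spec["style"],
        )

    if not typed_any:
        _collapse_annotation_nodes(graph, warnings)
    return graph, warnings


def _collapse_annotation_nodes(graph: PathwayGraph, warnings: List[str]) -> None:
    """In foreign files, an in-line annotation node with exactly one input and
    one output stands for an annotated edge; fold it away. Multi-output
    annotation nodes are kept as explicit distribution nodes."""
    for node in list(graph.iter_nodes()):
        if node.node_class.kind != "edge_annotation":
            continue
        ins = graph.in_edges(node.id)
        outs = graph.out_edges(node.id)
        if len(ins) == 1 and len(outs) == 1:
            src, tgt = ins[0].source, outs[0].target
            graph.remove_node(node.id)
            graph.connect(src, tgt, directed=True, annotation=node.node_class.subclass)
            warnings.append(
                f"in-line annotation node {node.id!r} collapsed into an "
                f"{node.node_class.subclass}-annotated edge {src!r}->{tgt!r}"
            )
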