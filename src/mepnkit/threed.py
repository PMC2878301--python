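"""2D→3D style translation.

The notation deliberately uses simple shapes, labels and colours, which maps
directly into 3D viewers: each 2D glyph becomes a solid (components spheres
or boxes by class, process and operator nodes small cubes), carrying over its
fill colour and label. 2D layout coordinates are preserved in the x/y plane;
z defaults to 0, or, optionally, compartments are stacked in separate z
layers so cellular location reads as depth.
"""

from __future__ import annotations

from typing import Dict, List

from .model import PathwayGraph
from .registry import COLOUR_TABLE

__all__ = ["layout3d"]

_Z_SPACING = 150.0


def layout3d(graph: PathwayGraph, z_stack_compartments: bool = False) -> List[Dict[str, object]]:
    """Translate a 2D diagram into 3D node records.

    Returns one record per node: id, label, kind, subclass, 3D solid, size
    scalar, colour (hex) and x/y/z coordinates, sorted by node id. With
    ``z_stack_compartments`` each compartment occupies its own z layer
    (alphabetical order, spaced 150 layout units apart); nodes without a
    compartment sit at z = 0.
    """
    z_of: Dict[str, float] = {}
    if z_stack_compartments:
        for i, comp in enumerate(graph.iter_compartments()):
            z_of[comp.id] = (i + 1) * _Z_SPACING
    records = []
    for node in graph.iter_nodes():
        style = graph.registry.style(node.node_class.kind, node.node_class.subclass)
        x, y = node.position2d or (0.0, 0.0)
        records.append({
            "id": node.id,
            "label": node.label or node.node_class.subclass,
            "kind": node.node_class.kind,
            "subclass": node.node_class.subclass,
            "shape3d": style.shape3d,
            "size3d": style.size3d,
            "colour": COLOUR_TABLE.get(style.fill, "#C0C0C0"),
            "x": float(x),
            "y": float(y),
            "z": z_of.get(node.compartment or "", 0.0),
        })
    return records
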