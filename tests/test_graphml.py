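"""GraphML interchange: round-trips, determinism, foreign-file classification."""

import pytest

from mepnkit.graphml import GraphMLError, classify_node, read_graphml, write_graphml
from mepnkit.model import NodeClass
from mepnkit.fixtures import build_enhanceosome

GML = "http://graphml.graphdrawing.org/xmlns"
Y = "http://www.yworks.com/xml/graphml"


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["plain", "editor"])
    def test_ifng_fixture_round_trips(self, ifng_graph, dialect):
        payload = write_graphml(ifng_graph, dialect)
        back, warnings = read_graphml(payload)
        assert warnings == []
        assert back == ifng_graph

    @pytest.mark.parametrize("dialect", ["plain", "editor"])
    def test_enhanceosome_bonds_survive(self, dialect):
        g = build_enhanceosome()
        back, _ = read_graphml(write_graphml(g, dialect))
        assert back == g
        assert all(not e.directed for e in back.iter_edges())

    @pytest.mark.parametrize("dialect", ["plain", "editor"])
    def test_random_graphs_round_trip(self, random_graphs, dialect):
        for g in random_graphs:
            back, _ = read_graphml(write_graphml(g, dialect))
            assert back == g, f"round-trip failed for {g.name}"

    def test_empty_graph_is_valid_document(self):
        from mepnkit.model import create_pathway
        payload = write_graphml(create_pathway("empty"))
        back, warnings = read_graphml(payload)
        assert len(back.nodes) == 0 and warnings == []

    def test_coordinates_preserved_exactly(self, random_graphs):
        from mepnkit.model import PathwayNode, create_pathway
        g = create_pathway("pos")
        g.add_node(PathwayNode("a", NodeClass("component", "protein"), "A",
                               position2d=(13.25, -7.125)))
        back, _ = read_graphml(write_graphml(g, "editor"))
        assert back.node("a").position2d == (13.25, -7.125)


class TestDeterminism:
    @pytest.mark.parametrize("dialect", ["plain", "editor"])
    def test_write_twice_byte_identical(self, ifng_graph, dialect):
        assert write_graphml(ifng_graph, dialect) == write_graphml(ifng_graph, dialect)


class TestEditorDialect:
    def test_light_blue_line_into_pathway_output(self, ifng_graph):
        payload = write_graphml(ifng_graph, "editor").decode()
        # the single edge into the output node carries the light-blue colour
        assert "#ADD8E6" in payload

    def test_unknown_dialect_rejected(self, ifng_graph):
        with pytest.raises(GraphMLError):
            write_graphml(ifng_graph, "dot")


class TestForeignImport:
    def _doc(self, body: str) -> str:
        return (
            f'<?xml version="1.0"?><graphml xmlns="{GML}" xmlns:y="{Y}">'
            f'<key id="ng" for="node" yfiles.type="nodegraphics"/>'
            f'<graph id="g" edgedefault="directed">{body}</graph></graphml>'
        )

    def _shape_node(self, nid, shape, label, fill="#CCCCFF"):
        return (
            f'<node id="{nid}"><data key="ng"><y:ShapeNode>'
            f'<y:Geometry x="10" y="20" width="80" height="30"/>'
            f'<y:Fill color="{fill}"/><y:NodeLabel>{label}</y:NodeLabel>'
            f'<y:Shape type="{shape}"/></y:ShapeNode></data></node>'
        )

    def test_minimal_protein_import(self):
        doc = self._doc(self._shape_node("n0", "roundrectangle", "STAT1"))
        graph, warnings = read_graphml(doc)
        assert warnings == []
        node = graph.node("n0")
        assert node.node_class == NodeClass("component", "protein")
        assert node.label == "STAT1"
        assert node.position2d == (10.0, 20.0)

    def test_dangling_edge_endpoint_rejected(self):
        doc = self._doc(
            self._shape_node("n0", "roundrectangle", "STAT1")
            + '<edge id="e0" source="n0" target="ghost"/>'
        )
        with pytest.raises(GraphMLError):
            read_graphml(doc)

    def test_malformed_xml_rejected(self):
        with pytest.raises(GraphMLError):
            read_graphml(b"<graphml><graph>")

    def test_unclassifiable_node_imports_generic_with_warning(self):
        doc = self._doc(self._shape_node("n0", "star8", "mystery"))
        graph, warnings = read_graphml(doc)
        assert graph.node("n0").node_class == NodeClass("component", "generic")
        assert len(warnings) == 1

    def test_inline_annotation_node_collapses_to_annotated_edge(self):
        body = (
            self._shape_node("a", "roundrectangle", "KRAS")
            + self._shape_node("b", "roundrectangle", "RAF1")
            + self._shape_node("ann", "ellipse", "A")
            + '<edge id="e0" source="a" target="ann"/>'
            + '<edge id="e1" source="ann" target="b"/>'
        )
        graph, warnings = read_graphml(self._doc(body))
        assert "ann" not in graph
        (edge,) = [e for e in graph.iter_edges()]
        assert (edge.source, edge.target, edge.annotation) == ("a", "b", "A")
        assert any("collapsed" in w for w in warnings)

    def test_arrowless_edge_becomes_physical_bond(self):
        body = (
            self._shape_node("a", "roundrectangle", "NFYA")
            + self._shape_node("b", "roundrectangle", "NFYB")
            + '<edge id="e0" source="a" target="b">'
            '<data key="eg"><y:PolyLineEdge>'
            '<y:Arrows source="none" target="none"/>'
            "</y:PolyLineEdge></data></edge>"
        )
        doc = (
            f'<?xml version="1.0"?><graphml xmlns="{GML}" xmlns:y="{Y}">'
            f'<key id="ng" for="node" yfiles.type="nodegraphics"/>'
            f'<key id="eg" for="edge" yfiles.type="edgegraphics"/>'
            f'<graph id="g" edgedefault="directed">{body}</graph></graphml>'
        )
        graph, _ = read_graphml(doc)
        (edge,) = list(graph.iter_edges())
        assert not edge.directed

    def test_group_node_becomes_compartment(self):
        body = (
            '<node id="cyto" yfiles.foldertype="group">'
            '<data key="ng"><y:GroupNode><y:Fill color="#FFFF99"/>'
            "<y:NodeLabel>cytoplasm</y:NodeLabel></y:GroupNode></data>"
            '<graph id="cyto:g" edgedefault="directed">'
            + self._shape_node("n0", "roundrectangle", "STAT1")
            + "</graph></node>"
        )
        graph, _ = read_graphml(self._doc(body))
        assert "cyto" in graph.compartments
        assert graph.compartments["cyto"].name == "cytoplasm"
        assert graph.node("n0").compartment == "cyto"


class TestClassifyNode:
    def test_circle_with_code_is_process(self, registry):
        nc = classify_node("ellipse", "#FF0000", "X", registry)
        assert nc == NodeClass("process", "X")

    def test_circle_with_and_is_boolean(self, registry):
        assert classify_node("ellipse", None, "AND", registry) == NodeClass(
            "boolean_operator", "AND")

    def test_receptor_label_is_complex(self, registry):
        nc = classify_node("roundrectangle", None,
                           "IFNGR1<2>:IFNGR2<2>:JAK1<2>:JAK2<2>", registry)
        assert nc == NodeClass("component", "protein_complex")

    def test_colour_is_only_a_tie_break(self, registry):
        # same shape and label, different colours: identical class
        a = classify_node("ellipse", "#FF0000", "B", registry)
        b = classify_node("ellipse", "#00FF00", "B", registry)
        assert a == b == NodeClass("process", "B")

    def test_diamond_is_ion(self, registry):
        assert classify_node("diamond", None, "Na+", registry) == NodeClass(
            "component", "ion_simple_molecule")
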