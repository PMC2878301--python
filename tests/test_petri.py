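"""Petri-net conversion and token-flow simulation properties."""

import numpy as np
import pytest

from mepnkit.fixtures import (
    MHC2_OUTPUT_NODE,
    build_enhanceosome,
    build_ifng_mhc2_pathway,
    ifng_marking,
)
from mepnkit.model import Compartment, NodeClass, PathwayNode, create_pathway
from mepnkit.petri import (
    Arc,
    PetriNet,
    PetriNetError,
    arc_table,
    petri_to_graphml,
    simulate,
    to_petri_net,
    trajectory_table,
)
from mepnkit.petri import _compile  # reachability oracle builds on the compiled form


def _comp(nid, label, compartment="cytoplasm", subclass="protein"):
    return PathwayNode(nid, NodeClass("component", subclass), label,
                       compartment=compartment)


def _graph():
    g = create_pathway("net")
    g.add_compartment(Compartment("cytoplasm", "cytoplasm"))
    return g


def reachable_markings(net: PetriNet, initial, max_states=50_000):
    """Brute-force reachability under interleaving (one firing at a time).

    Independent of the simulator's step semantics; markings are compared by
    place *name* so nets with different transition names are comparable.
    """
    places, p_index, compiled = _compile(net)
    start = tuple(initial.get(p, 0) for p in places)
    seen = {start}
    frontier = [start]
    while frontier:
        m = frontier.pop()
        for tid, consume, produce, reads, inhibits, gate in compiled:
            if any(m[p] < c for p, c in consume.items()):
                continue
            if any(m[p] < 1 for p in reads):
                continue
            if any(m[p] > 0 for p in inhibits):
                continue
            nxt = list(m)
            for p, c in consume.items():
                nxt[p] -= c
            for p, c in produce.items():
                nxt[p] += c
            t = tuple(nxt)
            if t not in seen:
                if len(seen) >= max_states:
                    raise RuntimeError("state space too large for the oracle")
                seen.add(t)
                frontier.append(t)
    return {frozenset((places[i], c) for i, c in enumerate(m) if c) for m in seen}


def build_and_net():
    """P1, P2 → AND → process → OUT, converted."""
    g = _graph()
    g.add_node(_comp("p1", "P1"))
    g.add_node(_comp("p2", "P2"))
    g.add_node(_comp("out", "OUT1"))
    g.add_node(PathwayNode("and1", NodeClass("boolean_operator", "AND")))
    g.add_node(PathwayNode("proc", NodeClass("process", "P")))
    g.connect("p1", "and1")
    g.connect("p2", "and1")
    g.connect("and1", "proc")
    g.connect("proc", "out")
    return to_petri_net(g)


def build_or_net():
    """Three kinases → OR →(C) phosphorylation of one substrate, converted."""
    g = _graph()
    for nid, label in [("s", "MAPK14"), ("sp", "MAPK14 [P]"),
                       ("k1", "MAP2K3"), ("k2", "MAP2K6"), ("k3", "MAP2K7")]:
        g.add_node(_comp(nid, label))
    g.add_node(PathwayNode("or1", NodeClass("boolean_operator", "OR")))
    g.add_node(PathwayNode("proc", NodeClass("process", "P")))
    for k in ("k1", "k2", "k3"):
        g.connect(k, "or1")
    g.connect("or1", "proc", annotation="C")
    g.connect("s", "proc")
    g.connect("proc", "sp")
    return to_petri_net(g)


def build_transport_chain():
    """C1 →(T)→ C2 →(T)→ C3, converted: a pure conservative chain."""
    g = _graph()
    g.add_node(_comp("p1", "C1"))
    g.add_node(_comp("p2", "C2"))
    g.add_node(_comp("p3", "C3"))
    g.add_node(PathwayNode("t1", NodeClass("process", "T")))
    g.add_node(PathwayNode("t2", NodeClass("process", "T")))
    g.connect("p1", "t1")
    g.connect("t1", "p2")
    g.connect("p2", "t2")
    g.connect("t2", "p3")
    return to_petri_net(g)


class TestConversion:
    def test_cleavage_chain_maps_to_two_places_one_transition(self):
        g = _graph()
        g.add_node(_comp("a", "A"))
        g.add_node(_comp("at", "A [t]"))
        g.add_node(PathwayNode("x", NodeClass("process", "X")))
        g.connect("a", "x")
        g.connect("x", "at")
        net = to_petri_net(g)
        assert len(net.places) == 2
        assert len(net.transitions) == 1
        assert len(net.arcs) == 2
        assert net.is_bipartite()

    def test_catalyst_becomes_read_arc_and_energy_side_condition(self):
        # cleavage of A by catalyst B, ATP-driven: B and the energy node gate
        # the transition through read arcs and are never consumed
        g = _graph()
        g.add_node(_comp("a", "A"))
        g.add_node(_comp("b", "B"))
        g.add_node(_comp("at", "A [t]"))
        g.add_node(PathwayNode("x", NodeClass("process", "X")))
        g.add_node(PathwayNode("e", NodeClass("energy_transfer", "energy_transfer"),
                               "ATP -> ADP"))
        g.connect("a", "x")
        g.connect("b", "x", annotation="C")
        g.connect("e", "x")
        g.connect("x", "at")
        net = to_petri_net(g)
        reads = {a.source for a in net.arcs if a.kind == "read"}
        assert reads == {"p:b", "p:e"}
        # without the side conditions the reaction is blocked
        traj = simulate(net, {"p:a": 1}, steps=5, runs=3, seed=0)
        assert traj.final_mean("p:at") == 0.0
        traj = simulate(net, {"p:a": 1, "p:b": 1, "p:e": 1}, steps=5, runs=3, seed=0)
        assert traj.final_mean("p:at") == 1.0
        assert traj.final_mean("p:b") == 1.0  # read arcs do not consume

    def test_and_inputs_become_one_arc_each(self):
        net = build_and_net()
        in_arcs = [a for a in net.arcs if a.target == "t:proc" and a.kind == "normal"]
        assert {a.source for a in in_arcs} == {"p:p1", "p:p2"}

    def test_or_branches_become_parallel_transitions(self):
        net = build_or_net()
        producing = [a.source for a in net.arcs
                     if a.target == "p:sp" and a.kind == "normal"]
        assert len(producing) == 3  # one transition per kinase branch
        assert net.is_bipartite()

    def test_validation_errors_refuse_conversion(self):
        g = _graph()
        g.add_node(_comp("a", "STAT1"))
        g.add_node(_comp("b", "STAT1"))
        with pytest.raises(PetriNetError) as err:
            to_petri_net(g)
        assert any(i.rule_id == "R1_UNIQUE_PER_COMPARTMENT" for i in err.value.issues)

    def test_physical_bonds_contribute_no_arcs(self):
        net = to_petri_net(build_enhanceosome())
        assert net.arcs == []
        assert len(net.places) == len(build_enhanceosome().nodes)

    def test_bipartite_on_fixtures_and_random_graphs(self, ifng_graph, random_graphs):
        import networkx as nx
        for g in [ifng_graph, *random_graphs]:
            net = to_petri_net(g)
            assert net.is_bipartite(), g.name
            # independent check through networkx two-colouring
            h = nx.DiGraph()
            h.add_nodes_from(net.places, bipartite=0)
            h.add_nodes_from(net.transitions, bipartite=1)
            h.add_edges_from((a.source, a.target) for a in net.arcs)
            colours = {n: (0 if n in net.places else 1) for n in h}
            assert all(colours[u] != colours[v] for u, v in h.edges)

    def test_every_element_has_provenance(self, ifng_graph):
        net = to_petri_net(ifng_graph)
        for element in [*net.places, *net.transitions]:
            assert net.provenance(element)


class TestSimulation:
    def test_transport_conserves_tokens_and_delivers(self):
        net = build_transport_chain()
        traj = simulate(net, {"p:p1": 1}, steps=10, runs=5, seed=3)
        assert traj.final_mean("p:p3") == 1.0
        totals = traj.means.sum(axis=1)
        assert np.allclose(totals, 1.0)  # conserved at every recorded step

    def test_and_gate_blocks_with_missing_input(self):
        net = build_and_net()
        traj = simulate(net, {"p:p1": 1}, steps=10, runs=10, seed=1)
        assert traj.final_mean("p:out") == 0.0
        assert np.all(traj.means[:, traj.places.index("p:out")] == 0.0)
        traj = simulate(net, {"p:p1": 1, "p:p2": 1}, steps=10, runs=10, seed=1)
        assert traj.final_mean("p:out") == 1.0

    def test_inhibitor_arc_hard_blocks(self):
        g = _graph()
        g.add_node(_comp("a", "A"))
        g.add_node(_comp("b", "B"))
        g.add_node(_comp("s", "SOCS1"))
        g.add_node(PathwayNode("proc", NodeClass("process", "P")))
        g.connect("a", "proc")
        g.connect("proc", "b")
        g.connect("s", "proc", annotation="I")
        net = to_petri_net(g)
        blocked = simulate(net, {"p:a": 1, "p:s": 1}, steps=10, runs=5, seed=2)
        assert blocked.final_mean("p:b") == 0.0
        free = simulate(net, {"p:a": 1}, steps=10, runs=5, seed=2)
        assert free.final_mean("p:b") == 1.0

    def test_adding_inhibitor_arc_never_increases_output(self):
        for seed in (0, 1, 2):
            net = build_transport_chain()
            base = simulate(net, {"p:p1": 3}, steps=8, runs=10, seed=seed)
            net.places["p:ext"] = "ext"
            net.arcs.append(Arc("p:ext", "t:t1", "inhibitor"))
            gated = simulate(net, {"p:p1": 3, "p:ext": 1}, steps=8, runs=10, seed=seed)
            assert gated.final_mean("p:p3") <= base.final_mean("p:p3")

    def test_conditional_gate_fires_one_branch_per_step(self):
        g = _graph()
        g.add_node(_comp("chol", "CHOL"))
        g.add_node(_comp("f1", "F1"))
        g.add_node(_comp("f2", "F2"))
        g.add_node(PathwayNode("gate", NodeClass("conditional_gate",
                                                 "conditional_gate")))
        g.connect("chol", "gate")
        g.connect("gate", "f1")
        g.connect("gate", "f2")
        net = to_petri_net(g)
        assert len(net.transitions) == 2
        steps, tokens = 6, 10
        traj = simulate(net, {"p:chol": tokens}, steps=steps, runs=40, seed=5)
        f1 = traj.final_mean("p:f1")
        f2 = traj.final_mean("p:f2")
        assert f1 + f2 == pytest.approx(min(steps, tokens))
        assert f1 > 0 and f2 > 0  # both outcomes realised across runs

    def test_identical_seed_identical_trajectory(self, ifng_graph):
        net = to_petri_net(ifng_graph)
        m = ifng_marking(net)
        a = simulate(net, m, steps=30, runs=5, seed=42)
        b = simulate(net, m, steps=30, runs=5, seed=42)
        assert a.places == b.places
        assert np.array_equal(a.means, b.means)

    def test_trajectory_shape_and_contract_errors(self):
        net = build_transport_chain()
        traj = simulate(net, {"p:p1": 1}, steps=7, runs=2, seed=0)
        assert traj.means.shape == (8, len(net.places))
        assert np.all(traj.means >= 0)
        with pytest.raises(PetriNetError):
            simulate(net, {}, steps=0, runs=1, seed=0)
        with pytest.raises(PetriNetError):
            simulate(net, {"p:nope": 1}, steps=1, runs=1, seed=0)


class TestOrEquivalence:
    def test_or_reachability_matches_parallel_transition_oracle(self):
        """An OR with k inputs reaches exactly the markings of k hand-built
        parallel single-branch transitions (brute-force comparison)."""
        converted = build_or_net()
        oracle = PetriNet(
            places={p: p[2:] for p in
                    ("p:s", "p:sp", "p:k1", "p:k2", "p:k3")},
            transitions={f"man{i}": f"man{i}" for i in range(3)},
        )
        for i, k in enumerate(("p:k1", "p:k2", "p:k3")):
            oracle.arcs += [
                Arc(k, f"man{i}", "read"),
                Arc("p:s", f"man{i}", "normal"),
                Arc(f"man{i}", "p:sp", "normal"),
            ]
        initial = {"p:s": 2, "p:k1": 1, "p:k3": 1}
        assert reachable_markings(converted, initial) == reachable_markings(
            oracle, initial)


class TestExports:
    def test_petri_graphml_is_deterministic_and_typed(self, ifng_graph):
        net = to_petri_net(ifng_graph)
        a = petri_to_graphml(net)
        assert a == petri_to_graphml(net)
        assert b"place" in a and b"transition" in a

    def test_arc_and_trajectory_tables(self):
        net = build_transport_chain()
        table = arc_table(net)
        assert table.splitlines()[0] == "source\ttarget\tkind"
        assert len(table.splitlines()) == 1 + len(net.arcs)
        traj = simulate(net, {"p:p1": 1}, steps=3, runs=2, seed=0)
        text = trajectory_table(traj)
        assert text.splitlines()[0] == "step\tplace\tmean_tokens"
        assert len(text.splitlines()) == 1 + 4 * len(net.places)
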