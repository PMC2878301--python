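"""Worked-example pathway builders and a random conformant-graph generator.

The builders reconstruct, node by node, the published worked examples the
notation was demonstrated on — the interferon-gamma receptor complex, the
26S proteasome's ring layout, the MHC class II enhanceosome, and the full
IFNγ → MHC class II antigen-presentation pathway — so every other module can
be exercised end to end without any external data. Counts asserted in tests
(subunit stoichiometries, ring dimensions, promoter-element and complex
counts) come from the printed description of each example.

:func:`random_pathway` generates conformant-by-construction random diagrams
for property testing: every graph it returns validates cleanly, round-trips
through GraphML and converts to a bipartite net.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Tuple

import numpy as np

from .model import Compartment, NodeClass, PathwayGraph, PathwayNode, create_pathway
from .petri import PetriNet

__all__ = [
    "build_receptor_complex",
    "ProteasomeLayout",
    "build_proteasome_core",
    "build_enhanceosome",
    "build_ifng_mhc2_pathway",
    "ifng_marking",
    "MHC2_OUTPUT_NODE",
    "random_pathway",
    "fixture_catalogue",
]

RECEPTOR_LABEL = "IFNGR1<2>:IFNGR2<2>:JAK1<2>:JAK2<2>"
MHC2_COMPLEX_LABEL = "CD74 (li):HLA-D (alpha):HLA-D (beta)"
MHC2_OUTPUT_NODE = "out_mhc2"


def _component(nid, subclass, label, compartment=None, **kw) -> PathwayNode:
    return PathwayNode(nid, NodeClass("component", subclass), label,
                       compartment=compartment, **kw)


def _node(nid, kind, subclass, label="", compartment=None, **kw) -> PathwayNode:
    return PathwayNode(nid, NodeClass(kind, subclass), label,
                       compartment=compartment, **kw)


def build_receptor_complex() -> PathwayNode:
    """The IFNγ receptor complex: IFNGR1, IFNGR2, JAK1 and JAK2 with two
    copies of each protein, drawn as one complex in the plasma membrane."""
    return _component("receptor", "protein_complex", RECEPTOR_LABEL,
                      compartment="plasma_membrane")


@dataclass(frozen=True)
class ProteasomeLayout:
    """The 26S proteasome drawn structurally: subunit names arranged as six
    concentric rings of seven subunits forming the core barrel, with a
    regulatory cap group at either end."""

    rings: Tuple[Tuple[str, ...], ...]
    caps: Tuple[Tuple[str, ...], Tuple[str, ...]]

    @property
    def label(self) -> str:
        subs = [s for ring in self.rings for s in ring]
        subs += [s for cap in self.caps for s in cap]
        return ":".join(subs)


def build_proteasome_core() -> ProteasomeLayout:
    alpha = tuple(f"PSMA{i}" for i in range(1, 8))
    beta = tuple(f"PSMB{i}" for i in range(1, 8))
    return ProteasomeLayout(
        rings=(alpha, beta, alpha, beta, alpha, beta),
        caps=(
            tuple(f"PSMC{i}" for i in range(1, 7)),
            tuple(f"PSMD{i}" for i in range(1, 7)),
        ),
    )


def build_enhanceosome() -> PathwayGraph:
    """The MHC class II enhanceosome on the CD74 promoter.

    Four promoter elements (the S, X, X2 and Y boxes) are bound by the
    preassembled transcription-factor complexes — the RFX trimer on X, CREB1
    on X2, the NFY trimer on Y and one unknown factor on S — with CIITA
    joining the assembly; every intra-assembly link is an undirected physical
    bond. Node-id lists are stored in ``graph.metadata``.
    """
    g = create_pathway("enhanceosome")
    g.add_compartment(Compartment("nucleus", "nucleus", "green"))
    g.add_node(_component("gene_cd74", "gene", "CD74", "nucleus"))
    elements = {
        "pe_s": "S-box", "pe_x": "X-box", "pe_x2": "X2-box", "pe_y": "Y-box",
    }
    for nid, label in elements.items():
        g.add_node(_component(nid, "gene", label, "nucleus"))
        g.connect("gene_cd74", nid, directed=False)
    binders = {
        "tf_unknown": ("protein", "UNKF (unknown factor)", "pe_s"),
        "tf_rfx": ("protein_complex", "RFX5:RFXANK:RFXAP", "pe_x"),
        "tf_creb1": ("protein", "CREB1", "pe_x2"),
        "tf_nfy": ("protein_complex", "NFYA:NFYB:NFYC", "pe_y"),
    }
    for nid, (subclass, label, element) in binders.items():
        g.add_node(_component(nid, subclass, label, "nucleus"))
        g.connect(nid, element, directed=False)
    g.add_node(_component("ciita", "protein", "CIITA", "nucleus"))
    g.connect("ciita", "tf_rfx", directed=False)
    g.connect("ciita", "tf_creb1", directed=False)
    g.metadata["promoter_elements"] = sorted(elements)
    g.metadata["tf_complexes"] = sorted(binders)
    return g


def build_ifng_mhc2_pathway() -> PathwayGraph:
    """The IFNγ → MHC class II antigen-presentation pathway.

    Encodes the narrated chain of events: IFNG dimerises and binds its
    receptor complex; JAK2 autophosphorylates (ATP-driven; inhibitable by
    SOCS1 or SOCS3 via an OR, reversed by PTPN2); STAT1 is phosphorylated
    (Y701), dimerises, is further phosphorylated by PRKCD (S727) and
    translocates to the nucleus; there it activates the SOCS1 (feedback) and
    IRF1 (feed-forward) genes through one distribution node; the pIV
    (STAT1:IRF1:USF1:IRF2) and pIII (STAT1:CREB1:RUNX2/3:TCF3:SPI1:IRF4)
    complexes assemble and activate the CIITA gene; CIITA protein joins the
    preassembled RFX/NFY/CREB1 enhanceosome complex, switching on the MHC
    class II genes; their products assemble into the generic
    CD74 (li):HLA-D (alpha):HLA-D (beta) complex, which feeds — through one
    pathway-module black box for the long antigen-loading step series — the
    terminal antigen-presentation pathway output.
    """
    g = create_pathway("ifng_mhc2")
    g.add_compartment(Compartment("extracellular", "extracellular space", "grey"))
    g.add_compartment(Compartment("plasma_membrane", "plasma membrane", "brown"))
    g.add_compartment(Compartment("cytoplasm", "cytoplasm", "yellow"))
    g.add_compartment(Compartment("nucleus", "nucleus", "green"))

    # ligand, receptor, activation
    g.add_node(_component("ifng", "protein", "IFNG", "extracellular"))
    g.add_node(_node("p_olig_ifng", "process", "O"))
    g.add_node(_component("ifng_dimer", "protein_complex", "IFNG:IFNG", "extracellular"))
    g.add_node(build_receptor_complex())
    g.add_node(_node("p_bind_rec", "process", "B"))
    g.add_node(_component("bound_rec", "protein_complex",
                          f"IFNG:IFNG:{RECEPTOR_LABEL}", "plasma_membrane"))
    g.add_node(_node("p_autophos", "process", "AP"))
    g.add_node(_component("active_rec", "protein_complex",
                          f"IFNG:IFNG:{RECEPTOR_LABEL} [P]", "plasma_membrane"))
    g.add_node(_node("energy_atp", "energy_transfer", "energy_transfer", "ATP -> ADP"))
    g.connect("ifng", "p_olig_ifng")
    g.connect("p_olig_ifng", "ifng_dimer")
    g.connect("ifng_dimer", "p_bind_rec")
    g.connect("receptor", "p_bind_rec")
    g.connect("p_bind_rec", "bound_rec")
    g.connect("bound_rec", "p_autophos")
    g.connect("p_autophos", "active_rec")
    g.connect("energy_atp", "p_autophos")

    # SOCS feedback inhibition and PTPN2 reversal
    g.add_node(_component("socs1", "protein", "SOCS1", "cytoplasm"))
    g.add_node(_component("socs3", "protein", "SOCS3", "cytoplasm"))
    g.add_node(_node("or_socs", "boolean_operator", "OR"))
    g.connect("socs1", "or_socs")
    g.connect("socs3", "or_socs")
    g.connect("or_socs", "p_autophos", annotation="I")
    g.add_node(_component("ptpn2", "protein", "PTPN2", "cytoplasm"))
    g.add_node(_node("p_dephos", "process", "-P"))
    g.connect("active_rec", "p_dephos")
    g.connect("p_dephos", "bound_rec")
    g.connect("ptpn2", "p_dephos", annotation="C")

    # STAT1 activation, dimerisation, nuclear translocation
    g.add_node(_component("stat1", "protein", "STAT1", "cytoplasm"))
    g.add_node(_node("p_phos_stat1", "process", "P"))
    g.add_node(_component("stat1_p", "protein", "STAT1 [P-Y701]", "cytoplasm"))
    g.connect("stat1", "p_phos_stat1")
    g.connect("p_phos_stat1", "stat1_p")
    g.connect("active_rec", "p_phos_stat1", annotation="C")
    g.add_node(_node("p_olig_stat1", "process", "O"))
    g.add_node(_component("stat1_dimer", "protein_complex",
                          "STAT1 [P-Y701]:STAT1 [P-Y701]", "cytoplasm"))
    g.connect("stat1_p", "p_olig_stat1")
    g.connect("p_olig_stat1", "stat1_dimer")
    g.add_node(_component("prkcd", "protein", "PRKCD", "cytoplasm"))
    g.add_node(_node("p_phos_prkcd", "process", "P"))
    g.add_node(_component("stat1_dimer_pp", "protein_complex",
                          "STAT1 [P-Y701] [P-S727]:STAT1 [P-Y701] [P-S727]",
                          "cytoplasm"))
    g.connect("stat1_dimer", "p_phos_prkcd")
    g.connect("p_phos_prkcd", "stat1_dimer_pp")
    g.connect("prkcd", "p_phos_prkcd", annotation="C")
    g.add_node(_node("p_transloc", "process", "T"))
    g.add_node(_component("stat1_dimer_nu", "protein_complex",
                          "STAT1 [P-Y701] [P-S727]:STAT1 [P-Y701] [P-S727]",
                          "nucleus"))
    g.connect("stat1_dimer_pp", "p_transloc")
    g.connect("p_transloc", "stat1_dimer_nu")

    # direct gene activation (one distribution node for the fan-out)
    g.add_node(_node("ann_stat_targets", "edge_annotation", "A",
                     is_distribution=True))
    g.add_node(_component("gene_socs1", "gene", "SOCS1", "nucleus"))
    g.add_node(_component("gene_irf1", "gene", "IRF1", "nucleus"))
    g.connect("stat1_dimer_nu", "ann_stat_targets")
    g.connect("ann_stat_targets", "gene_socs1")
    g.connect("ann_stat_targets", "gene_irf1")
    g.add_node(_node("p_expr_socs1", "process", "TR"))
    g.connect("gene_socs1", "p_expr_socs1")
    g.connect("p_expr_socs1", "socs1")
    g.add_node(_component("irf1", "protein", "IRF1", "nucleus"))
    g.add_node(_node("p_expr_irf1", "process", "TR"))
    g.connect("gene_irf1", "p_expr_irf1")
    g.connect("p_expr_irf1", "irf1")

    # the two CIITA-activating complexes (pIV and pIII)
    for nid, label in [("usf1", "USF1"), ("irf2", "IRF2"), ("creb1", "CREB1"),
                       ("runx", "RUNX2/3"), ("tcf3", "TCF3"), ("spi1", "SPI1"),
                       ("irf4", "IRF4")]:
        g.add_node(_component(nid, "protein", label, "nucleus"))
    g.add_node(_node("p_bind_piv", "process", "B"))
    g.add_node(_component("piv_complex", "protein_complex",
                          "STAT1:IRF1:USF1:IRF2", "nucleus"))
    for src in ("stat1_dimer_nu", "irf1", "usf1", "irf2"):
        g.connect(src, "p_bind_piv")
    g.connect("p_bind_piv", "piv_complex")
    g.add_node(_node("p_bind_piii", "process", "B"))
    g.add_node(_component("piii_complex", "protein_complex",
                          "STAT1:CREB1:RUNX2/3:TCF3:SPI1:IRF4", "nucleus"))
    for src in ("stat1_dimer_nu", "creb1", "runx", "tcf3", "spi1", "irf4"):
        g.connect(src, "p_bind_piii")
    g.connect("p_bind_piii", "piii_complex")
    g.add_node(_component("gene_ciita", "gene", "CIITA", "nucleus"))
    g.connect("piv_complex", "gene_ciita", annotation="A")
    g.connect("piii_complex", "gene_ciita", annotation="A")

    # CIITA joins the preassembled enhanceosome complex
    g.add_node(_node("p_expr_ciita", "process", "TR"))
    g.add_node(_component("ciita", "protein", "CIITA", "nucleus"))
    g.connect("gene_ciita", "p_expr_ciita")
    g.connect("p_expr_ciita", "ciita")
    g.add_node(_component("enh_pre", "protein_complex",
                          "RFX5:RFXANK:RFXAP:NFYA:NFYB:NFYC:CREB1", "nucleus"))
    g.add_node(_node("p_bind_enh", "process", "B"))
    g.add_node(_component("enhanceosome", "protein_complex",
                          "CIITA:RFX5:RFXANK:RFXAP:NFYA:NFYB:NFYC:CREB1",
                          "nucleus"))
    g.connect("ciita", "p_bind_enh")
    g.connect("enh_pre", "p_bind_enh")
    g.connect("p_bind_enh", "enhanceosome")

    # MHC class II gene battery and the generic peptide-receptor complex
    g.add_node(_node("ann_mhc_targets", "edge_annotation", "A",
                     is_distribution=True))
    g.connect("enhanceosome", "ann_mhc_targets")
    for nid, label in [("gene_cd74", "CD74"), ("gene_hla_dp", "HLA-DPA/B"),
                       ("gene_hla_dq", "HLA-DQA/B"), ("gene_hla_dr", "HLA-DRA/B")]:
        g.add_node(_component(nid, "gene", label, "nucleus"))
        g.connect("ann_mhc_targets", nid)
    g.add_node(_node("p_expr_cd74", "process", "TR"))
    g.add_node(_component("cd74", "protein", "CD74 (li)", "cytoplasm"))
    g.connect("gene_cd74", "p_expr_cd74")
    g.connect("p_expr_cd74", "cd74")
    g.add_node(_node("p_expr_hla_a", "process", "TR"))
    g.add_node(_component("hla_alpha", "protein", "HLA-DRA", "cytoplasm"))
    g.connect("gene_hla_dp", "p_expr_hla_a")
    g.connect("p_expr_hla_a", "hla_alpha")
    g.add_node(_node("or_hla", "boolean_operator", "OR"))
    g.add_node(_node("p_expr_hla_b", "process", "TR"))
    g.add_node(_component("hla_beta", "protein", "HLA-DRB1", "cytoplasm"))
    g.connect("gene_hla_dq", "or_hla")
    g.connect("gene_hla_dr", "or_hla")
    g.connect("or_hla", "p_expr_hla_b")
    g.connect("p_expr_hla_b", "hla_beta")
    g.add_node(_node("p_bind_mhc", "process", "B"))
    g.add_node(_component("mhc2_complex", "protein_complex",
                          MHC2_COMPLEX_LABEL, "cytoplasm"))
    for src in ("cd74", "hla_alpha", "hla_beta"):
        g.connect(src, "p_bind_mhc")
    g.connect("p_bind_mhc", "mhc2_complex")

    # the long antigen-loading step series, collapsed into one module
    g.add_node(_node("mod_antigen", "pathway_module", "pathway_module",
                     "antigen processing and loading"))
    g.add_node(_node(MHC2_OUTPUT_NODE, "pathway_output", "pathway_output",
                     "MHC class II antigen presentation"))
    g.connect("mhc2_complex", "mod_antigen")
    g.connect("mod_antigen", MHC2_OUTPUT_NODE, style="light_blue")
    g.metadata["ciita_activating_complexes"] = ["piii_complex", "piv_complex"]
    return g


def ifng_marking(net: PetriNet, *, ligand_tokens: int = 6,
                 socs1_tokens: int = 0) -> Dict[str, int]:
    """Default initial marking for the IFNγ fixture's net: constitutive
    proteins and the ATP side condition hold tokens, induced species start
    empty. ``ligand_tokens`` seeds the IFNG place; ``socs1_tokens`` pre-loads
    the SOCS1 place to model constitutive feedback inhibition."""
    marking = {
        "p:ifng": ligand_tokens,
        "p:receptor": 3,
        "p:energy_atp": 1,
        "p:stat1": 6,
        "p:ptpn2": 1,
        "p:prkcd": 1,
        "p:usf1": 3, "p:irf2": 3, "p:creb1": 3, "p:runx": 3,
        "p:tcf3": 3, "p:spi1": 3, "p:irf4": 3,
        "p:enh_pre": 3,
    }
    if socs1_tokens:
        marking["p:socs1"] = socs1_tokens
    return {k: v for k, v in marking.items() if k in net.places}


# --------------------------------------------------------------- generator

_MOD_CODES = ("P", "Ub", "Ac", "Me")


def random_pathway(seed: int, n_components: int, n_processes: int) -> PathwayGraph:
    """A conformant-by-construction random pathway, deterministic per seed.

    Components (unique symbols, occasional stoichiometry and modification
    decorations) are spread over two to five compartments; processes are
    drawn from the registry and wired with legal arities; AND/OR operators,
    annotated influence edges, distribution nodes and energy-transfer side
    conditions appear with moderate probability. The returned graph always
    passes validation with zero errors.
    """
    if n_components < 1 or n_processes < 0:
        raise ValueError("need n_components >= 1 and n_processes >= 0")
    rng = np.random.default_rng(seed)
    g = create_pathway(f"random_{seed}")
    n_comp = int(rng.integers(2, 6))
    comp_ids = [f"c{i}" for i in range(n_comp)]
    names = ["extracellular", "plasma membrane", "cytoplasm", "endosome", "vesicle"]
    for i, cid in enumerate(comp_ids):
        g.add_compartment(Compartment(cid, names[i % len(names)], "yellow"))

    comp_nodes: List[str] = []
    for i in range(n_components):
        label = f"PX{i}"
        subclass = "protein"
        r = rng.random()
        if r < 0.15:
            label += f"<{int(rng.integers(2, 5))}>"
            subclass = "protein_complex"
        elif r < 0.3:
            label += f" [{_MOD_CODES[int(rng.integers(0, len(_MOD_CODES)))]}]"
        elif r < 0.4:
            subclass = "ion_simple_molecule"
        nid = f"n{i}"
        g.add_node(_component(nid, subclass, label,
                              comp_ids[int(rng.integers(0, n_comp))]))
        comp_nodes.append(nid)

    registry = g.registry
    usable = sorted(
        code for code, pc in registry.process_classes.items()
        if pc.min_inputs <= max(1, min(3, n_components))
        and pc.min_outputs <= max(1, min(3, n_components))
    )

    def sample(k: int) -> List[str]:
        if k <= len(comp_nodes):
            idx = rng.choice(len(comp_nodes), size=k, replace=False)
        else:
            idx = rng.integers(0, len(comp_nodes), size=k)
        return [comp_nodes[int(i)] for i in idx]

    for j in range(n_processes):
        code = usable[int(rng.integers(0, len(usable)))]
        pc = registry.process_classes[code]
        k_in = int(rng.integers(pc.min_inputs,
                                int(min(pc.max_inputs, 3, n_components)) + 1))
        k_out = int(rng.integers(pc.min_outputs,
                                 int(min(pc.max_outputs, 3, n_components)) + 1))
        pid = f"proc{j}"
        g.add_node(_node(pid, "process", code))
        for src in sample(k_in):
            g.connect(src, pid)
        for tgt in sample(k_out):
            g.connect(pid, tgt)
        r = rng.random()
        if r < 0.2 and n_components >= 2:
            op = "AND" if r < 0.1 else "OR"
            bid = f"bool{j}"
            g.add_node(_node(bid, "boolean_operator", op))
            for src in sample(2):
                g.connect(src, bid)
            g.connect(bid, pid, annotation="C" if rng.random() < 0.5 else None)
        elif r < 0.3:
            eid = f"energy{j}"
            g.add_node(_node(eid, "energy_transfer", "energy_transfer", "ATP -> ADP"))
            g.connect(eid, pid)

    n_influence = int(rng.integers(0, max(1, n_components // 3) + 1))
    for j in range(n_influence):
        if n_components < 2:
            break
        src, tgt = sample(2)
        code = ("A", "I", "C")[int(rng.integers(0, 3))]
        if rng.random() < 0.5:
            g.connect(src, tgt, annotation=code)
        else:
            aid = f"ann{j}"
            fan = int(rng.integers(1, min(3, n_components)))
            targets = sample(fan)
            g.add_node(_node(aid, "edge_annotation", code,
                             is_distribution=fan > 1))
            g.connect(src, aid)
            for t in targets:
                g.connect(aid, t)
    return g


def fixture_catalogue() -> Dict[str, Callable]:
    """Named builders for every worked-example fixture."""
    return {
        "receptor_complex": build_receptor_complex,
        "proteasome_core": build_proteasome_core,
        "enhanceosome": build_enhanceosome,
        "ifng_mhc2": build_ifng_mhc2_pathway,
    }
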