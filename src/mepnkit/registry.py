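"""The mEPN glyph registry.

Every node drawn in an mEPN diagram belongs to a glyph class: a cellular
component (protein, complex, gene, ion/simple molecule, pathogen), a circular
process node carrying a one-to-three-letter code, a Boolean logic operator
(AND/OR/NOT), an in-line edge annotation (A activation, I inhibition,
C catalysis), or one of the auxiliary classes (energy/molecular transfer,
conditional gate, pathway module, pathway output, compartment label).

The registry catalogues these classes with their arity conventions and their
2D and 3D style records. Meaning is never carried by colour alone: the pair
(shape, printed code) identifies the class, colour is a reading aid.

The process-code table ships with exactly 31 entries. The codes anchored in
the notation's published description (binding B, dissociation D, cleavage X,
oligomerisation O, phosphorylation family, ubiquitination, translocation, …)
are fixed; the remaining entries are sensible defaults for the common
post-translational modifications and expression steps and are provisional —
any of them can be renamed, restyled, disabled or replaced through a YAML
override file (see :func:`load_registry_overrides`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, ConfigDict

__all__ = [
    "RegistryError",
    "UnknownGlyphError",
    "ProcessClass",
    "StyleRecord",
    "GlyphRegistry",
    "default_registry",
    "lookup_process",
    "load_registry_overrides",
]

UNBOUNDED = math.inf


class RegistryError(ValueError):
    """A registry or override document violates the glyph rules."""


class UnknownGlyphError(KeyError):
    """Lookup of a code that is not in the registry."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; keep a sentence
        return f"unknown glyph code {self.code!r}"


@dataclass(frozen=True)
class ProcessClass:
    """One circular process-node class, identified by a 1-3 character code.

    Arity bounds count edges on the component path only (annotated catalytic
    inputs, Boolean constructs and energy-transfer side conditions are not
    limited): a binding node takes several inputs and emits one product, a
    dissociation node the reverse.
    """

    code: str
    name: str
    category: str
    min_inputs: int = 1
    max_inputs: float = UNBOUNDED
    min_outputs: int = 1
    max_outputs: float = UNBOUNDED

    def __post_init__(self) -> None:
        if not 1 <= len(self.code) <= 3:
            raise RegistryError(
                f"process code {self.code!r} must be 1-3 characters long"
            )


@dataclass(frozen=True)
class StyleRecord:
    """2D and 3D rendering style for one glyph class.

    ``shape2d`` uses editor shape names (roundrectangle, diamond, ellipse, …);
    ``shape3d`` is the solid the 2D glyph translates to (components become
    spheres or boxes, process nodes small cubes) with a relative size scalar.
    Colour tags map to hex via :data:`COLOUR_TABLE`.
    """

    shape2d: str
    fill: str
    border: str = "black"
    shape3d: str = "sphere"
    size3d: float = 1.0


# colour tags -> hex, used by the editor-dialect GraphML writer
COLOUR_TABLE: Dict[str, str] = {
    "black": "#000000",
    "white": "#FFFFFF",
    "light_blue": "#ADD8E6",
    "mid_blue": "#3366CC",
    "dark_blue": "#000080",
    "yellow": "#FFFF99",
    "orange": "#FFA500",
    "red": "#CC0000",
    "green": "#66CC66",
    "dark_green": "#006600",
    "purple": "#9370DB",
    "pink": "#FFB6C1",
    "brown": "#996633",
    "grey": "#C0C0C0",
    "light_grey": "#E8E8E8",
    "lilac": "#CC99FF",
    "cream": "#FFF8DC",
}


@dataclass(frozen=True)
class GlyphRegistry:
    """Immutable catalogue of glyph classes and their styles."""

    process_classes: Mapping[str, ProcessClass]
    component_classes: Tuple[str, ...]
    boolean_ops: Tuple[str, ...]
    edge_annotations: Mapping[str, str]  # code -> meaning
    other_node_classes: Tuple[str, ...]
    styles: Mapping[Tuple[str, str], StyleRecord]  # (kind, subclass) -> style

    def __post_init__(self) -> None:
        for code, pc in self.process_classes.items():
            if code != pc.code:
                raise RegistryError(f"process table key {code!r} != class code {pc.code!r}")
        for kind, subclasses in self.class_table().items():
            for sub in subclasses:
                if (kind, sub) not in self.styles:
                    raise RegistryError(f"class {kind}/{sub} has no style record")

    def class_table(self) -> Dict[str, Tuple[str, ...]]:
        return {
            "component": self.component_classes,
            "process": tuple(self.process_classes),
            "boolean_operator": self.boolean_ops,
            "edge_annotation": tuple(self.edge_annotations),
            "energy_transfer": ("energy_transfer",),
            "conditional_gate": ("conditional_gate",),
            "pathway_module": ("pathway_module",),
            "pathway_output": ("pathway_output",),
            "compartment_label": ("compartment_label",),
        }

    def is_registered(self, kind: str, subclass: str) -> bool:
        return subclass in self.class_table().get(kind, ())

    def style(self, kind: str, subclass: str) -> StyleRecord:
        try:
            return self.styles[(kind, subclass)]
        except KeyError:
            raise UnknownGlyphError(f"{kind}/{subclass}") from None


def _process_table() -> Dict[str, ProcessClass]:
    inf = UNBOUNDED
    entries: List[ProcessClass] = [
        # junction-like
        ProcessClass("B", "binding", "binding", min_inputs=2, max_inputs=inf,
                     min_outputs=1, max_outputs=1),
        ProcessClass("O", "oligomerisation", "binding", min_inputs=1, max_inputs=inf,
                     min_outputs=1, max_outputs=1),
        ProcessClass("D", "dissociation", "dissociation", min_inputs=1, max_inputs=1,
                     min_outputs=2, max_outputs=inf),
        ProcessClass("X", "cleavage", "dissociation", min_inputs=1, max_inputs=1,
                     min_outputs=1, max_outputs=inf),
        # covalent state modifications (1-in/1-out on the component path)
        ProcessClass("P", "phosphorylation", "modification", 1, 1, 1, 1),
        ProcessClass("AP", "auto-phosphorylation", "modification", 1, 1, 1, 1),
        ProcessClass("-P", "dephosphorylation", "modification", 1, 1, 1, 1),
        ProcessClass("Ub", "ubiquitination", "modification", 1, 1, 1, 1),
        ProcessClass("-Ub", "deubiquitination", "modification", 1, 1, 1, 1),
        ProcessClass("Su", "sumoylation", "modification", 1, 1, 1, 1),
        ProcessClass("-Su", "desumoylation", "modification", 1, 1, 1, 1),
        ProcessClass("Ac", "acetylation", "modification", 1, 1, 1, 1),
        ProcessClass("-Ac", "deacetylation", "modification", 1, 1, 1, 1),
        ProcessClass("Me", "methylation", "modification", 1, 1, 1, 1),
        ProcessClass("-Me", "demethylation", "modification", 1, 1, 1, 1),
        ProcessClass("Gly", "glycosylation", "modification", 1, 1, 1, 1),
        ProcessClass("Pal", "palmitoylation", "modification", 1, 1, 1, 1),
        ProcessClass("Pre", "prenylation", "modification", 1, 1, 1, 1),
        ProcessClass("Hy", "hydroxylation", "modification", 1, 1, 1, 1),
        ProcessClass("Ox", "oxidation", "modification", 1, 1, 1, 1),
        ProcessClass("Red", "reduction", "modification", 1, 1, 1, 1),
        ProcessClass("A+", "activation change", "state", 1, 1, 1, 1),
        ProcessClass("A-", "inactivation change", "state", 1, 1, 1, 1),
        # transport
        ProcessClass("T", "translocation", "transport", 1, 1, 1, 1),
        ProcessClass("Sec", "secretion", "transport", 1, 1, 1, 1),
        ProcessClass("En", "endocytosis", "transport", 1, 1, 1, 1),
        # expression / turnover
        ProcessClass("TR", "transcription", "expression", 1, 1, 1, inf),
        ProcessClass("TL", "translation", "expression", 1, 1, 1, inf),
        ProcessClass("Sp", "splicing", "expression", 1, 1, 1, inf),
        ProcessClass("Dg", "degradation", "turnover", 1, 1, 0, inf,),
        ProcessClass("Cv", "conversion", "conversion", 1, inf, 1, inf),
    ]
    table = {pc.code: pc for pc in entries}
    if len(table) != len(entries):
        raise RegistryError("duplicate process codes in default table")
    assert len(table) == 31
    return table


_COMPONENT_STYLES: Dict[str, StyleRecord] = {
    "protein": StyleRecord("roundrectangle", "light_blue", shape3d="sphere", size3d=1.0),
    "protein_complex": StyleRecord("roundrectangle", "yellow", shape3d="sphere", size3d=1.4),
    "gene": StyleRecord("rectangle", "green", shape3d="cube", size3d=1.0),
    "ion_simple_molecule": StyleRecord("diamond", "purple", shape3d="octahedron", size3d=0.7),
    "pathogen": StyleRecord("hexagon", "red", shape3d="icosahedron", size3d=1.2),
    "generic": StyleRecord("octagon", "grey", shape3d="sphere", size3d=0.9),
}


def default_registry() -> GlyphRegistry:
    """The shipped mEPN registry: 31 process classes, the component classes,
    AND/OR/NOT, the A/I/C edge annotations and the auxiliary node classes,
    each with a 2D and a 3D style. Pure and deterministic."""
    processes = _process_table()
    styles: Dict[Tuple[str, str], StyleRecord] = {}
    for sub, st in _COMPONENT_STYLES.items():
        styles[("component", sub)] = st
    cat_fill = {
        "binding": "orange", "dissociation": "pink", "modification": "mid_blue",
        "state": "lilac", "transport": "dark_green", "expression": "green",
        "turnover": "brown", "conversion": "cream",
    }
    for code, pc in processes.items():
        styles[("process", code)] = StyleRecord(
            "ellipse", cat_fill[pc.category], shape3d="cube", size3d=0.5
        )
    for op in ("AND", "OR", "NOT"):
        styles[("boolean_operator", op)] = StyleRecord(
            "ellipse", "dark_blue", shape3d="cube", size3d=0.5
        )
    annotations = {"A": "activation", "I": "inhibition", "C": "catalysis"}
    for code in annotations:
        styles[("edge_annotation", code)] = StyleRecord(
            "ellipse", "white", shape3d="cube", size3d=0.35
        )
    other = ("energy_transfer", "conditional_gate", "pathway_module", "pathway_output")
    styles[("energy_transfer", "energy_transfer")] = StyleRecord(
        "parallelogram", "cream", shape3d="cylinder", size3d=0.5
    )
    styles[("conditional_gate", "conditional_gate")] = StyleRecord(
        "trapezium", "grey", shape3d="cone", size3d=0.8
    )
    styles[("pathway_module", "pathway_module")] = StyleRecord(
        "rectangle3d", "lilac", shape3d="cube", size3d=1.5
    )
    styles[("pathway_output", "pathway_output")] = StyleRecord(
        "fatarrow", "light_blue", shape3d="tetrahedron", size3d=1.2
    )
    styles[("compartment_label", "compartment_label")] = StyleRecord(
        "rectangle", "light_grey", shape3d="plane", size3d=4.0
    )
    return GlyphRegistry(
        process_classes=processes,
        component_classes=tuple(_COMPONENT_STYLES),
        boolean_ops=("AND", "OR", "NOT"),
        edge_annotations=annotations,
        other_node_classes=other,
        styles=styles,
    )


def lookup_process(registry: GlyphRegistry, code: str) -> ProcessClass:
    """Exact-match lookup of a process class by its printed code."""
    try:
        return registry.process_classes[code]
    except KeyError:
        raise UnknownGlyphError(code) from None


# ---------------------------------------------------------------- overrides


class _StyleOverride(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape2d: Optional[str] = None
    fill: Optional[str] = None
    border: Optional[str] = None
    shape3d: Optional[str] = None
    size3d: Optional[float] = None


class _ProcessOverride(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: Optional[str] = None
    category: str = "custom"
    min_inputs: int = 1
    max_inputs: Optional[float] = None  # None -> unbounded
    min_outputs: int = 1
    max_outputs: Optional[float] = None
    style: Optional[_StyleOverride] = None


class _OverrideDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    processes: Dict[str, _ProcessOverride] = {}
    disable_processes: List[str] = []
    edge_annotations: Dict[str, str] = {}
    styles: Dict[str, _StyleOverride] = {}  # "kind/subclass" -> partial style


def load_registry_overrides(
    base: GlyphRegistry, config: Union[str, Mapping, None]
) -> GlyphRegistry:
    """Merge a YAML/dict override document into `base` and re-validate.

    Overrides may add or rename process classes, disable them, add edge
    annotation codes, and restyle any class. Process-code length and
    uniqueness rules are re-checked on the merged registry; an empty config
    returns `base` unchanged.
    """
    if config is None:
        return base
    raw = yaml.safe_load(config) if isinstance(config, str) else config
    if raw is None:
        return base
    if not isinstance(raw, Mapping):
        raise RegistryError("override document must be a mapping")
    doc = _OverrideDoc.model_validate(raw)

    processes = dict(base.process_classes)
    styles = dict(base.styles)
    for code in doc.disable_processes:
        if code not in processes:
            raise RegistryError(f"cannot disable unknown process code {code!r}")
        del processes[code]
        del styles[("process", code)]
    for code, ov in doc.processes.items():
        pc = ProcessClass(
            code=code,
            name=ov.name or code,
            category=ov.category,
            min_inputs=ov.min_inputs,
            max_inputs=UNBOUNDED if ov.max_inputs is None else ov.max_inputs,
            min_outputs=ov.min_outputs,
            max_outputs=UNBOUNDED if ov.max_outputs is None else ov.max_outputs,
        )
        processes[code] = pc
        st = styles.get(("process", code), StyleRecord("ellipse", "grey", shape3d="cube", size3d=0.5))
        if ov.style:
            st = replace(st, **{k: v for k, v in ov.style.model_dump().items() if v is not None})
        styles[("process", code)] = st

    annotations = dict(base.edge_annotations)
    for code, meaning in doc.edge_annotations.items():
        annotations[code] = meaning
        styles.setdefault(
            ("edge_annotation", code),
            StyleRecord("ellipse", "white", shape3d="cube", size3d=0.35),
        )

    for key, ov in doc.styles.items():
        try:
            kind, sub = key.split("/", 1)
        except ValueError:
            raise RegistryError(f"style key {key!r} must be 'kind/subclass'") from None
        if (kind, sub) not in styles:
            raise RegistryError(f"style override for unknown class {key!r}")
        styles[(kind, sub)] = replace(
            styles[(kind, sub)],
            **{k: v for k, v in ov.model_dump().items() if v is not None},
        )

    return GlyphRegistry(
        process_classes=processes,
        component_classes=base.component_classes,
        boolean_ops=base.boolean_ops,
        edge_annotations=annotations,
        other_node_classes=base.other_node_classes,
        styles=styles,
    )
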