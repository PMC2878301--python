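"""mEPN component-label grammar.

A component label names a protein, complex, gene or molecule. The grammar:

* complexes are written as their subunits joined by ``:`` in biological order
  (order is meaningful — it usually reflects assembly order or position);
* each subunit is an official symbol (HGNC/MGD-style), optionally followed by
  ``(alias)`` groups, a ``<k>`` stoichiometry marker (``<n>`` when the copy
  number is unknown), and ``[mod]`` state-modification groups, one bracket per
  modification, e.g. ``[P]``, ``[Ub]``, ``[P-L232]`` (code ``P`` at site L232);
* a complex may carry a generic common name on a second label line; it is
  decorative and never part of the component's identity.

``parse_component_label`` and ``format_component_label`` are inverse up to one
normalisation pass: ``format(parse(L))`` is a fixed point of the grammar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

__all__ = [
    "LabelError",
    "Modification",
    "Subunit",
    "ComplexSpec",
    "parse_component_label",
    "format_component_label",
    "canonical_identity",
]

# stoichiometry marker for an unknown copy number
UNKNOWN_STOICHIOMETRY = "n"

_BRACKETS = {"(": ")", "<": ">", "[": "]"}
_CLOSERS = {v: k for k, v in _BRACKETS.items()}


class LabelError(ValueError):
    """Raised when a label does not conform to the mEPN grammar."""


@dataclass(frozen=True)
class Modification:
    """One state modification, e.g. phosphorylation ``[P]`` or ``[P-L232]``.

    The token before the first ``-`` is the modification code; anything after
    it is the site (residue + position). ``[t]`` (truncation) style lowercase
    codes are preserved as written — codes are case sensitive.
    """

    code: str
    site: Optional[str] = None

    @property
    def raw(self) -> str:
        """The bracket token this modification prints as."""
        return f"[{self.code}-{self.site}]" if self.site else f"[{self.code}]"


@dataclass(frozen=True)
class Subunit:
    """One constituent of a component label.

    ``stoichiometry`` is a positive integer, the string ``"n"`` for an
    unknown copy number, or ``None`` when no marker was written (one copy).
    """

    symbol: str
    aliases: tuple = ()
    stoichiometry: Union[int, str, None] = None
    modifications: tuple = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise LabelError("subunit symbol must be non-empty")
        s = self.stoichiometry
        if isinstance(s, int) and s < 1:
            raise LabelError(f"numeric stoichiometry must be >= 1, got {s}")
        if isinstance(s, str) and s != UNKNOWN_STOICHIOMETRY:
            raise LabelError(
                f"stoichiometry must be a positive integer or {UNKNOWN_STOICHIOMETRY!r}, got {s!r}"
            )


@dataclass(frozen=True)
class ComplexSpec:
    """Parsed component label: ordered subunits plus an optional generic name.

    Single proteins are one-subunit specs. ``raw`` keeps the original text and
    is excluded from equality (two specs are equal when they denote the same
    structure, whatever the input spacing was).
    """

    subunits: tuple
    generic_name: Optional[str] = None
    raw: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.subunits:
            raise LabelError("a component label needs at least one subunit")


def _split_top_level(text: str, sep: str) -> List[str]:
    """Split on `sep` outside any (), <>, [] group; reject unbalanced brackets."""
    parts: List[str] = []
    stack: List[str] = []
    cur: List[str] = []
    for ch in text:
        if ch in _BRACKETS:
            stack.append(_BRACKETS[ch])
            cur.append(ch)
        elif ch in _CLOSERS:
            if not stack or stack[-1] != ch:
                raise LabelError(f"unbalanced bracket {ch!r} in label {text!r}")
            stack.pop()
            cur.append(ch)
        elif ch == sep and not stack:
            parts.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    if stack:
        raise LabelError(f"unbalanced brackets in label {text!r}")
    parts.append("".join(cur))
    return parts


_GROUP_RE = re.compile(r"\(([^()]*)\)|<([^<>]*)>|\[([^\[\]]*)\]")


def _parse_subunit(text: str) -> Subunit:
    text = text.strip()
    if not text:
        raise LabelError("empty subunit between colons")
    m = _GROUP_RE.search(text)
    symbol = text[: m.start()].strip() if m else text
    if not symbol:
        raise LabelError(f"subunit {text!r} has no symbol before its bracket groups")
    aliases: List[str] = []
    stoich: Union[int, str, None] = None
    mods: List[Modification] = []
    pos = m.start() if m else len(text)
    for g in _GROUP_RE.finditer(text, pos):
        between = text[pos:g.start()].strip()
        if between:
            raise LabelError(f"unexpected text {between!r} between groups in {text!r}")
        pos = g.end()
        alias, st, mod = g.group(1), g.group(2), g.group(3)
        if alias is not None:
            aliases.append(alias.strip())
        elif st is not None:
            st = st.strip()
            if st == UNKNOWN_STOICHIOMETRY:
                stoich = UNKNOWN_STOICHIOMETRY
            elif st.isdigit() and int(st) >= 1:
                stoich = int(st)
            else:
                raise LabelError(
                    f"stoichiometry <{st}> is neither a positive integer nor 'n'"
                )
        else:
            code, dash, site = mod.strip().partition("-")
            if not code:
                raise LabelError(f"empty modification bracket in {text!r}")
            mods.append(Modification(code=code, site=site if dash else None))
    trailing = text[pos:].strip()
    if trailing:
        raise LabelError(f"unexpected trailing text {trailing!r} in subunit {text!r}")
    return Subunit(
        symbol=symbol,
        aliases=tuple(aliases),
        stoichiometry=stoich,
        modifications=tuple(mods),
    )


def parse_component_label(text: str) -> ComplexSpec:
    """Parse a component label into its structured form.

    A second, newline-separated label line is read as the complex's generic
    common name. Whitespace around groups is tolerated.

    Raises :class:`LabelError` on unbalanced brackets, empty subunits or a
    malformed stoichiometry marker.
    """
    if not text or not text.strip():
        raise LabelError("component label must be non-empty")
    first, _, rest = text.partition("\n")
    generic = rest.strip() or None
    subunits = tuple(_parse_subunit(p) for p in _split_top_level(first.strip(), ":"))
    return ComplexSpec(subunits=subunits, generic_name=generic, raw=text)


def _format_subunit(su: Subunit) -> str:
    out = [su.symbol]
    out.extend(f" ({a})" for a in su.aliases)
    if su.stoichiometry not in (None, 1):
        out.append(f"<{su.stoichiometry}>")
    out.extend(f" {m.raw}" for m in su.modifications)
    return "".join(out)


def format_component_label(spec: ComplexSpec) -> str:
    """Serialize a spec to its canonical label text.

    Canonical order within a subunit is alias groups, stoichiometry marker,
    modification brackets; ``<1>`` markers are dropped. ``format`` then
    ``parse`` reproduces the spec exactly.
    """
    label = ":".join(_format_subunit(su) for su in spec.subunits)
    if spec.generic_name:
        label += "\n" + spec.generic_name
    return label


def canonical_identity(spec_or_label: Union[ComplexSpec, str]) -> str:
    """A deterministic identity key for the once-per-compartment rule.

    Two labels denote the same component exactly when their keys match: the
    key is the subunit symbols in label order, each with its stoichiometry and
    the *sorted* multiset of modification tokens. Aliases and the generic name
    are decoration and never part of identity; modification order within a
    subunit is not significant; whitespace never matters.
    """
    spec = (
        parse_component_label(spec_or_label)
        if isinstance(spec_or_label, str)
        else spec_or_label
    )
    keys = []
    for su in spec.subunits:
        key = su.symbol
        if su.stoichiometry not in (None, 1):
            key += f"<{su.stoichiometry}>"
        key += "".join(sorted(m.raw for m in su.modifications))
        keys.append(key)
    return ":".join(keys)
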