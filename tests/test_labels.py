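"""Component-label grammar: parsing, serialization, identity."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from mepnkit.labels import (
    ComplexSpec,
    LabelError,
    Modification,
    Subunit,
    canonical_identity,
    format_component_label,
    parse_component_label,
)


class TestParse:
    def test_modifications_with_and_without_site(self):
        spec = parse_component_label("STAT1 [P] [P-L232]")
        (su,) = spec.subunits
        assert su.symbol == "STAT1"
        assert [(m.code, m.site) for m in su.modifications] == [
            ("P", None), ("P", "L232")]
        assert [m.raw for m in su.modifications] == ["[P]", "[P-L232]"]

    def test_receptor_complex_stoichiometries(self):
        spec = parse_component_label("IFNGR1<2>:IFNGR2<2>:JAK1<2>:JAK2<2>")
        assert [su.symbol for su in spec.subunits] == [
            "IFNGR1", "IFNGR2", "JAK1", "JAK2"]
        assert all(su.stoichiometry == 2 for su in spec.subunits)

    def test_alias_groups(self):
        spec = parse_component_label("CD74 (li):HLA-D (alpha):HLA-D (beta)")
        assert [su.aliases for su in spec.subunits] == [
            ("li",), ("alpha",), ("beta",)]
        assert [su.symbol for su in spec.subunits] == ["CD74", "HLA-D", "HLA-D"]

    def test_unknown_stoichiometry_marker(self):
        spec = parse_component_label("X<n>")
        assert spec.subunits[0].stoichiometry == "n"

    def test_bare_symbol(self):
        spec = parse_component_label("ABC")
        (su,) = spec.subunits
        assert (su.symbol, su.aliases, su.stoichiometry, su.modifications) == (
            "ABC", (), None, ())

    def test_generic_name_on_second_line(self):
        spec = parse_component_label("NFKB1:RELA\nNF-kB")
        assert spec.generic_name == "NF-kB"
        assert len(spec.subunits) == 2

    @pytest.mark.parametrize("bad", [
        "A[", "A]", "A<2", "A(x", "", "  ", "A::B", ":A", "A:",
        "A<0>", "A<x>", "A<-1>", "[P]",
    ])
    def test_malformed_labels_rejected(self, bad):
        with pytest.raises(LabelError):
            parse_component_label(bad)

    def test_group_order_is_free_on_input(self):
        a = parse_component_label("A [P]<2> (alias)")
        b = parse_component_label("A (alias)<2> [P]")
        assert a == b


class TestFormat:
    def test_canonical_output_matches_printed_style(self):
        assert format_component_label(
            parse_component_label("STAT1[P][P-L232]")) == "STAT1 [P] [P-L232]"
        assert format_component_label(
            parse_component_label("X<n>")) == "X<n>"
        assert format_component_label(
            ComplexSpec(subunits=(Subunit("GAPDH"),))) == "GAPDH"

    def test_unit_stoichiometry_dropped(self):
        spec = ComplexSpec(subunits=(Subunit("A", stoichiometry=1),))
        assert format_component_label(spec) == "A"

    def test_invalid_stoichiometry_rejected_at_construction(self):
        with pytest.raises(LabelError):
            Subunit("A", stoichiometry=0)

    @pytest.mark.parametrize("label", [
        "STAT1 [P] [P-L232]",
        "IFNGR1<2>:IFNGR2<2>:JAK1<2>:JAK2<2>",
        "CD74 (li):HLA-D (alpha):HLA-D (beta)",
        "X<n>",
        "A (a1) (a2)<3> [P-S727] [Ub]",
    ])
    def test_format_parse_fixed_point(self, label):
        once = format_component_label(parse_component_label(label))
        assert format_component_label(parse_component_label(once)) == once


class TestIdentity:
    def test_whitespace_insensitive(self):
        assert canonical_identity("STAT1 [P]") == canonical_identity("STAT1[P]")

    def test_states_are_distinct_components(self):
        assert canonical_identity("STAT1") != canonical_identity("STAT1 [P]")

    def test_modification_order_irrelevant(self):
        # oracle: every permutation of the same three tokens collapses to one key
        mods = ["[P]", "[Ub]", "[P-L232]"]
        keys = {
            canonical_identity("A " + " ".join(p))
            for p in itertools.permutations(mods)
        }
        assert len(keys) == 1

    def test_aliases_and_generic_name_ignored(self):
        assert canonical_identity("CD74 (li)") == canonical_identity("CD74")
        assert canonical_identity("A:B\ncommon name") == canonical_identity("A:B")

    def test_subunit_order_significant(self):
        assert canonical_identity("A:B") != canonical_identity("B:A")

    def test_stoichiometry_significant(self):
        assert canonical_identity("STAT1<2>") != canonical_identity("STAT1")


_symbols = st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=1,
                   max_size=6)
_aliases = st.lists(
    st.text(alphabet="abcdefghijklmnopqrstuvwxyz0123456789", min_size=1,
            max_size=5),
    max_size=3)
_stoich = st.one_of(st.none(), st.integers(min_value=1, max_value=5),
                    st.just("n"))
_mods = st.lists(
    st.builds(
        Modification,
        code=st.sampled_from(["P", "Ub", "t", "Ac", "Me"]),
        site=st.one_of(st.none(), st.from_regex(r"[A-Z][0-9]{1,3}",
                                                fullmatch=True)),
    ),
    max_size=3)
_subunits = st.builds(Subunit, symbol=_symbols, aliases=st.builds(tuple, _aliases),
                      stoichiometry=_stoich, modifications=st.builds(tuple, _mods))
_specs = st.builds(ComplexSpec,
                   subunits=st.lists(_subunits, min_size=1, max_size=4).map(tuple))


@settings(max_examples=300, derandomize=True, deadline=None)
@given(_specs)
def test_random_specs_survive_format_parse_format(spec):
    """Property: the grammar's serialization is a fixed point after one pass."""
    once = format_component_label(spec)
    again = format_component_label(parse_component_label(once))
    assert once == again
    # and identity is stable across the round trip
    assert canonical_identity(parse_component_label(once)) == canonical_identity(spec)
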