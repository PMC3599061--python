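"""Layer grammar: emission, parsing, round-trips, containment."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import carbon_chain, mol
from minichi.canon import canonical_ranks
from minichi.errors import IdentifierParseError, MinichiError
from minichi.graph import graphs_isomorphic
from minichi.layers import (
    AuxNumbering,
    LayeredIdentifier,
    emit_c_layer,
    emit_h_layer,
    identify,
    layer_subset,
    parse_identifier,
)
from minichi.normalize import normalize
from minichi.synthetic import CorpusSpec, random_molecule

# prefix, version, formula, then slash-letter layers in fixed order
GRAMMAR = re.compile(
    r"^InChI=1S?/[A-Za-z0-9.]+"
    r"(/c[0-9();*,-]+)?(/h[0-9H();+*,-]+)?(/q[0-9;+*-]+)?(/p[+-][0-9]+)?"
    r"(/b[0-9;+*,-]+)?(/t[0-9;+*,-]+)?(/m[01])?(/s[123])?"
    r"(/i[0-9;+*,-]+)?(/f[0-9H();+*,-]+)?$"
)


class TestCLayer:
    def test_ethane(self):
        g = carbon_chain(2)
        assert emit_c_layer(g, canonical_ranks(g)) == "1-2"

    def test_methane_empty(self):
        g = mol(["C"])
        assert emit_c_layer(g, canonical_ranks(g)) == ""

    def test_cyclopropane_ring_closure(self):
        g = mol(["C", "C", "C"], [(1, 2), (2, 3), (1, 3)])
        assert emit_c_layer(g, canonical_ranks(g)) == "1-2-3-1"

    def test_branch_parenthesized(self):
        g = mol(["C", "C", "C", "O"], [(1, 2), (2, 3), (2, 4)])
        s = emit_c_layer(g, canonical_ranks(g))
        assert "(" in s and ")" in s


class TestHLayer:
    def test_tautomer_pair_h_positions(self, refs):
        a = identify(refs["pyridinol-n-oxide"]).layered
        b = identify(refs["n-hydroxypyridinone"]).layered
        assert a.h_layer.endswith("7H")
        assert b.h_layer.endswith("8H")

    def test_no_hydrogens_layer_omitted(self):
        g = mol(["C", "F", "F", "F", "F"], [(1, 2), (1, 3), (1, 4), (1, 5)])
        assert identify(g).layered.h_layer == ""

    def test_mobile_group_token(self):
        g = mol(["C", "C", "N", "N"], [(1, 2), (2, 3, 2), (2, 4)])
        ns = normalize(g)
        comp = ns.components[0]
        s = emit_h_layer(comp, canonical_ranks(comp), ns.mobile_groups[0])
        assert "(H3," in s


class TestEmit:
    def test_tautomer_drawings_give_different_identifiers(self, refs):
        ida = identify(refs["pyridinol-n-oxide"]).identifier
        idb = identify(refs["n-hydroxypyridinone"]).identifier
        assert ida != idb

    def test_stereo_stripped_layers_are_subset(self, refs):
        full = identify(refs["menthol"]).layered
        flat = refs["menthol"].copy()
        for b in flat.bonds:
            b.wedge = "none"
        stripped = identify(flat).layered
        assert layer_subset(stripped, full)
        assert not layer_subset(full, stripped)

    def test_grammar_on_corpus(self):
        spec = CorpusSpec(seed=41)
        for i in range(120):
            s = identify(random_molecule(spec, i)).identifier
            assert GRAMMAR.match(s), s

    def test_multicomponent_multiplier(self):
        # two waters + salt: identical components collapse in the formula
        g = mol(["O", "O", "Na", "Cl"], [], charges={3: 1, 4: -1})
        lid = identify(g).layered
        assert lid.formula == "Cl.2H2O.Na"


class TestParse:
    def test_methane_string(self):
        pr = parse_identifier("InChI=1S/CH4/h1H4")
        assert len(pr.graph.atoms) == 1
        assert pr.graph.atoms[0].element == "C"
        assert pr.graph.atoms[0].implicit_h == 4

    def test_ethanol_roundtrip(self):
        g = mol(["C", "C", "O"], [(1, 2), (2, 3)])
        res = identify(g)
        assert graphs_isomorphic(parse_identifier(res.identifier).graph, g)

    def test_corpus_roundtrip_with_aux_exact(self):
        spec = CorpusSpec(seed=43)
        for i in range(60):
            g = random_molecule(spec, i)
            res = identify(g)
            pr = parse_identifier(res.identifier, res.aux.to_text())
            assert graphs_isomorphic(pr.graph, g)

    def test_aux_sidecar_text_roundtrip(self):
        g = mol(["C", "C", "O"], [(1, 2), (2, 3)], isotopes={3: 1})
        aux = identify(g).aux
        back = AuxNumbering.from_text(aux.to_text())
        assert back.component_maps == aux.component_maps
        assert back.isotopes == aux.isotopes
        assert back.bonds == aux.bonds

    def test_malformed_layer_names_letter(self):
        with pytest.raises(IdentifierParseError, match="'h'"):
            parse_identifier("InChI=1S/CH4/hXYZ")
        with pytest.raises(IdentifierParseError):
            parse_identifier("NotAnIdentifier")

    def test_unknown_layer_letter_rejected(self):
        with pytest.raises(IdentifierParseError, match="'z'"):
            LayeredIdentifier.from_string("InChI=1S/CH4/z99")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet="InChI=1S/ch0123456789()-+,;*qptbmf.CHONS", max_size=60))
    def test_fuzz_parse_never_crashes_uncontrolled(self, s):
        try:
            parse_identifier(s)
        except MinichiError:
            pass  # controlled rejection is the contract

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_fuzz_mutated_real_identifier(self, seed_int):
        import numpy as np

        rng = np.random.default_rng(seed_int)
        g = random_molecule(CorpusSpec(seed=47), int(seed_int) % 50)
        s = list(identify(g).identifier)
        k = int(rng.integers(len(s)))
        s[k] = "InChI=1S/ch9(),-+;*"[int(rng.integers(19))]
        try:
            parse_identifier("".join(s))
        except MinichiError:
            pass


class TestLayerSubset:
    def test_reflexive_on_corpus(self):
        spec = CorpusSpec(seed=53)
        for i in range(25):
            lid = identify(random_molecule(spec, i)).layered
            assert layer_subset(lid, lid)

    def test_different_formulas_disjoint(self):
        a = identify(carbon_chain(2)).layered
        b = identify(carbon_chain(3)).layered
        assert not layer_subset(a, b) and not layer_subset(b, a)

    def test_partial_order_laws(self, refs):
        spec = CorpusSpec(seed=59)
        lids = [identify(random_molecule(spec, i)).layered for i in range(15)]
        full = identify(refs["menthol"]).layered
        flat_g = refs["menthol"].copy()
        for b in flat_g.bonds:
            b.wedge = "none"
        lids += [full, identify(flat_g).layered]
        for a in lids:
            assert layer_subset(a, a)  # reflexive
        for a in lids:
            for b in lids:
                if layer_subset(a, b) and layer_subset(b, a):
                    assert a.layers_present() == b.layers_present()  # antisym
                for c in lids:
                    if layer_subset(a, b) and layer_subset(b, c):
                        assert layer_subset(a, c)  # transitive
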