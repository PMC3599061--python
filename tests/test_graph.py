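"""Molecular graph model, Molfile/SDF I/O, formulas, isomorphism."""

import itertools

import numpy as np
import pytest

from helpers import carbon_chain, mol, permute_graph
from minichi.errors import (
    ElementError,
    MolfileParseError,
    SizeLimitError,
    UnsupportedFeatureError,
)
from minichi.graph import (
    graphs_isomorphic,
    hill_formula,
    parse_hill,
    read_molfile,
    read_sdf,
    write_molfile,
    write_sdf,
)
from minichi.synthetic import CorpusSpec, random_molecule

METHANE_MOLFILE = """methane


  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
"""


class TestReadMolfile:
    def test_methane_implicit_h(self):
        g = read_molfile(METHANE_MOLFILE)
        assert len(g.atoms) == 1
        assert g.atoms[0].element == "C"
        assert g.atoms[0].implicit_h == 4

    def test_chg_property_overrides_and_reduces_h(self):
        text = METHANE_MOLFILE.replace("C  ", "O  ").replace(
            "M  END", "M  CHG  1   1  -1\nM  END"
        )
        g = read_molfile(text)
        assert g.atoms[0].formal_charge == -1
        assert g.atoms[0].implicit_h == 1  # O(-) takes a single H

    def test_malformed_counts_line_names_line(self):
        bad = METHANE_MOLFILE.replace("  1  0", "  x  0")
        with pytest.raises(MolfileParseError, match="line 4"):
            read_molfile(bad)

    def test_unknown_element_rejected(self):
        with pytest.raises(ElementError):
            read_molfile(METHANE_MOLFILE.replace("C  ", "Xx "))

    def test_v3000_rejected(self):
        with pytest.raises(UnsupportedFeatureError, match="V3000"):
            read_molfile(METHANE_MOLFILE.replace("V2000", "V3000"))

    def test_aromatic_bond_type_rejected(self):
        benzeneish = (
            "\n\n\n  2  1  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 C   0  0\n"
            "    1.0000    0.0000    0.0000 C   0  0\n"
            "  1  2  4  0  0  0  0\nM  END\n"
        )
        with pytest.raises(UnsupportedFeatureError, match="Kekulized"):
            read_molfile(benzeneish)

    def test_explicit_hydrogens_fold_into_neighbor(self):
        text = (
            "\n\n\n  3  2  0  0  0  0  0  0  0  0999 V2000\n"
            "    0.0000    0.0000    0.0000 O   0  0\n"
            "    1.0000    0.0000    0.0000 H   0  0\n"
            "   -1.0000    0.0000    0.0000 H   0  0\n"
            "  1  2  1  0  0  0  0\n  1  3  1  0  0  0  0\nM  END\n"
        )
        g = read_molfile(text)
        assert [a.element for a in g.atoms] == ["O"]
        assert g.atoms[0].implicit_h == 2


class TestWriteRoundTrip:
    @pytest.mark.parametrize("index", range(25))
    def test_corpus_roundtrip_isomorphic(self, index):
        spec = CorpusSpec(seed=13)
        g = random_molecule(spec, index)
        back = read_molfile(write_molfile(g))
        assert graphs_isomorphic(g, back)

    def test_isotope_emits_iso_line(self):
        g = mol(["C", "Cl"], [(1, 2)], isotopes={2: 2})
        text = write_molfile(g)
        assert "M  ISO" in text and " 37" in text
        back = read_molfile(text)
        assert back.atoms[1].isotope_delta == 2

    def test_two_component_salt_single_molfile(self):
        g = mol(["Na", "Cl"], [], charges={1: 1, 2: -1})
        back = read_molfile(write_molfile(g))
        assert len(back.components()) == 2
        assert graphs_isomorphic(g, back)

    def test_wedges_survive(self):
        g = mol(
            ["C", "F", "Cl", "Br"],
            [(1, 2, 1, "up"), (1, 3), (1, 4)],
            coords={1: (0, 0), 2: (1, 0), 3: (-1, 1), 4: (-1, -1)},
        )
        back = read_molfile(write_molfile(g))
        wedges = {b.key(): b.wedge for b in back.bonds}
        assert wedges[(1, 2)] == "up"


class TestSdf:
    def test_multi_record_with_properties(self):
        g1, g2 = carbon_chain(2), carbon_chain(3)
        g1.properties["STEREO_TYPE"] = "relative"
        text = write_sdf([g1, g2])
        records = list(read_sdf(text))
        assert len(records) == 2
        assert records[0].properties["STEREO_TYPE"] == "relative"
        assert graphs_isomorphic(records[1], g2)


class TestIsomorphism:
    def _brute_isomorphic(self, g1, g2):
        """Exhaustive attribute-preserving bijection search (oracle)."""
        if len(g1.atoms) != len(g2.atoms):
            return False
        a2 = {a.index: a for a in g2.atoms}
        e1 = {b.key(): b.order for b in g1.bonds}
        for perm in itertools.permutations([a.index for a in g2.atoms]):
            m = {a.index: perm[i] for i, a in enumerate(g1.atoms)}
            ok = all(
                (a.element, a.formal_charge, a.isotope_delta, a.implicit_h)
                == (
                    a2[m[a.index]].element,
                    a2[m[a.index]].formal_charge,
                    a2[m[a.index]].isotope_delta,
                    a2[m[a.index]].implicit_h,
                )
                for a in g1.atoms
            )
            if not ok:
                continue
            e2 = {b.key(): b.order for b in g2.bonds}
            mapped = {
                tuple(sorted((m[a], m[b]))): o for (a, b), o in e1.items()
            }
            if mapped == e2:
                return True
        return False

    def test_permuted_copy_is_isomorphic(self):
        g = mol(["C", "C", "O", "N"], [(1, 2), (2, 3), (2, 4)])
        g2 = permute_graph(g, {1: 3, 2: 1, 3: 4, 4: 2})
        assert graphs_isomorphic(g, g2)

    def test_constitutional_isomers_differ(self):
        ethanol = mol(["C", "C", "O"], [(1, 2), (2, 3)])
        dme = mol(["C", "O", "C"], [(1, 2), (2, 3)])
        assert not graphs_isomorphic(ethanol, dme)

    def test_butane_vs_isobutane_matches_brute_force(self):
        butane = carbon_chain(4)
        isobutane = mol(["C", "C", "C", "C"], [(1, 2), (1, 3), (1, 4)])
        assert graphs_isomorphic(butane, isobutane) == self._brute_isomorphic(
            butane, isobutane
        )
        assert not graphs_isomorphic(butane, isobutane)
        assert graphs_isomorphic(butane, butane) == self._brute_isomorphic(
            butane, butane
        )


class TestHillFormula:
    def test_reference_formulas(self, refs):
        assert hill_formula(refs["pyridinol-n-oxide"]) == "C5H5NO2"
        assert hill_formula(refs["menthol"]) == "C10H20O"
        assert hill_formula(mol(["C"])) == "CH4"

    def test_carbon_free_alphabetical(self):
        # per-component rule: alphabetical with no carbon
        assert hill_formula(mol(["Na", "Cl"], [(1, 2)])) == "ClNa"
        # disconnected components join with "." in sorted order
        salt = mol(["Na", "Cl"], [], charges={1: 1, 2: -1})
        assert hill_formula(salt) == "Cl.Na"

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        spec = CorpusSpec(seed=21)
        for i in range(10):
            g = random_molecule(spec, i)
            base = hill_formula(g)
            n = len(g.atoms)
            for _ in range(50):
                p = rng.permutation(n) + 1
                gp = permute_graph(g, {j + 1: int(p[j]) for j in range(n)})
                assert hill_formula(gp) == base

    def test_parse_hill_inverse(self):
        from minichi.graph import format_hill

        for f in ("C5H5NO2", "CH4", "ClNa", "C10H20O", "H2O4S"):
            assert format_hill(parse_hill(f)) == f


class TestSizeLimit:
    def test_exactly_1000_accepted(self):
        g = carbon_chain(1000)
        g.validate()

    def test_1001_rejected(self):
        with pytest.raises(SizeLimitError):
            carbon_chain(1001)
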