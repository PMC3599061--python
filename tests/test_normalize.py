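"""Metal disconnection, proton balance, mobile-H detection, idempotence."""

import numpy as np
import pytest

from helpers import carbon_chain, mol, permute_graph
from minichi.graph import graphs_isomorphic, hill_formula
from minichi.normalize import (
    STANDARD,
    NormalizationOptions,
    detect_mobile_h,
    disconnect_metals,
    normalize,
    proton_balance,
    reassemble,
)
from minichi.synthetic import CorpusSpec, random_molecule


class TestDisconnectMetals:
    def test_sodium_chloride_heterolytic(self):
        g = mol(["Na", "Cl"], [(1, 2)])
        out, removed = disconnect_metals(g)
        assert removed == [(1, 2, 1)]
        assert not out.bonds
        assert out.atom(1).formal_charge == 1
        assert out.atom(2).formal_charge == -1

    def test_glutamate_salt_two_components(self, refs):
        out, removed = disconnect_metals(refs["monosodium-glutamate"])
        comps = out.components()
        assert len(comps) == 2
        assert len(removed) == 1
        na = next(a for a in out.atoms if a.element == "Na")
        assert na.formal_charge == 1
        charges = sorted(
            sum(out.atom(i).formal_charge for i in comp) for comp in comps
        )
        assert charges == [-1, 1]

    def test_metal_free_graph_untouched(self):
        g = mol(["C", "C", "O"], [(1, 2), (2, 3)])
        out, removed = disconnect_metals(g)
        assert removed == []
        assert graphs_isomorphic(g, out)

    def test_connected_metals_mode_is_identity(self):
        g = mol(["Na", "Cl"], [(1, 2)])
        out, removed = disconnect_metals(g, enabled=False)
        assert removed == [] and len(out.bonds) == 1


class TestProtonBalance:
    def test_acetate_gains_proton(self):
        acetate = mol(["C", "C", "O", "O"], [(1, 2), (2, 3, 2), (2, 4)], {4: -1})
        out, p = proton_balance(acetate)
        assert p == -1
        assert all(a.formal_charge == 0 for a in out.atoms)
        assert hill_formula(out) == "C2H4O2"

    def test_neutral_ethanol_unchanged(self):
        g = mol(["C", "C", "O"], [(1, 2), (2, 3)])
        out, p = proton_balance(g)
        assert p == 0 and graphs_isomorphic(g, out)

    def test_methylammonium_loses_proton(self):
        g = mol(["C", "N"], [(1, 2)], {2: 1})
        out, p = proton_balance(g)
        assert p == 1
        assert out.atom(2).formal_charge == 0
        assert out.atom(2).implicit_h == 2  # methylamine

    def test_n_oxide_oxygen_left_alone(self, refs):
        out, p = proton_balance(refs["pyridinol-n-oxide"])
        assert p == 0
        assert out.atom(8).formal_charge == -1

    def test_zwitterion_fully_neutralized(self):
        # glycine drawn zwitterionic: +H3N-CH2-COO-
        g = mol(
            ["N", "C", "C", "O", "O"],
            [(1, 2), (2, 3), (3, 4, 2), (3, 5)],
            {1: 1, 5: -1},
        )
        out, p = proton_balance(g)
        assert p == 0
        assert all(a.formal_charge == 0 for a in out.atoms)


class TestMobileH:
    def test_acetamidine_single_group_spans_both_n(self):
        g = mol(["C", "C", "N", "N"], [(1, 2), (2, 3, 2), (2, 4)])
        groups = detect_mobile_h(g)
        assert len(groups) == 1
        assert groups[0].member_atoms == frozenset({3, 4})
        assert groups[0].mobile_h_count == 3  # =NH + NH2

    def test_hexane_no_candidates(self):
        assert detect_mobile_h(carbon_chain(6)) == []

    def test_oxime_nitroso_pair_not_merged(self, refs):
        # 1,4-relationship across the ring: neither drawing pools its oxygens
        assert detect_mobile_h(refs["pyridinol-n-oxide"]) == []
        assert detect_mobile_h(refs["n-hydroxypyridinone"]) == []

    def test_detection_invariant_under_permutation(self):
        g = mol(["C", "C", "N", "N", "O"], [(1, 2), (2, 3, 2), (2, 4), (1, 5)])
        base = {frozenset(gr.member_atoms) for gr in detect_mobile_h(g)}
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.permutation(5) + 1
            newidx = {i + 1: int(p[i]) for i in range(5)}
            gp = permute_graph(g, newidx)
            mapped = {
                frozenset(newidx[i] for i in s) for s in base
            }
            assert {
                frozenset(gr.member_atoms) for gr in detect_mobile_h(gp)
            } == mapped


class TestNormalize:
    def test_plain_molecule_identity_path(self):
        g = mol(["C", "C", "O"], [(1, 2), (2, 3)])
        ns = normalize(g)
        assert len(ns.components) == 1
        assert ns.proton_balance == 0
        assert ns.mobile_groups == [[]]
        assert ns.fixed_h_variant == [None]

    def test_glutamate_charge_conservation(self, refs):
        ns = normalize(refs["monosodium-glutamate"])
        assert len(ns.components) == 2
        # input is neutral: component charges plus proton balance cancel
        assert sum(ns.component_charges) + ns.proton_balance == 0
        assert ns.proton_balance == -1

    def test_acetamidine_records_fixed_h_variant(self):
        g = mol(["C", "C", "N", "N"], [(1, 2), (2, 3, 2), (2, 4)])
        ns = normalize(g)
        assert len(ns.mobile_groups[0]) == 1
        assert ns.fixed_h_variant[0] is not None

    @staticmethod
    def _counts(g):
        out: dict[str, int] = {}
        for a in g.atoms:
            out[a.element] = out.get(a.element, 0) + 1
            out["H"] = out.get("H", 0) + a.implicit_h
        return {k: v for k, v in out.items() if v}

    def test_mass_and_charge_conservation_on_corpus(self):
        spec = CorpusSpec(seed=17)
        for i in range(60):
            g = random_molecule(spec, i)
            ns = normalize(g)
            in_counts = self._counts(g)
            out_counts: dict[str, int] = {}
            for c in ns.components:
                for el, k in self._counts(c).items():
                    out_counts[el] = out_counts.get(el, 0) + k
            out_counts["H"] = out_counts.get("H", 0) + ns.proton_balance
            if out_counts.get("H") == 0:
                out_counts.pop("H")
            assert out_counts == in_counts
            in_q = sum(a.formal_charge for a in g.atoms)
            assert sum(ns.component_charges) + ns.proton_balance == in_q

    def test_idempotent_on_corpus(self):
        spec = CorpusSpec(seed=19)
        for i in range(40):
            g = random_molecule(spec, i)
            ns = normalize(g)
            for comp in ns.components:
                ns2 = normalize(comp)
                assert len(ns2.components) == 1
                assert ns2.proton_balance == 0
                assert graphs_isomorphic(ns2.components[0], comp)

    def test_reassemble_inverts_normalization(self, refs):
        for name in ("monosodium-glutamate", "guanine", "menthol"):
            g = refs[name]
            back = reassemble(normalize(g))
            assert graphs_isomorphic(back, g)

    def test_options_flags(self):
        opts = NormalizationOptions(detect_tautomers=False)
        g = mol(["C", "C", "N", "N"], [(1, 2), (2, 3, 2), (2, 4)])
        assert normalize(g, opts).mobile_groups == [[]]
        assert not opts.is_standard
        assert STANDARD.is_standard
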