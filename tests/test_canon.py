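"""Canonical ranking: partitions, refinement, brute-force optimum oracle."""

import itertools

import numpy as np
import pytest

from helpers import carbon_chain, mol, permute_graph
from minichi.canon import (
    canonical_ranks,
    initial_partition,
    positional_rows,
    refine,
    stable_partition,
)
from minichi.errors import CanonicalizationLimitError
from minichi.layers import identify
from minichi.synthetic import CorpusSpec, random_molecule


def _colors(g):
    cells = stable_partition(g)
    out = {}
    for ci, cell in enumerate(cells):
        for a in cell:
            out[a] = ci
    return out


def _oracle_key(g, order, colors):
    """Comparison key the canonicalization optimizes: color sequence
    (minimized), then adjacency rows (maximized)."""
    return ([colors[a] for a in order], [-r for r in positional_rows(g, order)])


def _brute_force_best(g):
    """Exhaustive optimum over all n! orderings — independent of the search."""
    colors = _colors(g)
    best = None
    for perm in itertools.permutations([a.index for a in g.atoms]):
        key = _oracle_key(g, list(perm), colors)
        if best is None or key < best:
            best = key
    return best


class TestInitialPartition:
    def test_ethanol_three_cells(self):
        g = mol(["C", "C", "O"], [(1, 2), (2, 3)])
        assert len(initial_partition(g)) == 3

    def test_benzene_single_cell(self):
        g = mol(
            ["C"] * 6,
            [(1, 2, 2), (2, 3, 1), (3, 4, 2), (4, 5, 1), (5, 6, 2), (6, 1, 1)],
        )
        cells = initial_partition(g)
        assert len(cells) == 1 and len(cells[0]) == 6

    def test_chfclbr_four_singletons(self):
        g = mol(["C", "F", "Cl", "Br"], [(1, 2), (1, 3), (1, 4)])
        cells = initial_partition(g)
        assert len(cells) == 4
        assert all(len(c) == 1 for c in cells)


class TestRefine:
    def test_pentane_hand_refinement(self):
        # the 5-path refines to {terminals}, {2-positions}, {center}
        g = carbon_chain(5)
        cells = refine(g, initial_partition(g))
        as_sets = [set(c) for c in cells]
        assert {1, 5} in as_sets and {2, 4} in as_sets and {3} in as_sets

    def test_discrete_partition_fixed_point(self):
        g = mol(["C", "F", "Cl", "Br"], [(1, 2), (1, 3), (1, 4)])
        cells = initial_partition(g)
        assert refine(g, cells) == cells

    def test_cyclohexane_vertex_transitive_single_cell(self):
        g = mol(["C"] * 6, [(i, i % 6 + 1) for i in range(1, 7)])
        cells = refine(g, initial_partition(g))
        assert len(cells) == 1


class TestCanonicalRanks:
    def test_single_atom(self):
        rk = canonical_ranks(mol(["C"]))
        assert rk.rank == {1: 1}

    def test_matches_brute_force_on_small_trees(self):
        # all element assignments over {C,N,O} on the two 4-atom trees
        shapes = [
            [(1, 2), (2, 3), (3, 4)],  # path
            [(1, 2), (1, 3), (1, 4)],  # star
        ]
        for bonds in shapes:
            for els in itertools.product("CNO", repeat=4):
                g = mol(list(els), bonds)
                rk = canonical_ranks(g)
                assert _oracle_key(g, rk.order, _colors(g)) == _brute_force_best(g)

    def test_matches_brute_force_on_corpus_graphs(self):
        spec = CorpusSpec(seed=11, min_atoms=3, max_atoms=6, stereo_probability=0)
        for i in range(40):
            g = random_molecule(spec, i)
            rk = canonical_ranks(g)
            assert _oracle_key(g, rk.order, _colors(g)) == _brute_force_best(g)

    def test_not_beaten_by_sampled_orderings_at_7_and_8(self):
        rng = np.random.default_rng(2)
        for n in (7, 8):
            spec = CorpusSpec(seed=23 + n, min_atoms=n, max_atoms=n,
                              stereo_probability=0)
            for i in range(5):
                g = random_molecule(spec, i)
                colors = _colors(g)
                rk = canonical_ranks(g)
                ours = _oracle_key(g, rk.order, colors)
                idx = [a.index for a in g.atoms]
                for _ in range(10_000):
                    order = [idx[j] for j in rng.permutation(n)]
                    assert ours <= _oracle_key(g, order, colors)

    def test_element_blocks_contiguous_carbon_first(self):
        spec = CorpusSpec(seed=29)
        for i in range(30):
            g = random_molecule(spec, i)
            rk = canonical_ranks(g)
            els = [g.atom(a).element for a in rk.order]
            non_c = [e for e in els if e != "C"]
            assert els == ["C"] * (len(els) - len(non_c)) + sorted(non_c)

    def test_expansion_cap_raises(self):
        ring = mol(["C"] * 12, [(i, i % 12 + 1) for i in range(1, 13)])
        with pytest.raises(CanonicalizationLimitError):
            canonical_ranks(ring, expansion_cap=5)


class TestPermutationInvariance:
    def test_identifier_byte_identical_under_shuffle(self):
        rng = np.random.default_rng(4)
        spec = CorpusSpec(seed=31)
        for i in range(150):
            g = random_molecule(spec, i)
            base = identify(g).identifier
            n = len(g.atoms)
            p = rng.permutation(n) + 1
            gp = permute_graph(g, {j + 1: int(p[j]) for j in range(n)})
            assert identify(gp).identifier == base

    def test_isomorphic_same_nonisomorphic_differ(self):
        spec = CorpusSpec(seed=37)
        mols = [random_molecule(spec, i) for i in range(40)]
        ids = [identify(g).identifier for g in mols]
        from minichi.graph import graphs_isomorphic

        for i in range(len(mols)):
            for j in range(i + 1, len(mols)):
                if ids[i] == ids[j]:
                    # identical identifiers only for identical structures
                    assert graphs_isomorphic(mols[i], mols[j])
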