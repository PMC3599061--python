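"""Shared test utilities: compact molecule builder and permutation helper."""

from __future__ import annotations

from dataclasses import replace

from minichi.graph import Atom, Bond, MolecularGraph


def mol(
    elements,
    bonds=(),
    charges=None,
    isotopes=None,
    coords=None,
    name="",
) -> MolecularGraph:
    """Build a graph from terse specs.

    ``bonds`` entries are (a1, a2[, order[, wedge]]); default coordinates
    place atoms on a gentle zigzag so no three neighbors are collinear.
    """
    charges = charges or {}
    isotopes = isotopes or {}
    atoms = []
    for i, el in enumerate(elements, start=1):
        if coords and i in coords:
            x, y = coords[i]
        else:
            x, y = float(i), 0.6 * (i % 2) + 0.13 * (i % 3)
        atoms.append(
            Atom(
                index=i,
                element=el,
                formal_charge=charges.get(i, 0),
                isotope_delta=isotopes.get(i, 0),
                x=x,
                y=y,
            )
        )
    bl = []
    for b in bonds:
        if len(b) == 2:
            bl.append(Bond(b[0], b[1]))
        elif len(b) == 3:
            bl.append(Bond(b[0], b[1], b[2]))
        else:
            bl.append(Bond(b[0], b[1], b[2], b[3]))
    g = MolecularGraph(atoms=atoms, bonds=bl, name=name)
    g.validate()
    g.assign_implicit_h()
    return g


def permute_graph(g: MolecularGraph, new_index: dict[int, int]) -> MolecularGraph:
    """Relabel atoms by the given old->new bijection."""
    atoms: list = [None] * len(g.atoms)
    for a in g.atoms:
        na = replace(a)
        na.index = new_index[a.index]
        atoms[na.index - 1] = na
    bonds = [
        Bond(new_index[b.a1], new_index[b.a2], b.order, b.wedge) for b in g.bonds
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, name=g.name)


def carbon_chain(n: int) -> MolecularGraph:
    return mol(["C"] * n, [(i, i + 1) for i in range(1, n)])
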