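"""Seeded generator of chemically valid molecular graphs, plus hand-encoded
reference structures used throughout the tests.

Generation is random-spanning-tree + probabilistic ring closure, with bond
promotion (double/triple) constrained by the standard valence table, optional
acid/base charge sites, optional stereo wedges on perceived stereocenters,
and a zigzag tree layout for 2D coordinates.  Every molecule is connected,
metal-free and fully valence-consistent; the corpus is deterministic
byte-for-byte given (seed, index).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .canon import stable_partition
from .elements import implicit_hydrogens, max_valence
from .graph import Atom, Bond, MolecularGraph, write_sdf

DEFAULT_PALETTE: tuple[tuple[str, float], ...] = (
    ("C", 0.70),
    ("N", 0.10),
    ("O", 0.12),
    ("S", 0.03),
    ("F", 0.015),
    ("Cl", 0.015),
    ("Br", 0.005),
    ("P", 0.005),
)


@dataclass(frozen=True)
class CorpusSpec:
    """Study conditions for a synthetic corpus.

    Defaults describe the reference corpus: 10,000 connected molecules of
    3-30 heavy atoms drawn from an organic palette, with moderate ring,
    unsaturation, stereo and charge content.
    """

    n_molecules: int = 10_000
    min_atoms: int = 3
    max_atoms: int = 30
    element_weights: tuple[tuple[str, float], ...] = DEFAULT_PALETTE
    ring_probability: float = 0.30
    heteroatom_h_probability: float = 0.70
    pi_bond_probability: float = 0.15
    stereo_probability: float = 0.25
    charge_probability: float = 0.05
    isotope_probability: float = 0.02
    seed: int = 7

    def __post_init__(self):
        for name in (
            "ring_probability",
            "heteroatom_h_probability",
            "pi_bond_probability",
            "stereo_probability",
            "charge_probability",
            "isotope_probability",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 1 <= self.min_atoms <= self.max_atoms:
            raise ValueError("bad atom-count range")


def _rng_for(spec: CorpusSpec, index: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed % (2**31), index % (2**31)])


def random_molecule(spec: CorpusSpec, index: int) -> MolecularGraph:
    """Deterministic molecule #``index`` of the corpus defined by ``spec``."""
    rng = _rng_for(spec, index)
    for _attempt in range(50):
        g = _try_build(spec, rng)
        if g is not None:
            g.name = f"mol-{spec.seed}-{index}"
            return g
    # valence dead ends are vanishingly rare; an all-carbon chain always works
    n = spec.min_atoms
    g = MolecularGraph(
        atoms=[Atom(index=i + 1, element="C", x=float(i), y=0.0) for i in range(n)],
        bonds=[Bond(i, i + 1) for i in range(1, n)],
        name=f"mol-{spec.seed}-{index}",
    )
    g.assign_implicit_h()
    return g


def _try_build(spec: CorpusSpec, rng) -> MolecularGraph | None:
    n = int(rng.integers(spec.min_atoms, spec.max_atoms + 1))
    symbols = [el for el, _ in spec.element_weights]
    weights = np.array([w for _, w in spec.element_weights], dtype=float)
    weights /= weights.sum()
    elements = [symbols[i] for i in rng.choice(len(symbols), size=n, p=weights)]

    open_val = [max_valence(el) for el in elements]
    if open_val[0] == 0:
        return None
    bonds: list[Bond] = []
    adj: dict[int, set[int]] = {1: set()}
    for i in range(2, n + 1):
        hosts = [j for j in range(1, i) if open_val[j - 1] >= 1]
        if not hosts or open_val[i - 1] < 1:
            return None
        j = int(hosts[rng.integers(len(hosts))])
        bonds.append(Bond(j, i))
        open_val[j - 1] -= 1
        open_val[i - 1] -= 1
        adj.setdefault(i, set()).add(j)
        adj[j].add(i)

    # ring closures
    for _ in range(2):
        if rng.random() >= spec.ring_probability:
            continue
        ends = [i for i in range(1, n + 1) if open_val[i - 1] >= 1]
        rng.shuffle(ends)
        placed = False
        for a in ends:
            partners = [
                b
                for b in ends
                if b != a and b not in adj[a] and open_val[b - 1] >= 1
            ]
            if partners:
                b = int(partners[rng.integers(len(partners))])
                bonds.append(Bond(min(a, b), max(a, b)))
                open_val[a - 1] -= 1
                open_val[b - 1] -= 1
                adj[a].add(b)
                adj[b].add(a)
                placed = True
                break
        if not placed:
            break

    # unsaturation
    het = {"N", "O", "S", "P"}
    order = list(range(len(bonds)))
    rng.shuffle(order)
    n_pi = 0
    for bi in order:
        b = bonds[bi]
        if open_val[b.a1 - 1] < 1 or open_val[b.a2 - 1] < 1:
            continue
        involves_het = elements[b.a1 - 1] in het or elements[b.a2 - 1] in het
        p = (
            1.0 - spec.heteroatom_h_probability
            if involves_het
            else spec.pi_bond_probability
        )
        if rng.random() < p:
            b.order = 2
            open_val[b.a1 - 1] -= 1
            open_val[b.a2 - 1] -= 1
            n_pi += 1
            if (
                open_val[b.a1 - 1] >= 1
                and open_val[b.a2 - 1] >= 1
                and not involves_het
                and rng.random() < 0.10
            ):
                b.order = 3
                open_val[b.a1 - 1] -= 1
                open_val[b.a2 - 1] -= 1
        if n_pi >= 4:
            break

    g = MolecularGraph(
        atoms=[Atom(index=i + 1, element=el) for i, el in enumerate(elements)],
        bonds=bonds,
    )
    g.assign_implicit_h()

    # isotopes first: the ionizable-site convention ranks the neutral
    # molecule as the parser will see it, isotopes included
    if rng.random() < spec.isotope_probability:
        a = g.atoms[int(rng.integers(len(g.atoms)))]
        a.isotope_delta = int(rng.choice([1, 2]))
    if rng.random() < spec.charge_probability:
        _place_ionizable_site(g, rng)

    _layout(g, rng)
    _place_wedges(g, spec, rng)
    g.validate()
    g.check_valences()
    return g


def _place_ionizable_site(g: MolecularGraph, rng) -> None:
    """Create one acid/base ion at the conventional site.

    Ions are drawn at the site the proton-balance convention designates
    (most acidic O-H class / most basic N class, canonically first within
    the class) — the same site where :func:`minichi.normalize.apply_protons`
    re-attaches protons, so the drawn species is recoverable from the
    identifier alone.
    """
    from .canon import canonical_ranks
    from .normalize import _acid_class

    adj = g.adjacency()
    rank = canonical_ranks(g).rank
    if rng.random() < 0.5:
        ohs = [a.index for a in g.atoms if a.element == "O" and a.implicit_h >= 1]
        if ohs:
            best = min(_acid_class(g, i) for i in ohs)
            pool = [i for i in ohs if _acid_class(g, i) == best]
            site = min(pool, key=lambda i: rank[i])
            g.atom(site).formal_charge = -1
            g.assign_implicit_h()
            return
    ns = [
        a.index
        for a in g.atoms
        if a.element == "N"
        and a.formal_charge == 0
        and g.bond_order_sum(a.index) <= 3
    ]
    sp3 = [i for i in ns if all(o == 1 for _, o in adj[i])]
    pool = sp3 or ns
    if pool:
        site = min(pool, key=lambda i: rank[i])
        g.atom(site).formal_charge = 1
        g.assign_implicit_h()


def _layout(g: MolecularGraph, rng) -> None:
    """Chemistry-style zigzag layout over a spanning tree; ring-closure
    bonds take whatever geometry results.  Small seeded jitter keeps
    substituents off exact lines."""
    nbrs = g.neighbors()
    if not g.atoms:
        return
    placed: dict[int, tuple[float, float]] = {1: (0.0, 0.0)}
    incoming: dict[int, float] = {1: math.pi}
    used_dirs: dict[int, list[float]] = {1: []}
    stack = [1]
    seen = {1}
    while stack:
        v = stack.pop()
        theta_in = incoming[v]
        base = theta_in + math.pi  # direction we arrived from, flipped
        offsets = [
            math.radians(d)
            for d in (150, -150, 90, -90, 60, -60, 120, -120, 30, -30, 0, 180)
        ]
        for w in sorted(nbrs[v]):
            if w in seen:
                continue
            seen.add(w)
            angle = None
            for off in offsets:
                cand = base + off
                if all(
                    abs(math.remainder(cand - u, 2 * math.pi)) > 0.2
                    for u in used_dirs.setdefault(v, [])
                ):
                    angle = cand
                    break
            if angle is None:
                angle = base + rng.random() * 2 * math.pi
            used_dirs[v].append(angle)
            x0, y0 = placed[v]
            placed[w] = (x0 + math.cos(angle), y0 + math.sin(angle))
            incoming[w] = angle
            used_dirs[w] = [angle + math.pi]
            stack.append(w)
    for a in g.atoms:
        x, y = placed[a.index]
        a.x = x + float(rng.normal(0.0, 0.02))
        a.y = y + float(rng.normal(0.0, 0.02))


def _place_wedges(g: MolecularGraph, spec: CorpusSpec, rng) -> None:
    if spec.stereo_probability <= 0.0:
        return
    cells = stable_partition(g)
    colors: dict[int, int] = {}
    for ci, cell in enumerate(cells):
        for a in cell:
            colors[a] = ci
    adj = g.neighbors()
    bond_by_key = {b.key(): b for b in g.bonds}
    for a in g.atoms:
        nbrs = adj[a.index]
        if len(nbrs) + a.implicit_h != 4 or a.implicit_h > 1:
            continue
        if len({colors[w] for w in nbrs}) != len(nbrs):
            continue
        if rng.random() >= spec.stereo_probability:
            continue
        # prefer a terminal neighbor so the wedge cannot clash with another
        # center's wedge on a shared bond
        candidates = sorted(nbrs, key=lambda w: (len(adj[w]) > 1, w))
        for w in candidates:
            b = bond_by_key[(min(a.index, w), max(a.index, w))]
            if b.wedge != "none":
                continue
            if b.a1 != a.index:
                b.a1, b.a2 = b.a2, b.a1
            b.wedge = "up" if rng.random() < 0.5 else "down"
            break


def corpus(spec: CorpusSpec):
    """Yield the whole corpus in index order."""
    for i in range(spec.n_molecules):
        yield random_molecule(spec, i)


def write_corpus_sdf(spec: CorpusSpec) -> str:
    return write_sdf(corpus(spec))


# ---------------------------------------------------------------------------
# Hand-encoded reference structures


def _mol(name, atoms, bonds) -> MolecularGraph:
    g = MolecularGraph(
        atoms=[
            Atom(
                index=i + 1,
                element=el,
                x=x,
                y=y,
                formal_charge=chg,
            )
            for i, (el, x, y, chg) in enumerate(
                (a if len(a) == 4 else (*a, 0)) for a in atoms
            )
        ],
        bonds=[
            Bond(*(b if len(b) == 4 else (*b, "none")))
            for b in bonds
        ],
        name=name,
    )
    g.validate()
    g.assign_implicit_h()
    g.check_valences()
    return g


def reference_molecules() -> dict[str, MolecularGraph]:
    """Named hand-encoded structures: guanine, monosodium glutamate,
    (-)-menthol with its three wedge-marked centers, and the two drawings
    of the 1,4-oxime/nitroso (2-pyridinol N-oxide) tautomer pair."""
    out: dict[str, MolecularGraph] = {}

    # guanine, Kekulized: N1(H)-C2(=N3)(NH2), N3-C4, C4=C5, C5-C6(=O6)-N1,
    # C5-N7=C8-N9(H)-C4
    out["guanine"] = _mol(
        "guanine",
        [
            ("N", 0.0, 1.0),    # 1  N1 (H)
            ("C", 0.87, 1.5),   # 2  C2
            ("N", 1.73, 1.0),   # 3  N3
            ("C", 1.73, 0.0),   # 4  C4
            ("C", 0.87, -0.5),  # 5  C5
            ("C", 0.0, 0.0),    # 6  C6
            ("O", -0.87, -0.5), # 7  O6
            ("N", 1.2, -1.45),  # 8  N7
            ("C", 2.2, -1.5),   # 9  C8
            ("N", 2.6, -0.55),  # 10 N9 (H)
            ("N", 0.87, 2.5),   # 11 N2 (H2)
        ],
        [
            (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 6, 1),
            (6, 1, 1), (6, 7, 2), (5, 8, 1), (8, 9, 2), (9, 10, 1),
            (10, 4, 1), (2, 11, 1),
        ],
    )

    # monosodium glutamate drawn covalently: HOOC-CH2-CH2-CH(NH2)-COO-Na
    out["monosodium-glutamate"] = _mol(
        "monosodium glutamate",
        [
            ("C", 0.0, 0.0),   # 1 carboxyl C (acid)
            ("O", -0.5, 0.87), # 2 =O
            ("O", -0.87, -0.5),# 3 O-H
            ("C", 1.0, 0.0),   # 4 CH2
            ("C", 1.5, 0.87),  # 5 CH2
            ("C", 2.5, 0.87),  # 6 CH (NH2)
            ("N", 3.0, 1.73),  # 7 NH2
            ("C", 3.0, 0.0),   # 8 carboxylate C
            ("O", 2.5, -0.87), # 9 =O
            ("O", 4.0, 0.0),   # 10 O-Na
            ("Na", 5.0, 0.0),  # 11
        ],
        [
            (1, 2, 2), (1, 3, 1), (1, 4, 1), (4, 5, 1), (5, 6, 1),
            (6, 7, 1), (6, 8, 1), (8, 9, 2), (8, 10, 1), (10, 11, 1),
        ],
    )

    # (-)-menthol: 2-isopropyl-5-methylcyclohexan-1-ol, wedges on the three
    # stereocenters C1 (OH), C2 (iPr) and C5 (CH3)
    out["menthol"] = _mol(
        "(-)-menthol",
        [
            ("C", 0.0, 1.0),     # 1  C1 (OH)
            ("C", 0.87, 0.5),    # 2  C2 (iPr)
            ("C", 0.87, -0.5),   # 3  C3
            ("C", 0.0, -1.0),    # 4  C4
            ("C", -0.87, -0.5),  # 5  C5 (CH3)
            ("C", -0.87, 0.5),   # 6  C6
            ("O", 0.0, 2.0),     # 7  OH
            ("C", 1.73, 1.0),    # 8  iPr CH
            ("C", 2.6, 0.5),     # 9  iPr CH3
            ("C", 1.73, 2.0),    # 10 iPr CH3
            ("C", -1.73, -1.0),  # 11 CH3
        ],
        [
            (1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (5, 6, 1),
            (6, 1, 1),
            (1, 7, 1, "up"), (2, 8, 1, "down"), (8, 9, 1), (8, 10, 1),
            (5, 11, 1, "up"),
        ],
    )

    # tautomer pair sharing skeleton and formula C5H5NO2
    out["pyridinol-n-oxide"] = _mol(
        "pyridin-2-ol N-oxide",
        [
            ("N", 0.0, 1.0, 1),   # 1 N(+)
            ("C", 0.87, 0.5),     # 2 C2 (OH)
            ("C", 0.87, -0.5),    # 3 C3
            ("C", 0.0, -1.0),     # 4 C4
            ("C", -0.87, -0.5),   # 5 C5
            ("C", -0.87, 0.5),    # 6 C6
            ("O", 1.73, 1.0),     # 7 O-H
            ("O", 0.0, 2.0, -1),  # 8 N-oxide O(-)
        ],
        [
            (1, 2, 1), (2, 3, 2), (3, 4, 1), (4, 5, 2), (5, 6, 1),
            (6, 1, 2), (2, 7, 1), (1, 8, 1),
        ],
    )
    out["n-hydroxypyridinone"] = _mol(
        "N-hydroxypyridin-2(1H)-one",
        [
            ("N", 0.0, 1.0),      # 1 N
            ("C", 0.87, 0.5),     # 2 C2 (=O)
            ("C", 0.87, -0.5),    # 3 C3
            ("C", 0.0, -1.0),     # 4 C4
            ("C", -0.87, -0.5),   # 5 C5
            ("C", -0.87, 0.5),    # 6 C6
            ("O", 1.73, 1.0),     # 7 ketone O
            ("O", 0.0, 2.0),      # 8 N-O-H
        ],
        [
            (1, 2, 1), (2, 3, 1), (3, 4, 2), (4, 5, 1), (5, 6, 2),
            (6, 1, 1), (2, 7, 2), (1, 8, 1),
        ],
    )
    return out
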