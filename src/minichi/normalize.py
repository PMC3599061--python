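"""Normalization: metal disconnection, proton balance, mobile-H detection.

The identifier describes the *normalized* structure; the drawn species is
recoverable from it via the proton balance p (protons removed minus protons
added during normalization) and, losslessly, via the auxiliary sidecar.

Proton balance is a structural, pKa-free rule applied to fixed site types:

* an O bearing a -1 charge is protonated to the neutral O-H form, unless an
  adjacent atom carries a positive charge (ylides/N-oxides are untouched);
* an N bearing a +1 charge and at least one attached H is deprotonated.

Both passes iterate to a fixed point so normalization is idempotent.

Mobile-hydrogen groups cover 1,3-shift tautomerism only: heteroatoms X, Y
from {N, O, S} joined through a single carbon as X-C=Y exchange a hydrogen
(or a charge) and are pooled into one group.  Longer-range shifts (1,4 and
beyond, e.g. oxime/nitroso interconversion across a ring) are deliberately
not merged, so such drawings keep distinct identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .elements import is_metal
from .graph import Bond, MolecularGraph


@dataclass(frozen=True)
class NormalizationOptions:
    """Mode switches for :func:`normalize`.

    The default instance is the "standard" option set; identifiers produced
    with it carry the standard version tag ("1S") and keys the "S" flag.
    """

    disconnect_metals: bool = True
    detect_tautomers: bool = True
    fixed_h: bool = False  # suppress mobile-H pooling in the main h-layer

    @property
    def is_standard(self) -> bool:
        return self.disconnect_metals and self.detect_tautomers and not self.fixed_h


STANDARD = NormalizationOptions()


@dataclass
class MobileHGroup:
    """Heteroatoms sharing mobile hydrogen(s) via 1,3-shifts.

    Indices refer to the component's own atom numbering.
    """

    member_atoms: frozenset[int]
    mobile_h_count: int
    mobile_charge: int = 0


@dataclass
class NormalizedStructure:
    components: list[MolecularGraph]
    proton_balance: int
    component_charges: list[int]
    mobile_groups: list[list[MobileHGroup]]
    fixed_h_variant: list[dict[int, int] | None]
    options: NormalizationOptions = STANDARD
    removed_metal_bonds: list[tuple[int, int, int]] = field(default_factory=list)
    input_index_maps: list[list[int]] = field(default_factory=list)

    @property
    def total_charge(self) -> int:
        return sum(self.component_charges)


def disconnect_metals(g: MolecularGraph, enabled: bool = True):
    """Cut every metal-nonmetal bond, charging fragments heterolytically
    (both electrons go to the more electronegative, non-metal end).

    Returns ``(graph, removed)`` with ``removed`` the cut bonds as
    ``(a1, a2, order)`` in the input numbering.  With ``enabled=False``
    (connected-metals mode) the graph passes through untouched.
    """
    if not enabled:
        return g.copy(), []
    cut = [
        b
        for b in g.bonds
        if is_metal(g.atom(b.a1).element) != is_metal(g.atom(b.a2).element)
    ]
    if not cut:
        return g.copy(), []
    out = g.copy()
    cut_keys = {b.key() for b in cut}
    out.bonds = [b for b in out.bonds if b.key() not in cut_keys]
    for b in cut:
        metal, other = (
            (b.a1, b.a2) if is_metal(g.atom(b.a1).element) else (b.a2, b.a1)
        )
        out.atom(metal).formal_charge += b.order
        out.atom(other).formal_charge -= b.order
    out.assign_implicit_h()
    return out, [(b.a1, b.a2, b.order) for b in cut]


def proton_balance(g: MolecularGraph) -> tuple[MolecularGraph, int]:
    """Neutralize chargeable O/N sites; return (graph, p).

    p = protons removed - protons added, so the drawn species is the
    normalized one plus p protons.
    """
    out = g.copy()
    adj = out.neighbors()
    p = 0
    changed = True
    while changed:
        changed = False
        for a in out.atoms:
            if a.element == "N" and a.formal_charge == 1 and a.implicit_h >= 1:
                a.formal_charge = 0
                out.assign_implicit_h()
                p += 1
                changed = True
        for a in out.atoms:
            if a.element == "O" and a.formal_charge == -1:
                if any(
                    out.atom(w).formal_charge > 0 for w in adj[a.index]
                ):
                    continue
                a.formal_charge = 0
                out.assign_implicit_h()
                p -= 1
                changed = True
    return out, p


def detect_mobile_h(g: MolecularGraph) -> list[MobileHGroup]:
    """Pool N/O/S heteroatoms linked as X-C=Y into mobile-H groups.

    A pooled set only becomes a group if it spans >= 2 atoms and carries at
    least one hydrogen or a net charge (otherwise nothing can move).
    """
    het = {
        a.index for a in g.atoms if a.element in ("N", "O", "S")
    }
    if len(het) < 2:
        return []
    adj = g.adjacency()
    parent = {i: i for i in het}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for a in g.atoms:
        if a.element != "C":
            continue
        singles = [w for w, o in adj[a.index] if o == 1 and w in het]
        doubles = [w for w, o in adj[a.index] if o == 2 and w in het]
        if singles and doubles:
            for x in singles:
                for y in doubles:
                    union(x, y)

    pools: dict[int, list[int]] = {}
    for i in het:
        pools.setdefault(find(i), []).append(i)
    groups = []
    for members in pools.values():
        if len(members) < 2:
            continue
        h = sum(g.atom(i).implicit_h for i in members)
        q = sum(g.atom(i).formal_charge for i in members)
        if h >= 1 or q != 0:
            groups.append(
                MobileHGroup(
                    member_atoms=frozenset(members),
                    mobile_h_count=h,
                    mobile_charge=q,
                )
            )
    groups.sort(key=lambda gr: min(gr.member_atoms))
    return groups


def normalize(
    g: MolecularGraph, opts: NormalizationOptions = STANDARD
) -> NormalizedStructure:
    """Full normalization pipeline; idempotent by construction.

    Components are split after metal disconnection; their final canonical
    ordering happens at emission time (it needs the canonical layer strings),
    so here they are kept in input order of their smallest atom index.
    """
    g.validate()
    g.check_valences()
    disc, removed = disconnect_metals(g, enabled=opts.disconnect_metals)
    comp_indices = disc.components()
    components: list[MolecularGraph] = []
    charges: list[int] = []
    groups: list[list[MobileHGroup]] = []
    fixed_variants: list[dict[int, int] | None] = []
    index_maps: list[list[int]] = []
    p_total = 0
    for indices in comp_indices:
        sub = disc.subgraph(indices)
        balanced, p = proton_balance(sub)
        p_total += p
        mg = detect_mobile_h(balanced) if opts.detect_tautomers else []
        if mg:
            fixed_variants.append(
                {a.index: a.implicit_h for a in balanced.atoms}
            )
        else:
            fixed_variants.append(None)
        components.append(balanced)
        charges.append(sum(a.formal_charge for a in balanced.atoms))
        groups.append(mg)
        index_maps.append(list(indices))
    return NormalizedStructure(
        components=components,
        proton_balance=p_total,
        component_charges=charges,
        mobile_groups=groups,
        fixed_h_variant=fixed_variants,
        options=opts,
        removed_metal_bonds=removed,
        input_index_maps=index_maps,
    )


# -- inverse direction -------------------------------------------------------

# Site-preference classes for re-applying the proton balance when a parsed
# structure is rebuilt without auxiliary data.  Deprotonation prefers the
# most acidic O-H (carboxylic > enol/phenol-like > other O-H); protonation
# prefers the most H-rich neutral N.  Ties break toward the lowest index.


def _acid_class(g: MolecularGraph, o_index: int) -> int:
    adj = g.adjacency()
    for c, order in adj[o_index]:
        if g.atom(c).element != "C" or order != 1:
            continue
        for w, o2 in adj[c]:
            if w != o_index and o2 == 2 and g.atom(w).element == "O":
                return 0  # carboxylic / vinylogous acid
        if any(o2 == 2 for _, o2 in adj[c]):
            return 1  # enol / phenol-like
    return 2


def apply_protons(
    g: MolecularGraph, p: int, prefer: set[int] | None = None
) -> MolecularGraph:
    """Re-apply a proton balance: p > 0 re-creates the cation by protonating
    the most basic N; p < 0 re-creates the anion by deprotonating the most
    acidic O-H.  ``prefer`` sites (e.g. future metal-bond endpoints) win all
    ties; remaining ties break toward the lowest atom index (the canonical
    number, for parsed structures).  Best-effort on exotic inputs."""
    prefer = prefer or set()
    out = g.copy()
    remaining = p
    while remaining > 0:
        adj = out.adjacency()
        sites = [
            a.index
            for a in out.atoms
            if a.element == "N"
            and a.formal_charge == 0
            and out.bond_order_sum(a.index) <= 3
        ]
        if not sites:
            break
        # sp3 amines are the preferred (most basic) protonation sites
        sites.sort(
            key=lambda i: (i not in prefer, any(o > 1 for _, o in adj[i]), i)
        )
        out.atom(sites[0]).formal_charge = 1
        out.assign_implicit_h()
        remaining -= 1
    while remaining < 0:
        sites = [
            a.index
            for a in out.atoms
            if a.element == "O" and a.formal_charge == 0 and a.implicit_h >= 1
        ]
        if not sites:
            break
        sites.sort(key=lambda i: (i not in prefer, _acid_class(out, i), i))
        out.atom(sites[0]).formal_charge = -1
        out.assign_implicit_h()
        remaining += 1
    return out


def reassemble(ns: NormalizedStructure) -> MolecularGraph:
    """Merge components back into one graph (input numbering when index
    maps are present), re-apply the proton balance, and restore any
    disconnected metal bonds.  The inverse of :func:`normalize` up to
    site ambiguity of the proton balance."""
    n_total = sum(len(c.atoms) for c in ns.components)
    maps = ns.input_index_maps
    if not maps:
        maps = []
        next_idx = 1
        for c in ns.components:
            maps.append(list(range(next_idx, next_idx + len(c.atoms))))
            next_idx += len(c.atoms)
    merged = MolecularGraph()
    from dataclasses import replace as _rep

    slots: list = [None] * n_total
    bonds = []
    for comp, m in zip(ns.components, maps):
        for a in comp.atoms:
            na = _rep(a)
            na.index = m[a.index - 1]
            slots[na.index - 1] = na
        for b in comp.bonds:
            bonds.append(Bond(m[b.a1 - 1], m[b.a2 - 1], b.order, b.wedge))
    merged.atoms = slots
    merged.bonds = bonds
    merged.assign_implicit_h()
    # invert protonation first (the sites a metal bond will claim must be
    # freed before the bond and its heterolytic charges are restored)
    pending = {
        a2 if is_metal(merged.atom(a1).element) else a1
        for a1, a2, _ in ns.removed_metal_bonds
    }
    merged = apply_protons(merged, ns.proton_balance, prefer=pending)
    for a1, a2, order in ns.removed_metal_bonds:
        merged.bonds.append(Bond(a1, a2, order))
        metal, other = (
            (a1, a2) if is_metal(merged.atom(a1).element) else (a2, a1)
        )
        merged.atom(metal).formal_charge -= order
        merged.atom(other).formal_charge += order
    merged.assign_implicit_h()
    return merged
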