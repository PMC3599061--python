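"""Tetrahedral and double-bond stereo perception from 2D drawings.

Tetrahedral parity convention: the four substituents (a phantom H ranks
lowest and comes first) are taken in canonical-rank order; z-coordinates are
assigned from the wedge flags drawn at the center (up = +1, down = -1, flat
= 0, phantom H opposite the wedged neighbors); parity is the sign of the
signed volume of the ordered substituent tetrahedron.  Any fixed convention
works, since acceptance of stereo is via self-consistency (mirror flips
every parity; permutation of input order changes nothing).

Stereogenicity is decided by branch in-equivalence under the stable
refinement partition, not CIP rules: a center counts only when its 3-4
heavy neighbors lie in pairwise different refinement cells (plus an implicit
H as the distinct fourth branch where present).  Refinement can only merge
truly equivalent-or-tighter classes, so this test never invents a false
center; it may conservatively miss centers whose branches are locally
distinct but globally symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .canon import CanonicalRanking
from .errors import GeometryError, StereoConflictError
from .graph import WEDGE_DOWN, WEDGE_UP, MolecularGraph

log = logging.getLogger("minichi")

_COLLINEAR_EPS = 1e-4


@dataclass
class TetrahedralCenter:
    atom: int  # canonical number
    neighbor_order: tuple[int, ...]  # canonical numbers, phantom H = 0 first
    parity: int  # +1 | -1


@dataclass
class DoubleBondDescriptor:
    bond: tuple[int, int]  # canonical numbers, higher first
    together: bool  # reference substituents cis (True) or trans (False)


@dataclass
class StereoSummary:
    centers: list[TetrahedralCenter]
    double_bonds: list[DoubleBondDescriptor]
    stereo_type: int = 1  # 1 absolute | 2 relative | 3 racemic
    mirror_flag: int = 0  # 1 iff canonical form required global inversion


def _signed_volume(p0, p1, p2, p3) -> float:
    ax, ay, az = (p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2])
    bx, by, bz = (p2[0] - p0[0], p2[1] - p0[1], p2[2] - p0[2])
    cx, cy, cz = (p3[0] - p0[0], p3[1] - p0[1], p3[2] - p0[2])
    return (
        ax * (by * cz - bz * cy)
        - ay * (bx * cz - bz * cx)
        + az * (bx * cy - by * cx)
    )


def perceive_tetrahedral(
    g: MolecularGraph, ranking: CanonicalRanking
) -> list[TetrahedralCenter]:
    """Stereocenters with defined (wedge-carrying) geometry.

    Candidates without any wedge at the center are silently skipped (drawn
    without stereo); a wedge on a non-stereogenic atom logs a warning and is
    ignored; wedges whose geometry collapses (zero signed volume) raise
    :class:`StereoConflictError`.
    """
    adj = g.neighbors()
    colors = ranking.colors
    wedge_at: dict[int, dict[int, int]] = {}
    for b in g.bonds:
        if b.wedge == WEDGE_UP:
            wedge_at.setdefault(b.a1, {})[b.a2] = 1
        elif b.wedge == WEDGE_DOWN:
            wedge_at.setdefault(b.a1, {})[b.a2] = -1

    centers: list[TetrahedralCenter] = []
    for a in g.atoms:
        nbrs = adj[a.index]
        n_heavy = len(nbrs)
        h = a.implicit_h
        if n_heavy + h != 4 or h > 1:
            if a.index in wedge_at:
                log.warning(
                    "wedge on non-tetrahedral atom %d ignored", a.index
                )
            continue
        branch_colors = [colors[w] for w in nbrs]
        if len(set(branch_colors)) != n_heavy:
            if a.index in wedge_at:
                log.warning(
                    "wedge on non-stereogenic atom %d ignored", a.index
                )
            continue
        zmap = wedge_at.get(a.index, {})
        if not zmap:
            continue  # stereogenic but drawn without stereo
        pts = []
        zsum = sum(zmap.get(w, 0) for w in nbrs)
        ordered = sorted(nbrs, key=lambda w: ranking.rank[w])
        if h == 1:
            # phantom H sits at the center, displaced opposite the wedges
            pts.append((a.x, a.y, -float(zsum)))
            neighbor_order = (0, *[ranking.rank[w] for w in ordered])
        else:
            neighbor_order = tuple(ranking.rank[w] for w in ordered)
        for w in ordered:
            wa = g.atom(w)
            pts.append((wa.x, wa.y, float(zmap.get(w, 0))))
        if h == 1 and zsum == 0:
            # wedge(s) cancel out; put phantom H below the plane
            pts[0] = (a.x, a.y, -1.0)
        vol = _signed_volume(*pts)
        if abs(vol) < _COLLINEAR_EPS:
            raise StereoConflictError(
                f"contradictory or degenerate wedges at atom {a.index}"
            )
        centers.append(
            TetrahedralCenter(
                atom=ranking.rank[a.index],
                neighbor_order=neighbor_order,
                parity=1 if vol > 0 else -1,
            )
        )
    centers.sort(key=lambda c: c.atom)
    return centers


def _smallest_ring_through(g: MolecularGraph, a1: int, a2: int) -> int | None:
    """Length of the smallest cycle containing bond a1-a2 (None if acyclic)."""
    nbrs = g.neighbors()
    from collections import deque

    dist = {a1: 0}
    dq = deque([a1])
    while dq:
        v = dq.popleft()
        for w in nbrs[v]:
            if v == a1 and w == a2:
                continue  # skip the direct edge
            if w not in dist:
                dist[w] = dist[v] + 1
                dq.append(w)
    return dist[a2] + 1 if a2 in dist else None


def perceive_double_bond(
    g: MolecularGraph, ranking: CanonicalRanking
) -> list[DoubleBondDescriptor]:
    """cis/trans descriptors for stereogenic C=C and C=N bonds.

    Small-ring double bonds (ring size < 8) carry no descriptor.  The
    reference substituent on each end is the lowest-canonical-rank heavy
    neighbor; an end with two equivalent substituents (same refinement
    cell) is non-stereogenic.
    """
    adj = g.neighbors()
    colors = ranking.colors
    out: list[DoubleBondDescriptor] = []
    for b in g.bonds:
        if b.order != 2:
            continue
        e1, e2 = g.atom(b.a1).element, g.atom(b.a2).element
        if {e1, e2} not in ({"C"}, {"C", "N"}):
            continue
        ring = _smallest_ring_through(g, b.a1, b.a2)
        if ring is not None and ring < 8:
            continue
        refs = []
        ok = True
        for end, other in ((b.a1, b.a2), (b.a2, b.a1)):
            subs = [w for w in adj[end] if w != other]
            if not subs:
                ok = False
                break
            if len(subs) == 2 and colors[subs[0]] == colors[subs[1]]:
                ok = False
                break
            refs.append(min(subs, key=lambda w: ranking.rank[w]))
        if not ok:
            continue
        p1, p2 = g.atom(b.a1), g.atom(b.a2)
        r1, r2 = g.atom(refs[0]), g.atom(refs[1])
        dx, dy = p2.x - p1.x, p2.y - p1.y
        s1 = dx * (r1.y - p1.y) - dy * (r1.x - p1.x)
        s2 = dx * (r2.y - p2.y) - dy * (r2.x - p2.x)
        scale = max(abs(dx) + abs(dy), 1e-12) ** 2
        if abs(s1) / scale < _COLLINEAR_EPS or abs(s2) / scale < _COLLINEAR_EPS:
            raise GeometryError(
                f"collinear substituents at double bond {b.a1}-{b.a2}"
            )
        hi, lo = sorted((ranking.rank[b.a1], ranking.rank[b.a2]), reverse=True)
        out.append(DoubleBondDescriptor(bond=(hi, lo), together=(s1 > 0) == (s2 > 0)))
    out.sort(key=lambda d: d.bond)
    return out


def classify_stereo_type(
    centers: list[TetrahedralCenter],
    double_bonds: list[DoubleBondDescriptor] | None = None,
    intent: str = "absolute",
) -> StereoSummary:
    """Assemble the stereo summary; pick the canonical global mirror.

    ``intent`` is "absolute" (default), "relative" or "racemic" — it comes
    from input annotation (SDF data field), never from inference.  The
    canonical parity assignment is whichever of the parity string and its
    mirror renders lexicographically smaller; ``mirror_flag`` is 1 iff the
    inversion was applied.
    """
    stereo_type = {"absolute": 1, "relative": 2, "racemic": 3}[intent]
    summary = StereoSummary(
        centers=[
            TetrahedralCenter(c.atom, c.neighbor_order, c.parity)
            for c in centers
        ],
        double_bonds=list(double_bonds or []),
        stereo_type=stereo_type,
        mirror_flag=0,
    )
    if not summary.centers:
        return summary
    rendered = _parity_string(summary.centers)
    flipped = _parity_string(
        [
            TetrahedralCenter(c.atom, c.neighbor_order, -c.parity)
            for c in summary.centers
        ]
    )
    if flipped < rendered:
        for c in summary.centers:
            c.parity = -c.parity
        summary.mirror_flag = 1
    return summary


def _parity_string(centers: list[TetrahedralCenter]) -> str:
    return ",".join(
        f"{c.atom}{'+' if c.parity > 0 else '-'}"
        for c in sorted(centers, key=lambda c: c.atom)
    )
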