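"""Layered identifier: emission, grammar, parsing, containment, aux sidecar.

Layer order is fixed: formula, /c, /h, /q, /p, /b, /t, /m, /s, /i, /f.
Empty layers are omitted.  Multi-component structures join per-component
sub-strings with ";" (runs of identical sub-strings collapse to "k*s") and
component formulas with "." (identical ones collapse to a count prefix).
Components are ordered by their canonical layer strings, so the identifier
is independent of input component order.

The c-layer grammar follows the style of printed connection layers such as
``7-5-3-1-2-4-6(5)8``: a spanning-tree walk from canonical atom 1 visiting
neighbors in rank order; consecutive atoms joined by "-", side items
(branches, and ring closures recorded at the revisiting end) parenthesized
except the last, which continues the chain; a ring closure is simply the
revisited canonical number.

Parsing handles only strings produced by this tool (its own dialect).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._util import recursion_headroom
from .canon import CanonicalRanking, canonical_ranks
from .elements import implicit_hydrogens, max_valence
from .errors import IdentifierParseError, ReconstructionError
from .graph import Atom, Bond, MolecularGraph, hill_formula, parse_hill
from .normalize import (
    STANDARD,
    MobileHGroup,
    NormalizationOptions,
    NormalizedStructure,
    normalize,
    reassemble,
)
from .stereo import (
    DoubleBondDescriptor,
    StereoSummary,
    TetrahedralCenter,
    perceive_double_bond,
    perceive_tetrahedral,
)

PREFIX = "InChI="

_LAYER_ORDER = ("c", "h", "q", "p", "b", "t", "m", "s", "i", "f")


@dataclass
class LayeredIdentifier:
    """Rendered layers (strings without their letter prefix; "" = absent)."""

    version_tag: str = "1S"
    formula: str = ""
    c_layer: str = ""
    h_layer: str = ""
    q_layer: str = ""
    p_layer: str = ""
    b_layer: str = ""
    t_layer: str = ""
    m_layer: str = ""
    s_layer: str = ""
    i_layer: str = ""
    f_block: str = ""

    _FIELDS = {
        "c": "c_layer",
        "h": "h_layer",
        "q": "q_layer",
        "p": "p_layer",
        "b": "b_layer",
        "t": "t_layer",
        "m": "m_layer",
        "s": "s_layer",
        "i": "i_layer",
        "f": "f_block",
    }

    def get(self, letter: str) -> str:
        return getattr(self, self._FIELDS[letter])

    def set(self, letter: str, value: str) -> None:
        setattr(self, self._FIELDS[letter], value)

    def render(self) -> str:
        parts = [PREFIX + self.version_tag, self.formula]
        for letter in _LAYER_ORDER:
            val = self.get(letter)
            if val:
                parts.append(letter + val)
        return "/".join(parts)

    @classmethod
    def from_string(cls, s: str) -> "LayeredIdentifier":
        """Split an identifier string into layers (no reconstruction)."""
        if not s.startswith(PREFIX):
            raise IdentifierParseError(f"missing {PREFIX!r} prefix")
        body = s[len(PREFIX):]
        segments = body.split("/")
        version = segments[0]
        if version not in ("1", "1S"):
            raise IdentifierParseError(f"unknown version tag {version!r}")
        if len(segments) < 2 or not segments[1]:
            raise IdentifierParseError("missing formula layer")
        out = cls(version_tag=version, formula=segments[1])
        seen_pos = -1
        for seg in segments[2:]:
            if not seg:
                raise IdentifierParseError("empty layer segment")
            letter, val = seg[0], seg[1:]
            if letter not in cls._FIELDS:
                raise IdentifierParseError("unknown layer letter", letter)
            pos = _LAYER_ORDER.index(letter)
            if pos <= seen_pos:
                raise IdentifierParseError("layer out of order", letter)
            if not val:
                raise IdentifierParseError("empty layer", letter)
            seen_pos = pos
            out.set(letter, val)
        return out

    def layers_present(self) -> dict[str, str]:
        out = {"formula": self.formula}
        for letter in _LAYER_ORDER:
            if self.get(letter):
                out[letter] = self.get(letter)
        return out


def layer_subset(a: LayeredIdentifier, b: LayeredIdentifier) -> bool:
    """True iff every layer present in ``a`` is byte-equal in ``b``."""
    la, lb = a.layers_present(), b.layers_present()
    return all(lb.get(k) == v for k, v in la.items())


# ---------------------------------------------------------------------------
# Per-component layer rendering


def emit_c_layer(component: MolecularGraph, ranking: CanonicalRanking) -> str:
    """Connectivity layer: spanning-tree walk, terminal H never appear."""
    if len(component.atoms) <= 1 or not component.bonds:
        return ""
    rank = ranking.rank
    nbrs = component.neighbors()
    for v in nbrs:
        nbrs[v] = sorted(nbrs[v], key=lambda w: rank[w])
    root = ranking.order[0]
    visited = {root}
    used: set[tuple[int, int]] = set()

    def edge(a, b):
        return (a, b) if a < b else (b, a)

    def walk(v) -> str:
        items: list[str] = []
        for w in nbrs[v]:
            e = edge(v, w)
            if e in used:
                continue
            if w in visited:
                used.add(e)
                items.append(str(rank[w]))
            else:
                used.add(e)
                visited.add(w)
                items.append(walk(w))
        s = str(rank[v])
        for item in items[:-1]:
            s += "(" + item + ")"
        if items:
            s += items[-1] if s.endswith(")") else "-" + items[-1]
        return s

    with recursion_headroom(2 * len(component.atoms)):
        return walk(root)


def _ranges(nums: list[int]) -> str:
    """Compress a sorted int list: runs of >=2 become "a-b"."""
    parts = []
    i = 0
    while i < len(nums):
        j = i
        while j + 1 < len(nums) and nums[j + 1] == nums[j] + 1:
            j += 1
        parts.append(str(nums[i]) if i == j else f"{nums[i]}-{nums[j]}")
        i = j + 1
    return ",".join(parts)


def _charge_token(q: int) -> str:
    if q == 0:
        return ""
    sign = "+" if q > 0 else "-"
    return sign + (str(abs(q)) if abs(q) > 1 else "")


def emit_h_layer(
    component: MolecularGraph,
    ranking: CanonicalRanking,
    mobile_groups: list[MobileHGroup] | None = None,
    pooled: bool = True,
) -> str:
    """Hydrogen layer: fixed H grouped by count, mobile groups appended.

    With ``pooled=False`` every H is listed at its fixed position (the form
    used inside the /f block).
    """
    mobile_groups = mobile_groups or []
    rank = ranking.rank
    mobile_atoms: set[int] = set()
    if pooled:
        for gr in mobile_groups:
            mobile_atoms |= gr.member_atoms
    by_count: dict[int, list[int]] = {}
    for a in component.atoms:
        if a.index in mobile_atoms or a.implicit_h == 0:
            continue
        by_count.setdefault(a.implicit_h, []).append(rank[a.index])
    parts = [
        _ranges(sorted(by_count[c])) + "H" + (str(c) if c > 1 else "")
        for c in sorted(by_count)
    ]
    if pooled:
        rendered_groups = []
        for gr in mobile_groups:
            nums = sorted(rank[i] for i in gr.member_atoms)
            head = "H"
            if gr.mobile_h_count > 1:
                head += str(gr.mobile_h_count)
            head += _charge_token(gr.mobile_charge)
            rendered_groups.append(
                "(" + head + "," + ",".join(map(str, nums)) + ")"
            )
        parts.extend(sorted(rendered_groups))
    return ",".join(parts)


def _emit_i_layer(component: MolecularGraph, ranking: CanonicalRanking) -> str:
    toks = sorted(
        (ranking.rank[a.index], a.isotope_delta)
        for a in component.atoms
        if a.isotope_delta
    )
    return ",".join(f"{n}{d:+d}" for n, d in toks)


def _t_string(centers: list[TetrahedralCenter]) -> str:
    return ",".join(
        f"{c.atom}{'+' if c.parity > 0 else '-'}"
        for c in sorted(centers, key=lambda c: c.atom)
    )


def _b_string(dbs: list[DoubleBondDescriptor]) -> str:
    return ",".join(
        f"{hi}-{lo}{'+' if d.together else '-'}"
        for d in sorted(dbs, key=lambda d: d.bond)
        for hi, lo in (d.bond,)
    )


# ---------------------------------------------------------------------------
# Stereo-aware ranking tie-break


def _resolve_ranking(component: MolecularGraph, rk: CanonicalRanking):
    """Among automorphically tied optimal rankings, pick the one whose
    rendered stereo layers are smallest (mirror-image parities compare by
    their mirror-canonical form so reflected inputs resolve identically)."""
    candidates = [rk.order] + rk.tied_orders
    if len(candidates) == 1:
        return rk, *_perceive(component, rk)
    best = None
    for order in candidates:
        cand = CanonicalRanking(
            rank={a: i + 1 for i, a in enumerate(order)},
            order=order,
            colors=rk.colors,
            tied_orders=[],
        )
        centers, dbs = _perceive(component, cand)
        t = _t_string(centers)
        t_flip = _t_string(
            [TetrahedralCenter(c.atom, c.neighbor_order, -c.parity) for c in centers]
        )
        key = (min(t, t_flip), _b_string(dbs), t)
        if best is None or key < best[0]:
            best = (key, cand, centers, dbs)
    return best[1], best[2], best[3]


def _perceive(component, ranking):
    centers = perceive_tetrahedral(component, ranking)
    dbs = perceive_double_bond(component, ranking)
    return centers, dbs


# ---------------------------------------------------------------------------
# Aux sidecar


@dataclass
class AuxNumbering:
    """Sidecar for lossless reconstruction: per-component canonical-to-input
    numbering plus the original bond/wedge/coordinate/charge/isotope record.

    ``component_maps[k][i-1]`` is the original input index of canonical atom
    ``i`` of component ``k`` (components in identifier order).  Bonds,
    coordinates, charges and isotopes are stored in original numbering.
    """

    component_maps: list[list[int]] = field(default_factory=list)
    charges: dict[int, int] = field(default_factory=dict)
    isotopes: dict[int, int] = field(default_factory=dict)
    bonds: list[tuple[int, int, int, str]] = field(default_factory=list)
    coords: dict[int, tuple[float, float]] = field(default_factory=dict)

    def to_text(self) -> str:
        parts = ["MAUX=1"]
        parts.append(
            "N:" + ";".join(",".join(map(str, m)) for m in self.component_maps)
        )
        if self.charges:
            parts.append(
                "Q:" + ",".join(f"{i}:{q}" for i, q in sorted(self.charges.items()))
            )
        if self.isotopes:
            parts.append(
                "I:" + ",".join(f"{i}:{d}" for i, d in sorted(self.isotopes.items()))
            )
        if self.bonds:
            parts.append(
                "B:"
                + ",".join(
                    f"{a}-{b}:{o}:{w[0]}" for a, b, o, w in self.bonds
                )
            )
        if self.coords:
            parts.append(
                "G:"
                + ";".join(
                    f"{i}:{x:.4f}:{y:.4f}"
                    for i, (x, y) in sorted(self.coords.items())
                )
            )
        return "|".join(parts)

    @classmethod
    def from_text(cls, text: str) -> "AuxNumbering":
        parts = text.strip().split("|")
        if not parts or parts[0] != "MAUX=1":
            raise IdentifierParseError("not an aux sidecar (missing MAUX=1)")
        out = cls()
        wedges = {"n": "none", "u": "up", "d": "down"}
        for part in parts[1:]:
            tag, _, body = part.partition(":")
            if tag == "N":
                out.component_maps = [
                    [int(x) for x in comp.split(",")] for comp in body.split(";")
                ]
            elif tag == "Q":
                out.charges = {
                    int(i): int(q)
                    for i, q in (tok.split(":") for tok in body.split(","))
                }
            elif tag == "I":
                out.isotopes = {
                    int(i): int(d)
                    for i, d in (tok.split(":") for tok in body.split(","))
                }
            elif tag == "B":
                for tok in body.split(","):
                    ab, o, w = tok.split(":")
                    a, b = ab.split("-")
                    out.bonds.append((int(a), int(b), int(o), wedges[w]))
            elif tag == "G":
                for tok in body.split(";"):
                    i, x, y = tok.split(":")
                    out.coords[int(i)] = (float(x), float(y))
            else:
                raise IdentifierParseError(f"unknown aux field {tag!r}")
        return out


# ---------------------------------------------------------------------------
# Emission


@dataclass
class EmitResult:
    identifier: str
    layered: LayeredIdentifier
    aux: AuxNumbering
    normalized: NormalizedStructure
    stereo: StereoSummary


def _join_components(strings: list[str]) -> str:
    """";"-join with "k*s" collapsing of runs of identical non-empty parts."""
    if all(not s for s in strings):
        return ""
    out = []
    i = 0
    while i < len(strings):
        j = i
        while j + 1 < len(strings) and strings[j + 1] == strings[i]:
            j += 1
        k = j - i + 1
        if k > 1 and strings[i]:
            out.append(f"{k}*{strings[i]}")
        else:
            out.extend([strings[i]] * k)
        i = j + 1
    return ";".join(out)


def _join_formulas(formulas: list[str]) -> str:
    out = []
    i = 0
    while i < len(formulas):
        j = i
        while j + 1 < len(formulas) and formulas[j + 1] == formulas[i]:
            j += 1
        k = j - i + 1
        out.append((str(k) if k > 1 else "") + formulas[i])
        i = j + 1
    return ".".join(out)


def emit_identifier(
    ns: NormalizedStructure,
    input_graph: MolecularGraph | None = None,
    intent: str = "absolute",
) -> EmitResult:
    """Assemble the full identifier string for a normalized structure.

    ``input_graph`` (the pre-normalization drawing) feeds the aux sidecar;
    without it the sidecar records the normalized form itself.
    """
    records = []
    maps = ns.input_index_maps or [
        [a.index for a in c.atoms] for c in ns.components
    ]
    for comp, groups, imap in zip(ns.components, ns.mobile_groups, maps):
        rk = canonical_ranks(comp)
        rk, centers, dbs = _resolve_ranking(comp, rk)
        rec = {
            "formula": hill_formula(comp),
            "c": emit_c_layer(comp, rk),
            "h": emit_h_layer(comp, rk, groups),
            "q": _charge_value_str(sum(a.formal_charge for a in comp.atoms)),
            "i": _emit_i_layer(comp, rk),
            "b": _b_string(dbs),
            "f": emit_h_layer(comp, rk, groups, pooled=False) if groups else "",
            "centers": centers,
            "dbs": dbs,
            "ranking": rk,
            "comp": comp,
            "imap": imap,
        }
        records.append(rec)

    records.sort(
        key=lambda r: (r["formula"], r["c"], r["h"], r["q"], r["i"], r["b"], r["f"])
    )

    # Global mirror canonicalization: emit whichever of the parity assignment
    # and its full inversion renders smaller; /m records the choice.
    all_centers = [c for r in records for c in r["centers"]]
    mirror_flag = 0
    if all_centers:
        raw = "|".join(_t_string(r["centers"]) for r in records)
        inv = "|".join(
            _t_string(
                [
                    TetrahedralCenter(c.atom, c.neighbor_order, -c.parity)
                    for c in r["centers"]
                ]
            )
            for r in records
        )
        if inv < raw:
            mirror_flag = 1
            for r in records:
                for c in r["centers"]:
                    c.parity = -c.parity
    summary = StereoSummary(
        centers=all_centers,
        double_bonds=[d for r in records for d in r["dbs"]],
        stereo_type={"absolute": 1, "relative": 2, "racemic": 3}[intent],
        mirror_flag=mirror_flag,
    )

    layered = LayeredIdentifier(
        version_tag="1S" if ns.options.is_standard else "1"
    )
    layered.formula = _join_formulas([r["formula"] for r in records])
    layered.c_layer = _join_components([r["c"] for r in records])
    layered.h_layer = _join_components([r["h"] for r in records])
    layered.q_layer = _join_components([r["q"] for r in records])
    if ns.proton_balance:
        layered.p_layer = f"{ns.proton_balance:+d}"
    layered.b_layer = _join_components([r["b"] for r in records])
    layered.t_layer = _join_components([_t_string(r["centers"]) for r in records])
    if all_centers:
        layered.m_layer = str(summary.mirror_flag)
        layered.s_layer = str(summary.stereo_type)
    layered.i_layer = _join_components([r["i"] for r in records])
    layered.f_block = _join_components([r["f"] for r in records])

    aux = _build_aux(ns, records, input_graph)
    return EmitResult(
        identifier=layered.render(),
        layered=layered,
        aux=aux,
        normalized=ns,
        stereo=summary,
    )


def _charge_value_str(q: int) -> str:
    return f"{q:+d}" if q else ""


def _build_aux(ns, records, input_graph) -> AuxNumbering:
    aux = AuxNumbering()
    for r in records:
        imap = r["imap"]
        # canonical position i holds component atom r["ranking"].order[i-1]
        aux.component_maps.append(
            [imap[a - 1] for a in r["ranking"].order]
        )
    src = input_graph
    if src is None:
        src = reassemble(ns)
    for a in src.atoms:
        if a.formal_charge:
            aux.charges[a.index] = a.formal_charge
        if a.isotope_delta:
            aux.isotopes[a.index] = a.isotope_delta
        aux.coords[a.index] = (a.x, a.y)
    for b in src.bonds:
        aux.bonds.append((b.a1, b.a2, b.order, b.wedge))
    return aux


def identify(
    g: MolecularGraph,
    opts: NormalizationOptions = STANDARD,
    intent: str | None = None,
) -> EmitResult:
    """One-call pipeline: normalize a drawing and emit its identifier."""
    if intent is None:
        intent = g.properties.get("STEREO_TYPE", "absolute").strip().lower()
        if intent not in ("absolute", "relative", "racemic"):
            intent = "absolute"
    ns = normalize(g, opts)
    return emit_identifier(ns, input_graph=g, intent=intent)


# ---------------------------------------------------------------------------
# Parsing back to structures


@dataclass
class ParseResult:
    layered: LayeredIdentifier
    normalized: NormalizedStructure
    graph: MolecularGraph  # reconstructed input drawing (exact with aux)


def _split_components(layer: str, n: int, letter: str) -> list[str]:
    """Expand ';'-joined, 'k*'-multiplied component sub-strings."""
    if not layer:
        return [""] * n
    out: list[str] = []
    for part in layer.split(";"):
        m = re.fullmatch(r"(\d+)\*(.*)", part)
        if m:
            out.extend([m.group(2)] * int(m.group(1)))
        else:
            out.append(part)
    if len(out) != n:
        raise IdentifierParseError(
            f"{len(out)} component entries for {n} components", letter
        )
    return out


def _split_formulas(formula: str) -> list[str]:
    out = []
    for part in formula.split("."):
        m = re.fullmatch(r"(\d*)([A-Za-z].*)", part)
        if not m:
            raise IdentifierParseError(f"bad formula component {part!r}")
        k = int(m.group(1)) if m.group(1) else 1
        out.extend([m.group(2)] * k)
    return out


def _parse_c_layer(s: str, letter: str = "c") -> list[tuple[int, int]]:
    """Parse a connection sub-string into an edge list."""
    if not s:
        return []
    tokens = re.findall(r"\d+|[()-]", s)
    if "".join(tokens) != s:
        raise IdentifierParseError(f"bad characters in {s!r}", letter)
    edges: list[tuple[int, int]] = []
    seen: set[int] = set()
    stack: list[int] = []
    cur: int | None = None
    expect_number = True
    for tok in tokens:
        if tok == "(":
            if cur is None:
                raise IdentifierParseError("branch before first atom", letter)
            stack.append(cur)
            expect_number = True
        elif tok == ")":
            if not stack:
                raise IdentifierParseError("unbalanced ')'", letter)
            cur = stack.pop()
            expect_number = False
        elif tok == "-":
            if cur is None or expect_number:
                raise IdentifierParseError("misplaced '-'", letter)
            expect_number = True
        else:
            n = int(tok)
            if cur is None:
                if n in seen:
                    raise IdentifierParseError("walk restarts on seen atom", letter)
                seen.add(n)
            else:
                e = (min(cur, n), max(cur, n))
                if cur == n or e in edges:
                    raise IdentifierParseError(f"bad edge {cur}-{n}", letter)
                edges.append(e)
                if n in seen:
                    pass  # ring closure: stay at cur? the walk ends or pops
                else:
                    seen.add(n)
                    cur = n
                    expect_number = False
                    continue
                # after a closure the chain cannot continue from the closure
                expect_number = False
                continue
            cur = n
            expect_number = False
    if stack:
        raise IdentifierParseError("unbalanced '('", letter)
    return edges


_H_FIXED_RE = re.compile(r"^(\d+(?:-\d+)?(?:,\d+(?:-\d+)?)*)H(\d*)$")
_H_MOBILE_RE = re.compile(r"^\(H(\d*)([+-]\d*)?,([\d,]+)\)$")


def _split_h_tokens(s: str) -> list[str]:
    """Split an h sub-string on commas outside parentheses, re-joining the
    atom-list prefix of each fixed-H token."""
    raw: list[str] = []
    depth = 0
    cur = ""
    for ch in s:
        if ch == "," and depth == 0:
            raw.append(cur)
            cur = ""
        else:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
            cur += ch
    if cur:
        raw.append(cur)
    # merge plain atom/range tokens into the following H token
    out: list[str] = []
    pending: list[str] = []
    for tok in raw:
        if re.fullmatch(r"\d+(?:-\d+)?", tok):
            pending.append(tok)
        else:
            out.append(",".join(pending + [tok]) if pending else tok)
            pending = []
    if pending:
        raise IdentifierParseError("trailing atom list in h layer", "h")
    return out


def _expand_ranges(spec: str) -> list[int]:
    nums = []
    for part in spec.split(","):
        if "-" in part:
            a, b = part.split("-")
            nums.extend(range(int(a), int(b) + 1))
        else:
            nums.append(int(part))
    return nums


def _parse_h_component(s: str):
    """Returns (fixed: dict atom->count, mobile: list of (h, charge, atoms))."""
    fixed: dict[int, int] = {}
    mobile = []
    if not s:
        return fixed, mobile
    for tok in _split_h_tokens(s):
        m = _H_FIXED_RE.match(tok)
        if m:
            count = int(m.group(2)) if m.group(2) else 1
            for n in _expand_ranges(m.group(1)):
                if n in fixed:
                    raise IdentifierParseError(f"atom {n} listed twice", "h")
                fixed[n] = count
            continue
        m = _H_MOBILE_RE.match(tok)
        if m:
            h = int(m.group(1)) if m.group(1) else 1
            qtok = m.group(2)
            q = 0
            if qtok:
                q = int(qtok[0] + (qtok[1:] or "1"))
            atoms = [int(x) for x in m.group(3).split(",")]
            if len(atoms) < 2:
                raise IdentifierParseError("mobile group needs >= 2 atoms", "h")
            mobile.append((h, q, atoms))
            continue
        raise IdentifierParseError(f"bad token {tok!r}", "h")
    return fixed, mobile


def _element_sequence(formula: str) -> list[str]:
    """Heavy-atom element per canonical index (C block, then alphabetical)."""
    try:
        counts = parse_hill(formula)
    except ValueError as exc:
        raise IdentifierParseError(str(exc)) from None
    counts.pop("H", None)
    seq: list[str] = []
    if "C" in counts:
        seq.extend(["C"] * counts.pop("C"))
    for el in sorted(counts):
        seq.extend([el] * counts[el])
    return seq


def _fill_bond_orders(
    elements: list[str],
    charges: list[int],
    h_counts: list[int],
    edges: list[tuple[int, int]],
) -> list[int] | None:
    """Assign bond orders consistent with per-atom element/charge/H.

    Finds extra-order increments (0/1/2 per edge) such that each atom's
    total bond-order sum yields exactly the required implicit-H count under
    the standard valence table.  Backtracking, deterministic; returns None
    when no assignment exists.
    """
    n = len(elements)
    deg = [0] * n
    for a, b in edges:
        deg[a - 1] += 1
        deg[b - 1] += 1

    def e_options(i: int) -> list[int]:
        opts = []
        for extra in range(0, 7):
            bos = deg[i] + extra
            if bos > max_valence(elements[i], charges[i]):
                break
            if implicit_hydrogens(elements[i], charges[i], bos) == h_counts[i]:
                opts.append(extra)
        return opts

    options = [e_options(i) for i in range(n)]
    if any(not o for o in options):
        return None

    incident: list[list[int]] = [[] for _ in range(n)]
    for ei, (a, b) in enumerate(edges):
        incident[a - 1].append(ei)
        incident[b - 1].append(ei)

    extra = [0] * len(edges)

    def feasible_atom(i: int, assigned: int, open_edges: int) -> bool:
        return any(
            assigned <= opt <= assigned + 2 * open_edges for opt in options[i]
        )

    assigned_sum = [0] * n
    open_count = [len(incident[i]) for i in range(n)]

    def rec(ei: int) -> bool:
        if ei == len(edges):
            return all(assigned_sum[i] in options[i] for i in range(n))
        a, b = edges[ei][0] - 1, edges[ei][1] - 1
        for x in (0, 1, 2):
            extra[ei] = x
            assigned_sum[a] += x
            assigned_sum[b] += x
            open_count[a] -= 1
            open_count[b] -= 1
            ok = feasible_atom(a, assigned_sum[a], open_count[a]) and feasible_atom(
                b, assigned_sum[b], open_count[b]
            )
            if ok and open_count[a] == 0 and assigned_sum[a] not in options[a]:
                ok = False
            if ok and open_count[b] == 0 and assigned_sum[b] not in options[b]:
                ok = False
            if ok and rec(ei + 1):
                return True
            assigned_sum[a] -= x
            assigned_sum[b] -= x
            open_count[a] += 1
            open_count[b] += 1
        extra[ei] = 0
        return False

    with recursion_headroom(2 * len(edges) + 10):
        if not rec(0):
            return None
    return [1 + x for x in extra]


def _place_charges(
    elements: list[str], h_counts: list[int], edges, q: int
) -> list[int] | None:
    """Heuristic per-atom charge placement for a component of net charge q."""
    n = len(elements)
    deg = [0] * n
    for a, b in edges:
        deg[a - 1] += 1
        deg[b - 1] += 1
    charges = [0] * n

    def has_option(i: int) -> bool:
        for extra in range(0, 7):
            bos = deg[i] + extra
            if bos > max_valence(elements[i], charges[i]):
                break
            if implicit_hydrogens(elements[i], charges[i], bos) == h_counts[i]:
                return True
        # degree-0 atoms: extra = 0 only
        return False

    budget = q
    # forced positives/negatives: atoms with no neutral option
    for i in range(n):
        if not has_option(i):
            for cand in (1, -1, 2, -2):
                charges[i] = cand
                if has_option(i):
                    budget -= cand
                    break
            else:
                charges[i] = 0
                return None
    # distribute the remaining net charge over plausible heteroatom sites
    order = sorted(
        range(n),
        key=lambda i: (
            {"O": 0, "S": 1, "N": 2}.get(elements[i], 3),
            i,
        ),
    )
    step = 1 if budget > 0 else -1
    for i in order:
        if budget == 0:
            break
        if charges[i] != 0:
            continue
        charges[i] += step
        if has_option(i):
            budget -= step
        else:
            charges[i] -= step
    if budget != 0:
        # last resort: pile the remainder on the first atom that tolerates it
        for i in range(n):
            charges[i] += budget
            if has_option(i):
                budget = 0
                break
            charges[i] -= budget
    return charges if budget == 0 else None


def parse_identifier(
    s: str, aux: AuxNumbering | str | None = None
) -> ParseResult:
    """Rebuild structures from an identifier produced by this tool.

    Without aux, bond orders come from the valence-filling heuristic and the
    drawn (pre-normalization) species is re-derived by re-applying the
    proton balance at preferred sites; both steps can fail or mis-place on
    exotic inputs.  With aux, reconstruction is exact.
    """
    layered = LayeredIdentifier.from_string(s)
    if isinstance(aux, str):
        aux = AuxNumbering.from_text(aux)
    opts = STANDARD if layered.version_tag == "1S" else NormalizationOptions(
        disconnect_metals=False
    )

    formulas = _split_formulas(layered.formula)
    ncomp = len(formulas)
    c_parts = _split_components(layered.c_layer, ncomp, "c")
    h_parts = _split_components(layered.h_layer, ncomp, "h")
    q_parts = _split_components(layered.q_layer, ncomp, "q")
    i_parts = _split_components(layered.i_layer, ncomp, "i")
    f_parts = _split_components(layered.f_block, ncomp, "f")
    try:
        p_val = int(layered.p_layer) if layered.p_layer else 0
    except ValueError:
        raise IdentifierParseError("bad proton balance", "p") from None

    components: list[MolecularGraph] = []
    charges_list: list[int] = []
    groups_list: list[list[MobileHGroup]] = []
    fixed_list: list[dict[int, int] | None] = []

    for k in range(ncomp):
        elements = _element_sequence(formulas[k])
        n = len(elements)
        edges = _parse_c_layer(c_parts[k])
        for a, b in edges:
            if not (1 <= a <= n and 1 <= b <= n):
                raise IdentifierParseError(f"edge {a}-{b} out of range", "c")
        fixed_h, mobile = _parse_h_component(h_parts[k])
        mobile_groups = [
            MobileHGroup(frozenset(atoms), h, qq) for h, qq, atoms in mobile
        ]
        if f_parts[k]:
            fixed_from_f, extra_mobile = _parse_h_component(f_parts[k])
            if extra_mobile:
                raise IdentifierParseError("mobile group inside /f", "f")
            h_counts_map = fixed_from_f
        else:
            h_counts_map = dict(fixed_h)
            for h, _q, atoms in mobile:
                # distribute pooled H deterministically from the lowest atom
                for j, atom in enumerate(sorted(atoms)):
                    if j < h:
                        h_counts_map[atom] = h_counts_map.get(atom, 0) + 1
        h_counts = [h_counts_map.get(i + 1, 0) for i in range(n)]
        q = int(q_parts[k]) if q_parts[k] else 0

        expected = parse_hill(formulas[k]).get("H", 0)
        if sum(h_counts) != expected:
            raise IdentifierParseError(
                f"H count mismatch: layers give {sum(h_counts)}, formula {expected}",
                "h",
            )

        charges = _place_charges(elements, h_counts, edges, q)
        if charges is None:
            raise ReconstructionError(
                f"cannot place net charge {q} on component {k + 1}"
            )
        orders = _fill_bond_orders(elements, charges, h_counts, edges)
        if orders is None:
            raise ReconstructionError(
                f"valence filling failed on component {k + 1}",
                partial=_raw_component(elements, edges, h_counts, charges),
            )
        comp = _raw_component(elements, edges, h_counts, charges)
        for bond, o in zip(comp.bonds, orders):
            bond.order = o
        for tok in (i_parts[k].split(",") if i_parts[k] else []):
            m = re.fullmatch(r"(\d+)([+-]\d+)", tok)
            if not m:
                raise IdentifierParseError(f"bad isotope token {tok!r}", "i")
            comp.atom(int(m.group(1))).isotope_delta = int(m.group(2))
        comp.assign_implicit_h()
        if [a.implicit_h for a in comp.atoms] != h_counts:
            raise ReconstructionError(
                f"filled orders do not reproduce H counts on component {k + 1}",
                partial=comp,
            )
        components.append(comp)
        charges_list.append(q)
        groups_list.append(mobile_groups)
        fixed_list.append(
            {i + 1: h_counts[i] for i in range(n)} if mobile_groups else None
        )

    ns = NormalizedStructure(
        components=components,
        proton_balance=p_val,
        component_charges=charges_list,
        mobile_groups=groups_list,
        fixed_h_variant=fixed_list,
        options=opts,
    )

    if aux is not None:
        graph = _graph_from_aux(layered, formulas, aux)
    else:
        graph = reassemble(ns)
    return ParseResult(layered=layered, normalized=ns, graph=graph)


def _raw_component(elements, edges, h_counts, charges) -> MolecularGraph:
    g = MolecularGraph(
        atoms=[
            Atom(index=i + 1, element=el, formal_charge=charges[i])
            for i, el in enumerate(elements)
        ],
        bonds=[Bond(a, b, 1) for a, b in edges],
    )
    for a, h in zip(g.atoms, h_counts):
        a.implicit_h = h
    return g


def _graph_from_aux(
    layered: LayeredIdentifier, formulas: list[str], aux: AuxNumbering
) -> MolecularGraph:
    if len(aux.component_maps) != len(formulas):
        raise IdentifierParseError(
            f"aux has {len(aux.component_maps)} components, identifier "
            f"{len(formulas)}"
        )
    n_total = sum(len(m) for m in aux.component_maps)
    atoms: list[Atom | None] = [None] * n_total
    for formula, cmap in zip(formulas, aux.component_maps):
        elements = _element_sequence(formula)
        if len(elements) != len(cmap):
            raise IdentifierParseError("aux map size mismatch with formula")
        for el, orig in zip(elements, cmap):
            if not (1 <= orig <= n_total) or atoms[orig - 1] is not None:
                raise IdentifierParseError(f"bad original index {orig} in aux")
            x, y = aux.coords.get(orig, (0.0, 0.0))
            atoms[orig - 1] = Atom(
                index=orig,
                element=el,
                formal_charge=aux.charges.get(orig, 0),
                isotope_delta=aux.isotopes.get(orig, 0),
                x=x,
                y=y,
            )
    g = MolecularGraph(
        atoms=atoms,  # type: ignore[arg-type]
        bonds=[Bond(a, b, o, w) for a, b, o, w in aux.bonds],
    )
    g.validate()
    g.assign_implicit_h()
    return g
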