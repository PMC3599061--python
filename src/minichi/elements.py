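"""Element data: symbols, valence rules, metal classification, isotope masses.

The implicit-hydrogen convention is a fixed, documented table: each element
has one or more allowed valences; the implicit H count of an atom is the
smallest allowed valence that accommodates its explicit bond-order sum, minus
that sum.  A formal charge shifts the allowed valences by the usual rule
(+1 on N gives 4, -1 on O gives 1, a charge on carbon removes a bond, ...).
Metals take no implicit hydrogens.
"""

from __future__ import annotations

# All IUPAC element symbols through Og, for input validation.
ELEMENT_SYMBOLS = frozenset(
    """H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co
    Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te
    I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir
    Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No
    Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og""".split()
)

# Metal set used by the disconnection rule: alkali, alkaline-earth, Al, Zn and
# the d-block, plus the heavier p-block metals.  B and Si are non-metals.
METALS = frozenset(
    """Li Na K Rb Cs Fr Be Mg Ca Sr Ba Ra Al Ga In Tl Sn Pb Bi
    Sc Ti V Cr Mn Fe Co Ni Cu Zn Y Zr Nb Mo Tc Ru Rh Pd Ag Cd
    La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu
    Hf Ta W Re Os Ir Pt Au Hg
    Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr""".split()
)

# Allowed neutral valences (ascending).  Elements not listed (noble gases,
# metals, exotics) get no implicit hydrogens.
_VALENCES: dict[str, tuple[int, ...]] = {
    "H": (1,),
    "B": (3,),
    "C": (4,),
    "N": (3,),
    "O": (2,),
    "F": (1,),
    "Si": (4,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "Cl": (1,),
    "Ge": (4,),
    "As": (3, 5),
    "Se": (2, 4, 6),
    "Br": (1,),
    "Te": (2, 4, 6),
    "I": (1,),
    "At": (1,),
}

# Mass number of the most abundant isotope, for the subset of elements the
# toolkit reads/writes; used to convert "M  ISO" absolute mass numbers to
# offsets and back.
MOST_ABUNDANT_MASS: dict[str, int] = {
    "H": 1, "He": 4, "Li": 7, "Be": 9, "B": 11, "C": 12, "N": 14, "O": 16,
    "F": 19, "Ne": 20, "Na": 23, "Mg": 24, "Al": 27, "Si": 28, "P": 31,
    "S": 32, "Cl": 35, "Ar": 40, "K": 39, "Ca": 40, "Sc": 45, "Ti": 48,
    "V": 51, "Cr": 52, "Mn": 55, "Fe": 56, "Co": 59, "Ni": 58, "Cu": 63,
    "Zn": 64, "Ga": 69, "Ge": 74, "As": 75, "Se": 80, "Br": 79, "Kr": 84,
    "Rb": 85, "Sr": 88, "Y": 89, "Zr": 90, "Nb": 93, "Mo": 98, "Ru": 102,
    "Rh": 103, "Pd": 106, "Ag": 107, "Cd": 114, "In": 115, "Sn": 120,
    "Sb": 121, "Te": 130, "I": 127, "Xe": 132, "Cs": 133, "Ba": 138,
    "La": 139, "W": 184, "Os": 192, "Ir": 193, "Pt": 195, "Au": 197,
    "Hg": 202, "Tl": 205, "Pb": 208, "Bi": 209, "Th": 232, "U": 238,
}


def is_metal(element: str) -> bool:
    return element in METALS


def allowed_valences(element: str, charge: int = 0) -> tuple[int, ...]:
    """Charge-adjusted allowed valences (ascending, floored at 0).

    Convention: for the electronegative p-block elements (N, O, S, P, Se, As,
    Te) a positive charge adds a bond and a negative charge removes one; for
    C, B, Si and the halogens any charge removes a bond (carbanion and
    carbocation are both trivalent, B(-) is tetravalent via 3 - charge).
    """
    if element in METALS or element not in _VALENCES:
        return (0,)
    base = _VALENCES[element]
    if element in ("N", "O", "S", "P", "Se", "As", "Te"):
        shifted = tuple(v + charge for v in base)
    elif element == "B":
        shifted = tuple(v - charge for v in base)
    elif element in ("C", "Si", "Ge", "H"):
        shifted = tuple(v - abs(charge) for v in base)
    else:  # halogens
        shifted = tuple(v - abs(charge) for v in base)
    out = tuple(sorted({max(0, v) for v in shifted}))
    return out or (0,)


def implicit_hydrogens(element: str, charge: int, bond_order_sum: int) -> int:
    """Implicit H count: smallest allowed valence >= bond sum, minus bond sum.

    If the bond sum exceeds every allowed valence, the atom simply gets no
    implicit H (validation of over-valent atoms happens elsewhere).
    """
    for v in allowed_valences(element, charge):
        if v >= bond_order_sum:
            return v - bond_order_sum
    return 0


def max_valence(element: str, charge: int = 0) -> int:
    return allowed_valences(element, charge)[-1]
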