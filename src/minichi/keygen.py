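"""27-character hashed key for search and indexing.

Anatomy: ``XXXXXXXXXXXXXX-YYYYYYYYSA-N`` — a 14-letter block encoding the
molecular skeleton (formula/connectivity/hydrogen/charge layers), an
8-letter block encoding stereochemistry, isotopes and fixed-H tautomer
detail, a standard flag ("S" for standard options, else "N"), the version
letter "A", and a final proton-balance character ("N" = neutral).

Both blocks are truncated SHA-256 digests re-coded in the A-Z alphabet:
block 1 takes the first 65 bits of the digest of the skeleton substring
(26^14 > 2^65), block 2 the first 37 bits of the digest of the stereo/
isotope substring (26^8 > 2^37).  The bit widths and the direct base-26
big-integer encoding are this tool's own convention; keys are search-safe
but deliberately not byte-compatible with any other implementation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from .layers import LayeredIdentifier

_SKELETON_LAYERS = ("c", "h", "q")
_STEREO_LAYERS = ("b", "t", "m", "s", "i", "f")

PROTON_RANGE = 12


@dataclass(frozen=True)
class HashedKey:
    block1: str  # 14 letters, skeleton
    block2: str  # 8 letters, stereo/isotopes
    flag_char: str  # "S" standard | "N" otherwise
    version_char: str  # "A"
    proton_char: str

    def render(self) -> str:
        return (
            f"{self.block1}-{self.block2}{self.flag_char}"
            f"{self.version_char}-{self.proton_char}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _as_layered(id_or_str) -> LayeredIdentifier:
    if isinstance(id_or_str, LayeredIdentifier):
        return id_or_str
    return LayeredIdentifier.from_string(id_or_str)


def skeleton_substring(identifier) -> str:
    """Formula + connectivity + hydrogen + charge layers — everything the
    first key block hashes; stereo/isotope/fixed-H layers are excluded, so
    stereoisomers share it."""
    lid = _as_layered(identifier)
    parts = [lid.formula]
    for letter in _SKELETON_LAYERS:
        val = lid.get(letter)
        if val:
            parts.append(letter + val)
    return "/".join(parts)


def stereo_substring(identifier) -> str:
    """Stereo/isotope/fixed-H layers hashed into the second block (may be
    empty for achiral, isotope-free structures)."""
    lid = _as_layered(identifier)
    parts = []
    for letter in _STEREO_LAYERS:
        val = lid.get(letter)
        if val:
            parts.append(letter + val)
    return "/".join(parts)


def _hash_letters(text: str, bits: int, letters: int) -> str:
    digest = hashlib.sha256(text.encode("utf-8")).digest()
    value = int.from_bytes(digest, "big") >> (256 - bits)
    out = []
    for _ in range(letters):
        value, r = divmod(value, 26)
        out.append(chr(ord("A") + r))
    return "".join(reversed(out))


def proton_char(p: int) -> str:
    """Proton-balance letter: 0 -> N, +1..+12 -> O..Z, -1..-12 -> M..B;
    beyond +-12 the overflow letter "A" is used."""
    if abs(p) > PROTON_RANGE:
        return "A"
    return chr(ord("N") + p)


def hashed_key(identifier, layered: LayeredIdentifier | None = None) -> HashedKey:
    """Compute the 27-character key of an identifier string."""
    lid = layered if layered is not None else _as_layered(identifier)
    p = int(lid.p_layer) if lid.p_layer else 0
    return HashedKey(
        block1=_hash_letters(skeleton_substring(lid), 65, 14),
        block2=_hash_letters(stereo_substring(lid), 37, 8),
        flag_char="S" if lid.version_tag == "1S" else "N",
        version_char="A",
        proton_char=proton_char(p),
    )


@dataclass
class CollisionReport:
    n_keys: int
    full_collisions: list[tuple[str, list[str]]]
    block1_collisions: list[tuple[str, list[str]]]
    duplicate_identifiers: list[str]

    @property
    def n_full_collisions(self) -> int:
        return len(self.full_collisions)


def collision_scan(keys: list[HashedKey], identifiers: list[str]) -> CollisionReport:
    """Find distinct identifiers sharing a full key or a skeleton block.

    Repeated identical identifiers are reported separately (same preimage,
    not a collision).
    """
    if len(keys) != len(identifiers):
        raise ValueError("keys and identifiers must be parallel lists")
    by_full: dict[str, set[str]] = {}
    by_b1: dict[str, set[str]] = {}
    seen: set[str] = set()
    dups: list[str] = []
    for key, ident in zip(keys, identifiers):
        if ident in seen:
            if ident not in dups:
                dups.append(ident)
            continue
        seen.add(ident)
        by_full.setdefault(key.render(), set()).add(ident)
        # stereoisomers share block1 by design (same preimage); a block1
        # collision means two distinct *skeleton substrings* hash together
        by_b1.setdefault(key.block1, set()).add(skeleton_substring(ident))
    full = [(k, sorted(v)) for k, v in sorted(by_full.items()) if len(v) > 1]
    b1 = [(k, sorted(v)) for k, v in sorted(by_b1.items()) if len(v) > 1]
    return CollisionReport(
        n_keys=len(keys),
        full_collisions=full,
        block1_collisions=b1,
        duplicate_identifiers=dups,
    )
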