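# minichi

A desk-scale, self-contained toolkit for layered chemical-structure
identifiers in the InChI style.  It converts 2D molecular drawings (Molfile
V2000 / SDF) into a canonical, layered identifier string, parses such
strings back into structures, compares identifiers by layer containment,
and derives a fixed-length 27-character hashed key for search and indexing.

It is written for cheminformatics work where a transparent, auditable
identifier pipeline matters more than byte-compatibility with the official
software: teaching, method prototyping, and testing structure-handling code
against a fully specified reference.  Every stage — normalization,
canonical labeling, layer grammar, hashing — is an ordinary Python module
with a documented, deterministic rule set.

## The identifier model

A drawing is first **normalized**: metal–nonmetal bonds are cleaved
heterolytically (salt handling), chargeable O⁻/N⁺H sites are neutralized
with the change recorded as a proton balance *p*, and heteroatoms that can
exchange a hydrogen through 1,3-tautomeric shifts (X–C=Y, X,Y ∈ {N,O,S})
are pooled into mobile-hydrogen groups.

Each component is then **canonically numbered**.  Atoms are partitioned by
invariants (element, degree, ring membership; then charge, H count,
isotope), the partition is refined to equitability, and remaining symmetry
is broken by a branch-and-bound search whose comparison key makes the
result provably equal to the optimum over all *n*! orderings — so a
brute-force oracle can (and in the tests, does) verify it.  Canonical
numbers group elements into contiguous blocks, carbon first, so the
element of atom *k* is recoverable from the formula alone.

The identifier lists its layers in fixed order, each introduced by `/` and
a lowercase letter:

```
InChI=1S / formula /c connectivity /h hydrogens /q charge /p protons
        /b double-bond stereo /t tetrahedral parities /m mirror /s stereo type
        /i isotopes /f fixed-H tautomer detail
```

Less detailed drawings of the same substance produce identifiers whose
layers are a subset of the more detailed one (`minichi diff` reports this).
The hashed key re-codes SHA-256 digests of the skeleton layers (14 letters)
and the stereo/isotope layers (8 letters) in A–Z, followed by a
standard-flag letter, the version letter `A`, and a proton-balance letter
(`N` = neutral).

## Worked example

(−)-menthol, drawn with its three wedge-marked stereocenters:

```
$ minichi gen --key menthol.mol
InChI=1S/C10H20O/c1-7(2)9-5-4-8(3)6-10(9)11/h7-11H,4-6H2,1-3H3/t8+,9-,10+/m0/s1	CMJYLMXMKRZQZU-EDSMFAQUSA-N
```

Reading the string: formula `C10H20O`; `/c` is a spanning-tree walk over
the ten heavy atoms in canonical numbering (branches in parentheses, a
repeated number closes a ring); `/h` places the twenty hydrogens
(`7-11H` = one H on atoms 7–11, `4-6H2`, `1-3H3`); `/t8+,9-,10+` gives the
tetrahedral parities of the three stereocenters, `/m0` says the parity
string did not need global inversion, `/s1` marks absolute stereochemistry.
The key's first block (`CMJYLMXMKRZQZU`) hashes everything before the
stereo layers — the mirror-image drawing shares it but gets a different
second block; the trailing `N` means no protons were added or removed.

Dropping the wedges from the drawing removes only the stereo layers, and
the two identifiers compare as contained:

```
$ minichi diff "InChI=1S/C10H20O/c1-7(2)9-5-4-8(3)6-10(9)11/h7-11H,4-6H2,1-3H3" \
               "InChI=1S/C10H20O/c1-7(2)9-5-4-8(3)6-10(9)11/h7-11H,4-6H2,1-3H3/t8+,9-,10+/m0/s1"
A<B first-differing-layer=t
```

The library API mirrors the CLI:

```python
import minichi

g = minichi.read_molfile(open("menthol.mol").read())
res = minichi.identify(g)           # normalize + canonicalize + emit
res.identifier                      # the string above
minichi.hashed_key(res.layered)     # HashedKey(block1='CMJYLMXMKRZQZU', ...)
back = minichi.parse_identifier(res.identifier, res.aux.to_text())
minichi.graphs_isomorphic(back.graph, g)   # True — lossless with aux
```

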