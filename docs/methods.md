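# Methods

This note documents the rule sets, conventions and numerical choices behind
the identifier pipeline, in enough detail to re-derive any emitted string
by hand.

## Input model and hydrogen convention

Structures are heavy-atom graphs; hydrogen exists only as a per-atom
implicit count.  Explicit H atoms in an input Molfile are folded into the
neighboring heavy atom at read time; explicit H carrying charge or isotope
labels, and H not bonded to a heavy atom (H₂), are rejected rather than
approximated.  Implicit counts come from a fixed valence table — C 4, N 3,
O 2, S 2/4/6 (lowest fitting), P 3/5, B 3, halogens 1, Si/Ge 4, Se/Te
2/4/6, As 3/5, metals 0 — with the usual charge shift (+1 on N gives
valence 4, −1 on O gives 1, any charge on C removes a bond, −1 on B adds
one).  The official algorithm's H-filling rules are not published in the
source we model, so this table is the package's own convention; it is
applied identically at generation, emission and parsing, which is what the
round-trip guarantees rely on.

Structures are capped at 1000 atoms; 1001 raises `SizeLimitError`.
Aromatic (type-4) Molfile bonds are rejected with instructions to supply a
Kekulized drawing: aromaticity perception would add a normalization stage
whose behavior could not be pinned to anything testable.

## Normalization

Standard mode applies three steps per structure, in order:

1. **Metal disconnection.**  Every bond between a metal (fixed list:
   alkali, alkaline-earth, Al, Zn, d-block, heavier p-block metals; B and
   Si count as non-metals) and a non-metal is deleted, charges adjusted as
   for heterolytic cleavage toward the non-metal (+order on the metal,
   −order on the partner).  A connected-metals mode leaves the graph
   untouched.
2. **Proton balance.**  O⁻ sites are protonated unless an adjacent atom is
   positively charged (N-oxides and ylides keep their dipole); N⁺ sites
   with ≥1 H are deprotonated.  Both passes iterate to a fixed point, so a
   zwitterion neutralizes completely and normalization is idempotent.  The
   net count *p* = protons removed − protons added is carried in `/p`; the
   drawn species is the normalized one plus *p* protons.
3. **Mobile-H detection.**  Heteroatoms X, Y ∈ {N, O, S} joined as X–C=Y
   through a single carbon are pooled (union–find over all such triples).
   A pool becomes a mobile-H group only if it spans ≥2 atoms and carries
   ≥1 H or a net charge.  1,4-shifts and longer are deliberately out of
   scope: the oxime/nitroso-type ring tautomer pair therefore keeps two
   distinct identifiers, differing exactly in the h-layer position of the
   mobile proton — the narrowest rule consistent with the behavior the
   design reproduces.

The inverse direction (`apply_protons`, used when rebuilding the drawn
species from an identifier) re-attaches protons at conventioned sites:
deprotonation prefers the most acidic O–H class (carboxylic > enol/phenol
> other), protonation the sp³ N class, ties broken by lowest canonical
number, with endpoints of removed metal bonds taking precedence.  The
synthetic generator draws its ions at the same conventional sites, so the
proton balance is invertible by construction; on arbitrary external input
with several equivalent-class sites the re-placed proton may land on a
different (isomorphism-inequivalent) site — a documented best-effort.

## Canonical numbering

Atoms are first partitioned by the topological invariant (element rank,
degree, ring flag), refined to an equitable partition (cells split by the
multiset of neighbor cell indices; sub-cells keep the parent position,
ordered by signature), then split by (charge, H count, isotope) and
refined again.  Element rank orders carbon first, then other elements
alphabetically, so canonical numbers form contiguous element blocks and
the parser can recover each atom's element from the formula plus position.

Topology-first staging is load-bearing: if charges and H counts entered
the initial partition, two tautomeric or protomeric drawings of one
skeleton could silently renumber their heteroatoms so that "the O with the
H" always received the same number, collapsing distinct drawings onto one
string.  With staged refinement the numbering is fixed by the skeleton and
the H simply appears at a different number.

Remaining non-singleton cells are resolved by branch-and-bound over
orderings consistent with the stable cell order, maximizing the sequence
of positional adjacency rows (row *i* records which earlier positions atom
*i* bonds to, earlier bit more significant).  The comparison key —
(stable-color sequence, adjacency rows) — was chosen over the more obvious
"smallest serialized layer string" because equitable refinement does not
commute with layer-string minimality (on n-pentane the refinement cell
order forces `1-3-5-4-2` though `1-3-4-5-2` is string-smaller); with the
color-prefixed key, the refinement-constrained search provably equals the
exhaustive optimum over all n! orderings, which the test suite checks
directly (exhaustively to n = 6, by 10,000 sampled orderings at n = 7–8).
All orderings achieving the optimal key (color-preserving automorphisms,
up to 1000 retained) are kept; if the molecule has stereocenters, the
ordering whose rendered parity layers are smallest — compared through
their mirror-canonical form so reflected inputs resolve identically — is
used.  A configurable node-expansion cap (default 10⁶) bounds the
worst-case search on pathologically symmetric graphs and raises
`CanonicalizationLimitError` instead of stalling.

Bond orders never enter the invariants or the serialized connectivity:
the identifier is bond-order-free by design, orders influence it only
through H counts and normalization.

## Stereochemistry

A tetrahedral center is an atom with four pairwise-distinct substituent
branches — 4 heavy neighbors in pairwise different refinement cells, or 3
plus one implicit H — carrying at least one wedge drawn *at* the center.
Equitable cells can only merge atoms that invariants cannot separate, so
this test never invents a false center; it may conservatively miss centers
whose branches are locally distinct but globally symmetric, and it does
not read wedges anchored at the neighbor.  Parity is the sign of the
signed volume of the substituents taken in canonical-rank order (phantom H
first, at the center with z opposite the wedged neighbors; wedge up = +1,
down = −1).  Zero volume with wedges present is reported as a stereo
conflict.  Any fixed convention is equally valid here; the tests pin the
self-consistency that matters: a single neighbor transposition or a wedge
flip inverts parity, reflection of the drawing inverts every parity, and
input atom order changes nothing.

Double-bond descriptors cover stereogenic C=C and C=N with a defined
reference substituent (lowest canonical rank) on each end; bonds in rings
smaller than 8 carry none.  The side of each reference substituent is the
sign of a 2D cross product; near-collinear geometry (normalized cross
product below 10⁻⁴) raises `GeometryError` rather than guessing.

The t-layer is rendered in whichever global orientation (as drawn, or all
parities inverted) gives the lexicographically smaller string; `/m`
records the choice (1 = inverted), so enantiomers share their t-layer and
differ in `/m` — and hence in the second key block only.  `/s` encodes
user intent (1 absolute, 2 relative, 3 racemic) taken from the SDF
`STEREO_TYPE` field, never inferred.  A single global mirror flag covers
multi-component structures.

## Layer grammar

Order: formula, `/c`, `/h`, `/q`, `/p`, `/b`, `/t`, `/m`, `/s`, `/i`,
`/f`; empty layers are omitted.  Components sort by their canonical layer
strings; per-component sub-strings join with `;` (runs of identical ones
collapse to `k*s`), formulas with `.` and a count prefix.  The c-layer is
a depth-first spanning-tree walk from canonical atom 1, neighbors in rank
order; at each atom all items but the last are parenthesized, ring
closures are recorded at the revisiting end as the bare repeated number.
The h-layer groups fixed H by count (`1-4,7H`, `5H2`, …, ranges for runs
≥2) and appends mobile groups as `(H3,6,7)` (count, optional charge sign,
member numbers).  `/q` carries per-component net charges, `/p` the global
proton balance, `/i` per-atom mass offsets (`3+1`), `/b` descriptors as
`hi-lo+`/`hi-lo-` (+ = references together), `/t` parities as `8+,9-`.

`/f` holds the fixed-H placement (the h-layer grammar without pooling)
whenever mobile groups exist, in standard mode too.  This is a deliberate
dialect choice: the pooled h-layer shows the tautomer-invariant core —
two drawings of one tautomer pair share every layer before `/f` — while
`/f` keeps the identifier losslessly invertible, so reconstruction
failures are confined to bond-order filling rather than tautomer
ambiguity.

## Parsing and reconstruction

Parsing accepts only this tool's dialect.  Elements come from the formula
plus the element-block convention; bonds from the c-layer; H placement
from `/f` when present, else from the fixed h-layer with pooled mobile H
distributed from the lowest-numbered member.  Net component charges are
placed heuristically (atoms whose degree exceeds the neutral valence are
charged first, then heteroatoms in O, S, N order).  Bond orders are then
reconstructed by exact backtracking: each atom's residual (extra order
needed to make the valence table reproduce its H count) constrains 0/1/2
increments per edge, with interval pruning; no valid assignment raises
`ReconstructionError` carrying the partial graph.  Multiple valid
assignments can exist that are not isomorphic — H counts usually pin the
Kekulé pattern up to isomorphism, but not always — and this residual
ambiguity is the measured ≲0.15% failure rate of aux-free round-trips on
the reference corpus.  With the auxiliary sidecar (numbering map plus the
original bond orders, wedges, coordinates, charges and isotopes, stored in
original numbering) reconstruction is exact by construction; the sidecar
includes bond orders precisely so that the aux route never valence-fills.

## Synthetic corpus

The generator emulates small organic drawings: a random spanning tree over
a weighted palette (C 0.70, N 0.10, O 0.12, S 0.03, F 0.015, Cl 0.015,
Br 0.005, P 0.005), up to two ring-closure bonds (probability 0.30 each),
bond promotion to double/triple bounded by open valences (probability 0.15
at C–C bonds; heteroatom bonds promote with probability 1 − 0.70, the
heteroatom-H keep probability; ≤4 π bonds), one acid/base charge site with
probability 0.05 placed at the conventional site (see proton balance), one
heavy-isotope label with probability 0.02, wedges on perceived
stereocenters with probability 0.25, and zigzag tree-layout coordinates
with small seeded jitter.  The default corpus is 10,000 molecules of 3–30
heavy atoms, fixed seed, byte-reproducible; that size keeps a full
emit-and-reparse sweep around a minute on one CPU, and the acceptance
tests run it at full scale.

What the generator does *not* emulate — multi-component inputs, drawn
salts, exotic valences, macrocyclic stereo bonds, crowded 2D layouts with
overlapping atoms, aromatic (un-Kekulized) input — bounds what green tests
show: round-trip and invariance results transfer to real data only insofar
as real drawings stay within the modeled feature set.  Salt handling,
metal disconnection and the tautomer pair are exercised by hand-encoded
reference structures instead (guanine, monosodium glutamate, (−)-menthol,
and the two pyridinol N-oxide drawings).

## Hashed key

Block 1 is the first 65 bits of SHA-256 of the skeleton substring
(formula/c/h/q layers, slash-joined), encoded base-26 into 14 letters
(26¹⁴ > 2⁶⁵); block 2 is the first 37 bits of the digest of the
stereo/isotope substring (b/t/m/s/i/f; the empty string hashes as itself)
in 8 letters.  Then a standard flag (`S`/`N`), version letter `A`, and the
proton letter: 0 → `N`, +1…+12 → `O`…`Z`, −1…−12 → `M`…`B`, overflow `A`.
The proton balance is deliberately excluded from both hash inputs since it
has its own character.  Bit widths and the big-integer base-26 encoding
are this package's own; keys are not byte-compatible with any other tool,
and at corpus scale (10⁴ structures in a 65+37-bit space) the birthday
bound makes collisions vanishingly unlikely — the collision scanner
nevertheless checks every corpus run and distinguishes true collisions
from repeated identifiers.

## Known limitations

* No aromaticity perception, V3000, query features, Rgroups, polymers or
  3D stereo perception.
* Tautomer scope is 1,3-shifts only; longer-range tautomers keep distinct
  identifiers by design.
* Stereo perception ignores wedges not anchored at the center, and
  partition-based branch equivalence can miss globally symmetric centers;
  no CIP labels, axial chirality or allenes.
* Aux-free reconstruction can mis-place protons or choose a different
  valid Kekulé assignment on inputs outside the generator's conventions.
* Canonicalization of adversarially symmetric graphs (strongly regular
  graphs, say) can hit the expansion cap; chemical graphs at the 1000-atom
  limit are fine.
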