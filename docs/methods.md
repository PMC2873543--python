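# Methods

This note records the models, conventions and numerical choices behind
`rnafrag`, and what the test suite does and does not establish.

## The extended dot-bracket representation

A record holds one or more named strands; base pairs are resolved over the
concatenation of the strands in record order, so pairs may join different
strands. Three extensions to classic dot-bracket notation:

* `-` marks a residue that exists in the molecule (it appears in the declared
  SEQRES sequence, or is implied by a jump in author numbering) but has no
  atoms in the coordinate section. Treating these as first-class positions
  keeps window arithmetic honest: a pattern of length 10 cannot silently slide
  across an unobserved stretch, and only the `?` wildcard may cover one.
* Pseudoknots use bracket tiers in the fixed priority order
  `()` < `[]` < `{}` < `<>`. Tier 0 is a maximum-cardinality non-crossing
  subset of the canonical pairs, computed by an interval dynamic program
  (each position joins at most one canonical pair, so the transition is O(1)
  and the whole assignment O(n²)). Ties in the DP are broken toward taking
  the pair that opens earlier; this is deterministic and keeps hairpin stems
  nested when a pseudoknotted helix of equal size competes (the kissing-loop
  case, where both the two 3-bp stems and the 6-bp loop–loop helix form
  non-crossing subsets of size six). Remaining pairs go greedily, in (i, j)
  order, to the lowest tier where they cross nothing; topologies needing more
  than four tiers are rejected — none arise in practice.
* Sequences use one-letter codes with case semantics: uppercase `A C G U`
  for unmodified ribonucleotides, lowercase for modified or non-RNA analogs
  named after the closest parent nucleoside (`1MA → a`, `PSU → u`, DNA
  `DT → u`, …), and `n` when no parent can be assigned. The mapping uses
  gemmi's residue tables plus a small override list.

Since `>` is both the strand-header marker and the tier-3 closing bracket,
a `>` opens a header only when immediately followed by a name character;
names follow the `strandN` convention, which lets a header and its body be
written without a separator (`>strand1GAcUgAAgAuc`).

## Canonical pair detection

The annotation pipeline needs its own geometric pair detector. A candidate
pair of bases (pre-filtered by a C1′–C1′ k-d-tree query) is canonical when:

* C1′–C1′ distance is 10.4 ± 1.5 Å;
* at least two of the class-specific Watson–Crick-edge donor–acceptor
  heavy-atom distances are below 3.4 Å (A·U: N1–N3, N6–O4; G·C: N1–N3,
  N2–O2, O6–N4; G·U wobble: O6–N3, N1–O2);
* the angle between the least-squares base planes is below 30°;
* each counted contact vector lies within 45° of both base planes.

The last criterion is a deliberate addition: hydrogen bonds between paired
bases are nearly coplanar with them, while polar atoms of *stacked* bases
(vertical separation ≈ 2.8–3.4 Å, parallel planes) can also pass a purely
distance-based test. Requiring in-plane contacts separates edge-to-edge
pairing from stacking without a free parameter tuned to any dataset. The
same rule applies to the noncanonical channel: any two bases with ≥ 2
in-plane polar base-atom contacts < 3.4 Å that do not meet the canonical
criteria are recorded as a noncanonical interaction, which feeds multiplet
extraction.

Modified residues pair by parent nucleoside, so a 2′-O-methylated `g` can
close a canonical pair with `C`. Each base joins at most one canonical pair:
candidates are ranked by mean hydrogen-bond distance (ties toward the
lexicographically smaller (i, j)) and accepted greedily. Wobble G·U counts
as canonical throughout, consistent with standard usage.

## Element decomposition

Stems are maximal runs of stacked pairs (i, j), (i+1, j−1) whose adjacency
does not span a strand break; an isolated pair is a stem of length one, and
a dinucleotide step is each adjacent stacked pair (stem length − 1 steps per
stem). Loop decomposition runs over **tier-0 pairs only**: for each closing
pair, the unpaired segments between it and its direct child pairs form the
loop, classified by segment count (1 hairpin; 2 internal, or bulge when
exactly one segment is empty; ≥ 3 junction, empty segments allowed — they
represent coaxially stacked helices). A strand break inside any segment,
including zero-length ones, blocks the loop: a blunt duplex end is not a
hairpin, while a junction assembled from three separate strands survives
because its breaks fall inside the child helices. Keeping higher tiers out
of loop decomposition means a kissing complex reads as two hairpins plus a
pseudoknotted stem, matching how such queries are written. Missing (`-`)
positions count toward segment lengths — the residues exist even without
coordinates. Multiplets are connected components (≥ 3 bases) of the graph
over all recorded interactions, canonical and noncanonical.

Library statistics sum models, strands, residues and coordinate-less
residues over *all* models per method; element counts are reported both over
all models and over first models only. Percentages are rounded half-up to
two decimals. Every model of a multi-model entry contributes to the
all-models columns, including identical X-ray singletons.

## Search semantics

A hit assigns each query strand a contiguous window on a structure strand.
Windows are pairwise disjoint, ordered consistently with the query's strand
order (strictly increasing global start positions), and two query strands
may map to disjoint windows of one structure strand — required for patterns
whose two halves flank a hairpin on a single chain. Character semantics:

* sequence letters: uppercase A/C/G/U require an unmodified residue of that
  identity; lowercase requires a modified residue of that parent; IUPAC
  ambiguity codes constrain the parent regardless of modification (`N`
  matches anything, including residues of unknown parent); letters never
  match a coordinate-less residue unless the aligned structure character is
  `?` (a hit must be extractable as 3D coordinates; under `?` the identity
  declared in SEQRES is still checked);
* `.` matches a residue with coordinates that is canonically unpaired; with
  the through-space option it also matches residues whose partner lies
  outside the matched fragment, and those external partners are reported
  with a one-base-in-fragment flag;
* a bracket requires the two matched positions to pair canonically *with
  each other*; pattern tiers express topology only, so a `[` is satisfied
  by a canonical pair of any tier in the entry;
* `?` matches any residue — paired (the partner constraint is waived),
  unpaired, or missing. `-` in an entry is matched only by `?`.

With strand shift, the hits of all cyclic rotations of the strand list are
unioned; rotation permutes the strand order and remaps the pair topology
(the bracket characters themselves are not rewritten — only paired-ness
matters to the matcher). Anchors `^`/`$` pin windows to strand termini and
rotate with their strands. Hits with identical residue sets within an
entry/model are reported once, and the hit list is sorted deterministically
by entry, model, first segment and rotation.

The matcher enumerates per-strand candidate windows that pass the local
character checks, backtracks over ordered disjoint assignments, and applies
the assignment-dependent checks (pattern pairs, through-space dots) at the
end. The test suite validates it against a deliberately naive oracle that
enumerates *every* window combination and re-implements the semantics
independently, over every query form the notation supports (sequence-only,
anchored, wildcard, multi-strand, pseudoknot, junction, kissing) and every
advanced-option combination. Unbalanced bracket patterns are grammar errors.

Filters operate at entry level: experimental method, maximum resolution
(entries without a reported resolution pass), deposition-date range, and
exclusion of entries containing modified residues.

## Conformational parameters

All angles are degrees in (−180°, 180°], IUPAC sign convention, computed by
the atan2 torsion formula; the value is invariant under rigid motion and
chain reversal and changes sign under mirror reflection. Atoms missing from
a residue or its neighbours yield absent values (`NA` in TSV output) rather
than errors. η and θ use C4′/P atoms of consecutive residues and are absent
at termini and across coordinate gaps. Sugar pucker follows the
Altona–Sundaralingam convention: P = atan2((ν4+ν1)−(ν3+ν0), 2ν2(sin 36° +
sin 72°)) shifted to [0°, 360°), amplitude ν2/cos P; a planar ring reports
amplitude 0 with no phase.

## The synthetic generator

The generator builds every structure from two primitives:

* **Helical blocks.** Runs of stacked planted pairs become ideal helices with
  exact screw symmetry: twist 32.7°, rise 2.81 Å. Pair frames are constructed
  once per class from the ideal nucleotide geometries of the Chemical
  Component Dictionary bundled with biotite: the second base is placed by
  least squares so the class's edge hydrogen bonds are 2.90 Å and C1′–C1′ is
  10.40 Å, searching both face parities (in the wrong parity the constraints
  cannot be satisfied jointly, which identifies the correct one). Distinct
  blocks of one entry are separated by 70 Å so stems, kissing helices and
  junction arms never interact. Modified residues are substituted by rigid
  superposition of their CCD template onto the parent's base ring.
* **Parked residues.** Unpaired residues sit on a remote line at 10 Å
  spacing, far beyond any detection criterion.

This geometry is self-consistent rather than fiber-diffraction-accurate: the
backbone is not covalently continuous between blocks, sugar puckers are
whatever the CCD templates carry, and only homopolymer helices are exactly
screw-symmetric along a strand (heteropolymer frames differ slightly between
pair classes). Tests therefore compare detection and geometry against the
generator's own construction targets, which is exactly what they are meant
to establish: that annotation recovers planted structure and that the
analysis path is the inverse of the construction path. Passing them does not
certify detection thresholds against experimental coordinate noise, nor the
behaviour of loop geometry in real, compactly folded RNA.

Separate internal-coordinate constructors serve as geometry oracles: a
backbone chain built atom-by-atom (natural-extension placement) from target
α–ζ torsions, and a ribose ring fitted by least squares to target bond
lengths and the five ring torsions of a requested (phase, amplitude). Both
are exact up to floating point, so torsion recovery is tested at 1e−3° and
pucker recovery at 0.5°.

The built-in default library (16 entries) fixes the study conditions:
duplexes of 8/10/12 bp (exact-match and sliding-window search targets), a
wobble-containing duplex, GNRA and UUCG hairpins (the latter a sequence-
constraint negative), a modified-residue hairpin, an anticodon-like modified
single strand, an internal loop, an adenosine bulge, a three-strand
junction, a kissing complex with its unpaired decoy, a duplex with two
injected coordinate gaps, a translated-strand duplex decoy and a random
unstructured strand, spread over X-ray/NMR/EM/other methods with a range of
resolutions and deposition dates to exercise every filter. Sizes are kept at
oracle scale (strands ≤ 26 nt) so brute-force window enumeration stays
instant; nothing in the suite depends on larger instances.

## PDB I/O conventions

Reading and writing delegate to gemmi. One strand = one chain id; chain
breaks are never inferred from distance. Alternate locations keep blank or
`A`. Missing residues come from SEQRES when present — author numbering that
indexes directly into SEQRES takes precedence over sequence-based alignment,
which is ambiguous around repeats — and otherwise from jumps in author
numbering (gap residues get parent `unknown`). Placeholders are inserted
into every model and the operation is idempotent. Written fragments preserve
author chain ids, residue numbers and insertion codes; the full entry id is
carried in TITLE because the HEADER id field truncates to four characters.
Only PDB format is supported; mmCIF is an extension point.

## Limitations

* Non-canonical pairs are detected only as unclassified contacts; there is
  no edge/orientation taxonomy, and no base-pair or base-pair-step parameters
  (twist, rise, propeller, …).
* Torsion-range filters on search hits are not built in; the geometry module
  exposes the values for external filtering.
* The dot-bracket library encodes canonical pairs only as brackets; whether
  deposited libraries of this kind include non-canonical brackets varies by
  producer, and this package takes the canonical-only interpretation.
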