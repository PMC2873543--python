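# rnafrag

Annotation and search of three-dimensional RNA fragments through their
secondary structure.

RNA structural biologists routinely need to find every occurrence of a motif
— a GNRA tetraloop, a kissing complex, a decamer duplex, a three-way junction
— across a corpus of deposited RNA coordinate files, and then pull out the 3D
coordinates and conformational parameters of each occurrence. `rnafrag`
implements that workflow as a library and command-line tool:

* **Extended dot-bracket annotation.** Canonical base pairs (Watson–Crick
  A·U and G·C plus the G·U wobble) are detected geometrically from the atom
  coordinates and rendered as multi-strand dot-bracket strings. The dialect
  extends the classic notation with `-` for residues whose coordinates are
  missing from the file, and with extra bracket tiers `[]`, `{}`, `<>` for
  pseudoknots (tier 0 is a maximum-cardinality nested subset; crossing pairs
  move upward). Residues are coded `A C G U` when unmodified and `a c g u`
  for modified or non-RNA analogs, by closest parent nucleoside (`n` when no
  parent can be assigned).
* **Structural elements.** Each secondary structure is decomposed into
  residues, base pairs, multiplets (triplets and higher, as connected
  components of the base-interaction graph), dinucleotide steps, stems, and
  loops closed by one (hairpin), two (internal loop / bulge) or *n* ≥ 3
  canonical pairs (*n*-way junctions).
* **Fragment search.** Queries use the same strand-header notation, with
  sequence constraints (IUPAC codes; case encodes modification state),
  structure constraints, and wildcards `^` `$` (5'/3' anchors) and `?` (any
  residue: paired, unpaired, or missing). Advanced options search all
  deposited models, admit through-space partners outside the fragment, and
  union the hits of every cyclic rotation of the strand order (strand shift).
  Hits carry original author chain/residue numbering and can be written back
  out as PDB fragments.
* **Conformational parameters.** Backbone torsions α–ζ, glycosidic χ, the
  pseudotorsions η = C4′(n−1)–P(n)–C4′(n)–P(n+1) and
  θ = P(n)–C4′(n)–P(n+1)–C4′(n+1), and Altona–Sundaralingam sugar pucker
  (phase, amplitude).
* **Synthetic structures.** A deterministic generator builds idealized
  duplexes, hairpins, junctions and kissing complexes (with injectable
  coordinate gaps, decoys and modified residues) so the whole pipeline is
  testable without downloading anything.

## Worked example

Generate the built-in synthetic library and annotate its kissing-loop entry:

```sh
$ rnafrag fixtures --out demo --seed 1
$ rnafrag annotate --in demo/KISS.pdb
#= KISS model 1
>A
GCGAGGAGGCCGC
(((.[[[[[[)))
>B
GCGAGCCUCCCGC
(((.]]]]]])))
```

Each strand's 3-bp stem is nested (`(((...)))`, tier 0) and the six
loop–loop pairs between the two hairpin loops cross them, so they are
emitted on the second bracket tier (`[[[[[[` / `]]]]]]`) — the signature of
a kissing complex.

Search the library for GNRA tetraloop hairpins, in every NMR model:

```sh
$ rnafrag search --query '>strand1 NNNGNRANNN(((....)))' --library demo --all-models
entry	model	rotation	segments	pairs
HPGNRA	1	0	A:1-10	1=10[both_in_fragment];2=9[both_in_fragment];3=8[both_in_fragment]
HPGNRA	2	0	A:1-10	1=10[both_in_fragment];2=9[both_in_fragment];3=8[both_in_fragment]
HPGNRA	3	0	A:1-10	1=10[both_in_fragment];2=9[both_in_fragment];3=8[both_in_fragment]
HPMOD	1	0	A:1-10	1=10[both_in_fragment];2=9[both_in_fragment];3=8[both_in_fragment]
```

The three hits on `HPGNRA` are its three NMR models; `HPMOD` matches because
the IUPAC codes `N`/`R` constrain only the parent nucleoside, so its modified
loop adenosine still satisfies the pattern. The UUCG-loop entry does not
match the sequence constraint, and the matched stem pairs are reported with
both bases inside the fragment.

Conformational parameters per residue (`NA` marks angles undefined at
termini):

```sh
$ rnafrag torsions --in demo/DUP08.pdb | head -3
entry	model	chain	residue	alpha	beta	gamma	delta	epsilon	zeta	chi	eta	theta	pucker_phase	pucker_amplitude
DUP08	1	A	1	NA	179.98	176.92	98.33	52.71	-50.98	-153.01	NA	86.00	89.89	41.85
DUP08	1	A	2	55.03	-179.93	176.91	98.35	-25.24	18.69	57.14	-132.85	66.76	89.75	41.77
```

Library-wide statistics (counts per experimental method, with the percentage
of residues lacking coordinates, and element counts over all models vs first
models only):

```sh
$ rnafrag stats --library demo | head -7
method	structures	models	strands	residues	missing	missing_pct
EM	1	1	2	12	0	0.00
NMR	5	7	9	104	0	0.00
X-ray	9	9	18	148	2	1.35
other	1	1	1	11	0	0.00
All	16	18	30	275	2	0.73
```

The same operations are available from Python (`rnafrag.parse_dotbracket`,
`annotate_structure`, `extract_loops`, `parse_query`, `search_library`,
`torsion_table`, …); see the module docstrings and `docs/methods.md`.

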