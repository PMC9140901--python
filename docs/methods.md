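# Methods

`mitoforms` analyses the structural biology of circular plant mitochondrial
genomes: dispersed repeats as recombination substrates, the alternative
genome conformations they mediate, long-read evidence for those
conformations, plastid-derived insertions, and descriptive genome
statistics.  This note records the models, the parameters that matter, the
numerical conventions, and the limits of what the synthetic tests show.

## The conformational model

A plant mitogenome assembled as one circular "master" molecule of length
*L* typically coexists in vivo with recombination products of its dispersed
repeats.  For a repeat pair with copies at `[a1, b1)` and `[a2, b2)`
(0-based, half-open, circular coordinates):

* **Direct pair** (same strand): a crossover between the copies splits the
  master circle into two subgenomic circles, `[a1, a2)` and `[a2, a1)`,
  of sizes `(a2 − a1) mod L` and `L − (a2 − a1) mod L`.  The sizes always
  sum to *L* and each subcircle retains one repeat copy — invariants the
  tests assert exactly.
* **Inverted pair** (one copy is the reverse complement of the other): the
  crossover reverse-complements the block `[a1, b2)`, leaving both copies
  in place and flipping the inter-repeat segment.  Molecule length is
  conserved; base content is conserved in the double-stranded sense
  (A+T and C+G totals), not per reported strand.

`enumerate_conformations` constructs the alternative molecules explicitly
by string surgery and extracts four junction references — each repeat copy
with `flank` bp (default 1000) of context on each side, in master order and
in recombinant order.  Junction references are exact substrings of their
conformation molecules by construction.

## Read classification

Only a read that spans a repeat copy with alignable sequence in *both*
flanks can distinguish conformations; everything else is uninformative.
Classification of one read proceeds as:

1. **Probe**: a ≤250 bp segment from the repeat centre is aligned (infix
   edit alignment) against the read and its reverse complement; reads
   without the repeat are dismissed cheaply.
2. **Locate**: the full repeat copy is aligned infix; the read must contain
   it entirely, within an edit budget implied by `min_identity`.
3. **Anchor**: the `anchor` bp (default 100) immediately upstream and
   downstream of the located copy are compared with the four junctions'
   flank anchors at `min_identity` (default 0.85).  The (upstream,
   downstream) pairing decides the junction; junction labels collected
   across both strands decide the read:
   only-master → `master`, only-alternative → `alternative`, both or
   neither → `uninformative`.

Anchors of 100 bp at 85 % identity are far beyond chance agreement at
long-read error rates while tolerant of ~5–15 % read error.  The
uninformative class absorbs reads contained in the repeat, touching one
flank, or (for near-identical flanks) consistent with both arrangements;
support fractions are computed over informative reads only.

The alignment primitive is pluggable (`backend=` on `ReadClassifier`); the
default is the Myers bit-vector edit-distance engine from `edlib`.  All
junction and anchor logic is independent of the backend.

## Support fractions and the multipartite model

Per repeat: `frac_alt = 100 · n_alt / (n_master + n_alt)`, rounded half-up
to two decimals with exact rational arithmetic (`decimal`), `frac_master`
its complement.  A tally with no informative reads reports `NA`, never
0/0.  Records are ordered by repeat length descending.

A repeat is **recombinationally active** when `frac_alt ≥
activity_threshold` (default 20 %, configurable) — chosen midway between
the ~50 % support seen for highly active repeats and the <4 % seen for
substoichiometric ones.  Each active direct repeat contributes its two
subcircles to the multipartite model independently (pairwise surgery);
active inverted repeats are listed as inversion isomers.  When two active
repeats' copies interleave around the circle, simultaneous recombination
yields products pairwise surgery cannot represent: the model emits the
pairwise products and sets an `ambiguous` flag rather than resolving the
combinatorics.  The model makes no claim about in vivo stoichiometry.

## Repeat detection

**Dispersed repeats** are found by self-comparison with 7-mer seeding
(matching the word size a short-word BLASTn search would use), co-diagonal
seed chaining (gap ≤ 40 bp bridges isolated mismatches; chains shorter
than word+5 bp are discarded as chance), ungapped X-drop extension, and
deterministic (length ≥ 100 bp AND identity ≥ 90 %) filters in place of an
E-value cut-off — E-values depend on corpus-dependent Karlin–Altschul
statistics, while length+identity is reproducible and directly testable.
Extension is ungapped; organelle repeat pairs of interest are near-exact.
Circularity is handled by scanning the doubled sequence and normalising
records onto `[0, L)`; fragment images of wrapped repeats are removed by a
circle-aware containment filter, so only maximal pairs are reported, with
`copy1` before `copy2`, overlapping self-hits suppressed.  At
`min_identity=1.0` the finder is equivalent to an O(n²) exact-substring
brute force (asserted on 5 kb toys); rotation of the circle rotates the
record set (asserted for several offsets).

**SSRs** are maximal perfect runs of primitive 1–6 bp motifs with per-unit
minimum copy numbers 10/5/4/3/3/3 (mono → hexa).  Motifs are reported as
the lexicographic minimum over rotations; records nested in a longer
record are suppressed; N never participates.  The scanner is asserted
equal to an independent regex-based oracle on 100 kb.

**Tandem arrays** are detected by periodicity profiles (`s[i] == s[i+p]`
for each period p ≤ 500), runs bridged across isolated substitutions, then
trimmed to the maximum-scoring window (vectorised Kadane) under the
scoring (+2 match, −7 mismatch, −7 indel) against the array's own majority
consensus; arrays scoring ≥ 50 with ≥ 2 copies are reported.  Detection is
substitution-aware but ungapped, so indel-containing arrays are found only
if their gapless core still scores; the indel penalty therefore never
applies to a reported array.  This is the known gap vs a full
Tandem-Repeats-Finder implementation and is acceptable for the perfect or
near-perfect organellar arrays this package targets.

## Homology and MTPT

Cross-genome shared DNA uses the same seeded gapless engine on both
strands of both (doubled, if circular) molecules.  The **shared-DNA
fraction** is the percentage of each genome covered by the union of its
homologous segments — overlap-merged, so repeated hits never double-count
— against that genome's own length.  **MTPTs** are simply the
mito-vs-plastid homologous segments ≥ 100 bp; totals are computed on
merged mitochondrial intervals.  On planted-transfer genomes, recall of
planted segments at 0 % divergence is 100 %; reported segments may exceed
the planted length by a few bases when flanking bases match by chance
(probability 1/4 per boundary base), which the tests bound explicitly.

## Genome statistics

GC % = 100·(G+C)/(A+C+G+T) with ambiguous bases excluded from the
denominator (all-N is undefined, reported `NA`).  `coding_bp` is the union
of CDS intervals — overlapping or dual-annotated genes are counted once,
so genome fractions cannot exceed 100 %.  Intron count is Σ(exons − 1)
over genes.  Annotation is accepted as GenBank flat files (Biopython) or
GFF3 (gffutils); the two routes are asserted to give identical statistics
for equivalent annotations.  Functional classes (respiratory complexes,
cytochrome-c biogenesis, ribosomal proteins, …) are assigned by gene-name
prefix.

## The synthetic-data generator

The generator emulates the study system: a circular mitogenome of
10^5–4×10^5 bp with i.i.d. background composition at a specified GC
fraction (default 0.4554; no higher-order composition model), planted
direct/inverted repeat pairs (exact copies by construction), and planted
plastid transfers copied verbatim into a companion plastid molecule.
Repeat plant sizes in the test fixtures span ~100 bp to ~5.6 kb and MTPT
plants 115–887 bp, matching the size ranges the analysis must handle.

Reads are sampled uniformly on the molecules of a stated conformation
mixture (subcircles weighted by length), with log-normal lengths —
**median 50 kb, σ = 0.5, truncated at 200 bp and at one full wrap**
(truncated reads are flagged).  The ultralong scale is a deliberate
design: only reads spanning repeat + both anchors are informative, so
resolving a 5 kb repeat with useful statistics requires a read library
whose typical read dwarfs the repeat; back-solving the spanning-read
arithmetic for published per-repeat tallies (tens of spanning reads for a
5.6 kb repeat at ~50× coverage) puts the implied mean read length near
50 kb.  Errors are i.i.d. substitutions and single-base indels (defaults
3 %/1 %/1 %, 5 % total); no homopolymer-specific or quality model.  One
integer seed makes genome and reads byte-reproducible; FASTA, a 1-based
truth TSV and a config echo are written for provenance.

What the generator does **not** emulate — and hence what passing tests do
not establish for real data: non-uniform coverage, chimeric and adapter
artefacts, heteroplasmy gradients, homopolymer-biased errors, diverged
(non-identical) repeat copies, and nuclear insertions of organellar DNA.

## Validation experiments and problem sizes

* Mixture recovery: 200 kb circle, one 5 kb direct repeat, 1000 reads per
  replicate at 5 % error, mixtures w ∈ {0.05, 0.25, 0.5}, 20 seeded
  replicates each; the estimated alternative fraction is required to land
  within ±5 points of 100w in ≥95 % of replicates.  With the ultralong
  length default this yields ~500 informative reads per replicate
  (binomial sd ≈ 2.2 points at w = 0.5).
* Oracle equivalences: SSR vs regex oracle at 100 kb; dispersed finder vs
  O(n²) brute force at 5 kb; junctions vs string surgery on 100 random
  toys.
* End-to-end: a 100 kb fixture with two planted repeat pairs and three
  planted transfers runs the full pipeline twice and compares every output
  byte-for-byte.

These sizes keep the whole suite within a few minutes on one core while
leaving every statistical margin intact.

## Numerical conventions and degenerate inputs

* All report coordinates are 1-based inclusive; BED is 0-based half-open;
  internal arithmetic is 0-based half-open with `mod L` wraparound.
* All percentages are rounded half-up to 2 decimals via `decimal` on exact
  rationals — printed values are reproducible and do not depend on binary
  float representation.
* Degenerate inputs: empty reads are uninformative; zero informative
  tallies report `NA`; overlapping repeat copies are rejected for
  conformation surgery (no well-defined exchange); all-N sequences have
  undefined GC; a zero-length genome is rejected for coverage statistics.
* Determinism: every stochastic component takes an explicit integer seed;
  per-replicate seeds are derived with `numpy.random.SeedSequence`.

## Known limitations

* Ungapped extension: diverged repeats whose alignment requires indels are
  reported as fragmented or shortened segments.
* The tandem detector does not model indel-containing arrays.
* The multipartite model is pairwise: joint stoichiometry across several
  simultaneously active repeats is out of scope, and flagged rather than
  resolved when repeats interleave.
* Classification requires full containment of a repeat copy in the read;
  very long repeats relative to the read length leave few informative
  reads, exactly as in real long-read studies.
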