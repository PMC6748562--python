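# Methods

This note documents the models, conventions and design choices behind
`barcodeaudit`, and what the synthetic benchmarks do and do not show.

## The audit procedure

A specimen enters the pipeline with a morphological identification — a
partial Linnaean lineage over the ranks order, superfamily, family,
subfamily, genus, species — and, when sequencing succeeded, a COI-5P
barcode. The reference library is a set of year-stamped records, each
carrying a sequence, a (possibly partial or interim-only) lineage, a BIN
label and a public flag. Identification against a library *snapshot*
(records deposited by year *y* that a view admits) proceeds in three
steps: exhaustive pairwise matching, top-hit concordance classification,
and aggregation.

### Library views

Two views mirror the access-controlled search options of barcode
reference databases. *SLBR* admits records with a species-level or
interim (BIN) identification and at least 500 bp of sequence, public or
not; *PRBD* admits published records of at least 500 bp regardless of
identification rank. Sequence length counts every non-gap character,
including ambiguous bases. Snapshots are monotone: a record admitted in
year *y* is admitted in every later year, which is what makes
retrospective growth curves well-defined.

### Matching

Pairwise comparison uses a global alignment with free terminal gaps
("overlap" alignment), the standard contract for barcode identification
where a query fragment may cover only part of a full-length reference.
Scoring is match +1, mismatch −1, gap −2 (linear); identity is
matches / aligned columns with terminal-gap columns excluded; IUPAC
ambiguity codes count as a match exactly when their base sets intersect
(conservative toward identification). Comparisons with fewer than
300 bp of aligned overlap are discarded rather than scored, so a ~407 bp
barcode fragment remains identifiable while junk overlaps contribute
nothing. A *hit* requires identity strictly above the threshold
(default 98.0%): a pair at exactly 98.0% is not a hit. Hits are ordered
by identity descending, ties broken by record id ascending, making every
downstream decision deterministic. The dynamic program propagates
(matches, columns) along the optimal path with a fixed diagonal > up >
left tie-break; the kernel is compiled with numba and cross-checked in
the tests against biopython's `PairwiseAligner` configured with the same
scores.

### Concordance categories

Classification looks at the single top hit, in a fixed precedence order:

1. no sequence, or no supra-threshold hit → category 4 (*no match*),
   unless the best sub-threshold hit carries the same name at the
   morphological identification's lowest rank → category 3
   (*sub-threshold same name*);
2. identical species name → category 2 (*concordant*);
3. hit named deeper and consistent at all shared ranks → category 1
   (*DNA gave a lower rank*);
4. hit named higher but consistent → category 2;
5. identical lineage at the same non-species rank → category 2
   (self-comparison of, say, two family-level identifications is
   agreement, not refinement);
6. hit carries only a BIN label → category 3 (*interim*);
7. congeneric sister species → category 3;
8. any rank named on both sides disagreeing → category 5 (*discordant*).

Only ranks named on both sides are ever compared, so missing
intermediate ranks never manufacture disagreement; names are compared
case-insensitively after whitespace normalisation, with no synonym
resolution; subspecific epithets are truncated to the binomen on ingest.
When supra-threshold hits beyond the first conflict with the morphology,
the result keeps category by the top hit but carries the conflicting
lineages as an annotation — the evidence an expert reviewer would want.
Specimens without sequence data form a separate sequencing-failure
bucket and never enter category denominators.

### MOTU (BIN-surrogate) clustering

Sequences are clustered by single linkage on p-distance: two records
share a MOTU when a chain of pairs, each at distance ≤ 0.022, connects
them. The threshold is the conventional BIN seed value and is
configurable; the Markov-refinement stage of the RESL algorithm that
produces official BINs is deliberately not reproduced, and no
equivalence with BOLD BIN pages is claimed. Implementation is a
hierarchical single-linkage cut (scipy); the tests hold it equal to an
independent union-find over the thresholded distance graph. Pairs with
insufficient overlap contribute no edge. Cluster ids are the
lexicographically smallest member id, making the clustering invariant to
input order.

A multi-member cluster is *discordant* when any rank carries two or more
distinct names among its members — a cluster mixing two families is
discordant even if no member has a species name — and *concordant*
otherwise; higher-rank names consistent with deeper ones agree, and
interim-only members impose no constraint. Singletons are excluded from
the concordance denominator. Size summaries report the ≤ 10-record
count with an inclusive bound.

### Reporting arithmetic

Every percentage is `100·n/d` rounded to one decimal, half away from
zero, computed in decimal arithmetic so count pairs reproduce exactly
(85/201 → 42.3, 47/55 → 85.5). Identified fraction = categories
1 + 2 + 3 + 5.

## The synthetic study

The generator draws a moth-like taxonomy (default 10 families × 4
genera × 4 species), evolves a root sequence down the tree under a
one-shot uniform substitution model (each site substitutes with
probability *d* to a uniformly chosen different base): root → family at
4*d*, family → genus at 2*d*, genus → species at *d* with
*d* = interspecific divergence 0.05, and species ancestor → haplotype at
the intraspecific divergence 0.005. Two congeneric ancestors then
differ per site with probability 2d(1−d) + (2/3)d², the closed form the
calibration test checks. There are no indels by default: COI barcodes
are length-conserved, and the choice keeps expectations in closed form.

Defaults are the study conditions the pipeline is built around: 241
intercepted specimens; sequencing fails at rate 0.166; 6.5% of
successful sequences are truncated to 407 bp fragments; morphological
identifications are truncated at a sampled rank (38.3% species-level
mass, most of the rest at family); an 11-year (2009–2019) library
schedule totalling 150 records, front-loaded and nearly flat after
2015, with public fraction 0.35. Species abundance is Zipf(1)-skewed,
shared between library sampling and interceptions: heavy skew is what
produces the high singleton-MOTU fractions seen in real interception
data, and the library/schedule/public-fraction values were chosen so
expected species coverage tracks the identification endpoints reported
for real retrospective audits (≈55% non-public in the first year, ≈79%
non-public and ≈43% public in the final year).

Misidentifications (rate 0.02, applied independently to library records
and specimens) swap the attached name for a **confamilial,
non-congeneric** taxon — a different genus in the same family, or a
different family when the identification is truncated above genus. A
congeneric swap would surface as a sister-species (interim) call rather
than a discordance; cross-genus error is the kind the discordant
category exists to catch, and the choice makes the injected rate
recoverable: with a clean complete library, the category-5 specimens are
exactly the corrupted ones. Every corruption, failure and fragment is
recorded in truth ledgers.

### What the synthetic benchmarks show — and what they don't

Parameter recovery holds by construction *and* is verified: a complete,
correctly identified, species-level public library with misidentification
rate 0 yields 100% categories 1 + 2, and an injected rate *m* = 0.1
returns as a category-5 rate within binomial error at n = 1000 queries.
Growth, monotonicity and view-nesting properties are checked on smaller
seeded scenarios.

What passing these tests does **not** show: fidelity to any real
identification engine (the matcher is a documented local contract, not
BOLD's undisclosed k-mer/HMM pipeline); realistic absolute
identification rates (a 160-species closed world is far easier to cover
than the global fauna, and the sub-threshold same-name rescue is
generous at high ranks, so simulated identified fractions run above
real-world ones); codon structure, coalescent genealogies or geographic
population structure, none of which are modelled.

## Numerical and degenerate-input choices

- Strict `> 98.0` threshold comparison; the 13-mismatches-in-650-bp pair
  sits at exactly 98.0% and is excluded (tested as a boundary case).
- Deterministic tie-breaks everywhere: hit ordering by (identity desc,
  record id asc); alignment-path moves diagonal > up > left; cluster ids
  by smallest member.
- Empty libraries are legal (everything classifies category 4); empty
  sequences and non-IUPAC characters are hard errors; lineages must name
  at least one rank or a BIN label, and a species name requires a genus.
- Interim-only morphological identifications cannot be classified and
  are rejected at ingest.
- Missing-overlap pairs get a sentinel distance of 9.0 in the clustering
  matrix, far above any usable threshold, rather than NaN/inf (keeps the
  scipy linkage numerically clean).
- All simulation randomness flows from one integer seed through named
  `numpy` generator streams (truth / library / queries), so outputs are
  byte-reproducible.

## Problem sizes

The shipped test suite and the acceptance script are sized for a single
CPU: the acceptance run uses the full 241-specimen, 150-record study
(about two minutes, dominated by the ~30k pairwise alignments and the
~350-sequence MOTU clustering); the parameter-recovery checks use a
27-species taxonomy with a 54-record complete library and 1000 queries;
structural property tests use a 12-species, 24-record scenario.

## Known limitations

- Single top-hit classification: no multi-hit consensus, no
  probabilistic assignment, no placement on a tree.
- "Sister species" means congeneric with a different epithet; true
  sister-group topology is not computed.
- No synonym or authority resolution: two valid names for one species
  count as discordant.
- Plain single linkage can chain distinct species through intermediate
  haplotypes where RESL's refinement would split them.
- One record = one sequence; no deduplication of multiple sequences per
  physical specimen.
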