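# Methods

`mitofeatures` re-implements the descriptive analyses routinely reported
for a newly sequenced insect mitochondrial genome: annotation-table
arithmetic, strand-partitioned base composition with AT/GC skews, codon
usage with RSCU under the invertebrate mitochondrial code, constrained
tRNA cloverleaf folding, and structural annotation of the control region.
It ships seeded synthetic-data generators with complete ground truth so
every stage is testable without downloading any deposit. The packaged
reference tables transcribe the published annotation of the
*Suwallia teleckojensis* mitogenome (GenBank MF198253), which also serves
as the default layout for the genome generator.

## Annotation model

A `FeatureTable` is an ordered list of named, stranded, 1-based inclusive
intervals — the layout of a published mitogenome organization table —
with optional anticodon spans and start/stop codons (incomplete stops
written `T-` / `TA-`). All coordinates stay 1-based inclusive internally;
0-based half-open views exist only at I/O boundaries. Junction gaps are
`start(downstream) − end(upstream) − 1` over consecutive rows, so positive
values are intergenic spacers and negative values overlaps. The circular
wrap-around junction (last feature back to the first) is appended as a
flagged record but excluded from the spacer/overlap census, matching how
these counts are conventionally reported. The census carries a note when
the longest spacer sits at the tRNA-Ser(UCN)/ND1 junction, where prose
descriptions sometimes attribute it to the neighbouring junction.

Gene-order comparison is positional over (name, strand) pairs against a
reference arrangement (built-in: the ancestral insect order, i.e. the
*Drosophila*-type arrangement); genes absent from either side are listed,
never dropped. The bicistron check reads the 7-mer shared by a
7-nt-overlapping gene pair in gene sense and matches it against ATGNTAA —
the overlap in which the downstream gene's ATG start and the upstream
gene's TAA stop share bases and the pair is translated as one transcript.

The protein-coding total length and per-codon-position site counts are
coordinate-derived (11,246 bp; 3,748 sites per position for the packaged
table). Published tables sometimes print slightly different totals
(11,244; 3,743); the package reports the coordinate-derived values and
does not attempt to reconcile them.

## Composition and skews

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C), over unambiguous bases
(IUPAC ambiguity codes are counted separately and excluded from
denominators; U folds into T). Undefined denominators yield `None`, not
an exception. Partitions concatenate the selected features **in gene
sense** — minority-strand features are reverse-complemented — the only
convention that reproduces the characteristic positive GC skew of
minority-strand partitions. Codon-position partitions stride every third
base of each coding sequence in gene sense after dropping the incomplete
trailing stop fragment. Report rounding follows the published layout: one
decimal for proportions, two for AT skew, three for GC skew.

When skews are recomputed from proportions already rounded to one
decimal, the result can differ from a skew computed on raw counts by up
to ~0.005; reproduction tests against printed tables therefore compare at
that tolerance rather than demanding printed-rounding equality row by
row.

## Codon usage and RSCU

Amino-acid assignments come from translation table 5 (invertebrate
mitochondrial: AGA/AGG = Ser, UGA = Trp, AUA = Met) via Biopython's codon
tables. Synonymous families group by amino acid, making serine one
8-codon family (UCN + AGN) and leucine one 6-codon family; UAA/UAG form a
2-codon stop family. A switch splits the serine boxes for cross-tool
comparison. RSCU(c) = N(c) · k / Σ_family N with k the family size; a
family with zero total yields null RSCU for all members. Counting
includes every complete codon of every protein-coding gene — start
codons and complete stop codons included, incomplete stop fragments and
codons containing ambiguous bases excluded (the latter tallied). J/N
strand classes follow the feature's strand. Verified arithmetically
against the packaged published table: all 64 codons × 3 strand classes
reproduce at two decimals (e.g. 94 × 8 / 324 = 2.32 for the 8-fold
serine family).

## tRNA cloverleaf folding

Metazoan mitochondrial tRNAs keep a rigid core: a 7-bp acceptor stem, a
5-bp anticodon stem around a 7-nt loop with the anticodon at loop
positions 3–5, and DHU/TΨC stems of 3–5 bp, with the DHU stem absent in
tRNA-Ser(AGN). The fold is a deterministic constrained search, not
free-energy minimization (the published analyses report only arm
geometries and pair classes, never energies): the anticodon anchors the
AC arm, the sequence ends anchor the acceptor stem (3′ tail 0–4 nt), and
all DHU/TΨC geometries within bounds (connectors 0–4/0–3/0–1 nt, loops
3–12 nt, variable loop 2–12 nt) are enumerated. A DHU or TΨC stem
candidate is admissible only with ≤ 1 non-canonical pair. Candidates are
ranked lexicographically by (Watson–Crick pairs, G–U wobble pairs,
−mismatches); ties break toward the smaller DHU connector, then lower
stem start positions, then the remaining geometry tuple — fully
deterministic. If no admissible DHU stem exists the region folds as a
bare loop (`dhu_present = False`), which is how the Ser(AGN) case
emerges. Infeasible anticodon anchorings return a diagnostic
`FoldFailure`, never an exception; sequences outside 60–80 nt violate a
precondition and raise.

Pair classes: {A·U, U·A, G·C, C·G} Watson–Crick; {G·U, U·G} wobble;
everything else a mismatch reported with its base identity. rRNA analysis
is deliberately limited to lengths and pairwise percent identity
(gap-in-one counts as difference, double-gap columns drop): published
rRNA secondary-structure figures are homology-drawn, not computed, so
there is nothing algorithmic to reproduce.

## Control region

* **Poly-N tracts** — maximal single-base runs ≥ 7 nt (threshold
  configurable).
* **Tandem repeats** — a simplified re-implementation of the
  Tandem Repeats Finder idea. For each period p (2–200), distance-p
  self-matches are segmented greedily at ≥ 80 % identity; a segment must
  also pass a binomial significance filter (z ≥ 5 against the 0.25
  random-match background) — without it, a 500-nt random sequence yields
  about one spurious period-2 call. Candidates reduce to their smallest
  sufficient period, then boundaries are re-derived in two steps: the
  maximal-scoring subarray of the match-to-consensus profile (match +1,
  mismatch −2) over the segment widened by three periods per side, then
  an edge walk that crosses a single mismatched base only when the bases
  beyond it continue the consensus phase (two of the next three, or
  exactly the adjacent one — the signature of a single substitution in an
  edge copy). Overlapping calls resolve by aligned-length × identity,
  tolerating overlaps up to 25 % of the shorter call so distinct arrays
  that merely touch are both reported. Consensus is the column-majority
  of the unit stack; copy number is span/period to one decimal.
  Measured operating characteristics under the defaults: false-positive
  rate ~1 % on 500-nt uniform-random sequences (min_copies 3,
  min_identity 0.9); exact span+period recovery on 100 % of 200 clean
  planted arrays; period recovery 100 % and copy number within ±0.3 on
  ~98 % of 200 arrays at 10 % unit divergence.
* **Stem-loops** — a combinatorial hairpin scan replacing thermodynamic
  folding, again because only spans and motifs are reported. Every loop
  placement (3–20 nt) is extended outward pair by pair within a mismatch
  budget (G–U counts as pairing by default); stems trim to close on
  canonical pairs at both ends; maximal non-nested hits are ranked by
  pair count. Flanking motifs: literal TATA within 20 nt upstream of the
  5′ stem, G(A)nT (n ≥ 1) within 20 nt downstream of the 3′ stem, nearest
  hit recorded.
* **Conserved sequence blocks** — per-column identity of an aligned set
  of control regions (highest base frequency over all rows; gaps count in
  the denominator, never as the majority), classed at the 100/75/50 %
  tiers; maximal runs of columns at or above the requested tier with
  length ≥ 15 become CSB1…n in coordinate order. Block calls are
  invariant to taxon order by construction.
* **Segmentation** — leading / repeat array / remainder around the
  top-scoring tandem repeat; with no repeat the whole region is leading.

## Synthetic data and ground truth

All generators consume a single seeded NumPy generator in a fixed order,
so equal seeds give byte-identical output. Ground truth is recorded at
construction time (allocated base counts, emitted codons, planted spans),
not by running the analysis code being tested.

* **Genomes** — the default spec reproduces the packaged annotation's
  coordinates verbatim. Bicistron 7-mers and every PCG's start/stop codon
  are stamped first; features then write in table order into unwritten
  cells, so overlapping neighbours share bases exactly as in a real
  genome while codon-level truth stays exact. Interior codons are drawn
  AT-rich, never in-frame stops. rRNAs realize their composition targets
  by exact largest-remainder allocation plus a seeded shuffle, making
  composition assertions exact rather than statistical. tRNAs embed a
  solved cloverleaf geometry matching the annotated length and anticodon
  position; a tRNA whose span was partially pre-written by a neighbour is
  flagged `clean = False` and excluded from structure-level guarantees.
  Spacer gaps fill with run-capped AT-rich background (no chance poly-N
  tract reaches the reporting threshold).
* **tRNAs** — stems realize the requested per-pair classes; unpaired
  bases are random, except that a stem-less DHU region draws from {A, C}
  only, which cannot form canonical pairs, so no spurious DHU stem is
  admissible. For all-Watson–Crick specs the generator additionally
  verifies that the planted structure is the *unique* optimum of the
  constrained fold, repairing chance alternative stems by mutating one
  free base at a time (a sequence admitting an equal-score alternative
  geometry has no well-defined planted truth).
* **Control regions** — defaults follow the published architecture:
  736-nt leading segment (stem-loop SL1 with a 3′ G(A)nT flank only, a
  9-nt poly-T), a 7-nt unit × 6.7 copies, and a remainder carrying SL2
  (5′ TATA + 3′ G(A)nT) and further poly-A/T/C tracts; the remainder is
  sized so the whole region matches the annotated 1,249 nt (the published
  segment sizes do not themselves sum to the region length). Planted
  elements carry non-pairing guards so their spans are exactly
  recoverable; the repeat array's flanks are phase-broken at the first
  three positions and every third position to 18 nt — a flank that
  quasi-continued the unit's phase would make the planted boundary
  genuinely ambiguous for any detector. The TATA search window upstream
  of a hairpin planted without the motif is scrubbed of chance TATA
  boxes. Repeat units draw with uniform base composition for the same
  boundary-identifiability reason. "x % unit mutation" distributes
  round(x·length) substitutions at most one per unit copy (uniform
  position within the copy): each diverged copy remains recognizable,
  whereas clustered hypermutation of an edge copy would destroy the
  boundary evidence and make the planted copy number unrecoverable in
  principle.
* **CR alignments** — gap-free equal-length rows; planted blocks are
  conserved at their tier (100 % = identical; 75/50 % = the smallest
  majority meeting the tier, dissenters mutated to distinct bases so no
  competing majority arises); background columns keep the reference base
  with the requested probability. No indel evolution or phylogenetic
  substitution model is simulated — passing tests show detector
  correctness on planted structure, not robustness to alignment error or
  realistic sequence evolution.

## Problem sizes

Reproduction checks run on the full packaged tables (38 features, 64
codons × 3 strand classes, 20 composition partitions). Round-trip suites
use 200 seeded replicates per property (cloverleaf recovery; clean and
10 %-diverged repeat arrays; 7-taxon × 900-column alignments with four
planted blocks of 18–54 nt; hairpin + motif recovery), the sizes at which
the binomial uncertainty on a ≥ 95 % recovery criterion is a few seeds.
The acceptance script reports the same quantities at 150–200 replicates.

## Known limitations

* The constrained fold assumes the annotated anticodon position is
  correct; it does not search alternative anticodon placements.
* The repeat finder's boundary resolution is one base only when flanks
  are phase-distinct; in real sequence a flank that happens to continue
  the repeat phase is absorbed into the call (and arguably should be).
* The published tRNA mismatch census (38 non-canonical pairs, 29 of them
  G–U) depends on hand-drawn structures of the deposited sequence and is
  not recomputable from the tables alone; the pair-census machinery is
  validated on planted structures instead.
* CSB calling assumes a trustworthy alignment; producing the alignment is
  out of scope.
* Report-layer rounding follows one published table style; other journals
  round differently.
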