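# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Array detection

Detection is a consensus-extension repeat finder in the style of the
CRISPR Recognition Tool. A window of `search_window` = 8 nt slides over
the sequence; a word whose successive recurrences are spaced within
[spacer_min + repeat_min, spacer_max + repeat_max] = [38, 86] bp seeds a
candidate with ≥ `min_repeats` = 3 instances. Instances are extended
left and right one column at a time while at least
`column_consensus_min` = 0.75 of them agree with the column consensus,
subject to the length bounds (repeats 19–38 bp, spacers 19–48 bp, the
canonical size ranges for these loci). Chains whose implied spacer
violates the bounds are split at the offending junction; instances whose
overall identity to the consensus falls below 0.9 are shed from the ends;
arrays with an interior outlier are discarded. Every emitted array is
asserted against the full contract (strict repeat/spacer alternation,
lengths in bounds, no N inside a repeat).

Two refinements beyond the plain consensus rule:

* **Boundary trimming** (`boundary_consensus_min` = 0.9). With few
  repeat instances the 0.75-consensus extension walks past the true
  repeat boundary by chance (with 4 instances a random spacer column
  reaches 3/4 agreement with probability ≈ 0.2), which shifts every
  spacer boundary and breaks exact-coordinate recovery. After extension,
  outermost columns with agreement below 0.9 are trimmed back. On
  near-identical repeats this pins boundaries exactly; the cost is that a
  mutation in a terminal repeat column of a small array can shave that
  column.
* **Spacer dissimilarity** (`max_spacer_identity` = 0.6). Tandem
  repeats masquerade as arrays at a multiple of their unit length (a
  26-bp unit recurs at 52 bp, inside the spacing window) and their
  "spacers" are then copies of one another, which would sail through the
  spacer-length-regularity validation test. A candidate whose spacers
  have mean pairwise identity above 0.6 (computed over the shorter
  spacer) is rejected. True spacers are mutually unrelated (~0.25
  identity for random sequence), so genuine arrays are unaffected.

Overlapping candidates are resolved deterministically: more repeats,
then longer span, then leftmost. Detection is per-record, so splitting a
multi-FASTA into chunks and concatenating results equals a single pass.

The detector does not model hairpin structure, array orientation, or
leader ends, and makes no attempt to reproduce any specific legacy
tool's output byte-for-byte.

## Validation

A candidate array is *bona fide* under three independent lines of
evidence, with two reporting modes:

| condition | evidence | threshold |
|---|---|---|
| (i) | translated search of the **entire source sequence** vs a Cas protein database | E ≤ 1e−12 |
| (ii) | nucleotide search of the consensus repeat (either orientation) vs a known-repeat database | E ≤ 1e−5, word size 4 |
| (iii) | population standard deviation of spacer lengths | ≤ 2.0 bp |

Conservative mode = (i) ∨ (ii); liberal mode = (i) ∨ (ii) ∨ (iii), so the
conservative spacer set is always a subset of the liberal one. Condition
(i) deliberately searches the whole read/contig rather than a window
around the array, since cas genes flank arrays at variable distance.
The spacer-length SD is the population form (divide by n); a one-spacer
array has SD 0 and therefore passes (iii) — such arrays are flagged
(`single_spacer`) so users can filter them. An empty or missing database
renders its condition false with a warning rather than failing, because
validation must degrade gracefully when references are unavailable.

The repeat positional profile (`repeat_pfm`) summarizes a repeat set as a
4×L count matrix with per-column information content
2 + Σ_b f log₂ f bits. Bona fide repeat sets are strongly conserved
(→ 2 bits/column); random decoys carry ≈ 0 bits. The test suite asserts
a > 1-bit mean separation at n = 50 repeats.

## Homology search and E-value statistics

The search is seed-and-extend: every exact shared word (configurable
size; 7 for spacer-vs-virome, 4 for repeat-vs-repeat-db, 3 for translated
searches) seeds gapped extension. Seeds on nearby diagonals (within 2 ×
word size) of one subject are clustered; for queries ≤ 2000 residues the
whole query is aligned against a window padded by the query length around
the cluster with an affine-gap local aligner (Gotoh, via Biopython's
PairwiseAligner), which guarantees the full Smith–Waterman optimum
whenever the optimal alignment carries a seed word — a property the test
suite verifies against an independent full-matrix oracle on hundreds of
random pairs. Longer queries (whole contigs in translated mode) first run
an ungapped X-drop extension (drop 16) from each seed and only anchors
scoring ≥ 18 are aligned gapped in a ±32-residue window; this is the
classic two-stage filter and bounds work on megabase inputs, at the cost
that heavily gapped weak alignments on very long queries may be scored
from their ungapped anchor only.

Scoring defaults: nucleotide +1/−2 with gap open 2, extend 1 (a gap of
length g costs open + g·extend); protein BLOSUM62 with gap open 11,
extend 1. The statistical parameters are computed, not tabulated: λ is
the positive root of Σ pᵢpⱼ e^(λ sᵢⱼ) = 1 (Brent's method, uniform base
composition for DNA, Robinson–Robinson frequencies for protein) and K
comes from the lattice-case convolution series truncated when a term
falls below 1e−6. For the default schemes these reproduce the published
ungapped values (+1/−2: λ = 1.3327, K = 0.621; BLOSUM62: λ = 0.3176,
K = 0.134). Gapped alignments reuse the ungapped λ and K — a documented
approximation that is adequate for thresholding at the loose cutoffs
this pipeline uses (1e−1 … 1e−12). Numeric E-value parity with any
external search tool is explicitly not promised; thresholds, not
E-values, are the contract. Composition-based statistics, low-complexity
masking and HSP chaining are out of scope.

E-values use m = query length (total translated length across frames in
translated mode) and n = total database residues, so doubling the
database exactly doubles every E-value. Mutually overlapping HSPs on one
(subject, strand) keep only the highest-scoring member; results are
sorted by E-value then subject id and are independent of record insertion
order.

## Target analysis

Virome sequences that themselves carry a liberal-mode bona fide array are
removed before matching (an array-bearing "virome" sequence is likely
cellular contamination, and its array would create spurious self-matches).
Spacers are then searched with word size 7 at E ≤ 0.1 — deliberately
permissive, because spacers are short and viral genes diverge quickly —
keeping the best hit per (spacer, contig). ORFs are called only on
contigs that received a match, in that order, so that spacers spanning
two adjacent genes are still detected. The ORF caller is a transparent
ATG-to-stop scanner (both strands, ≥ 30 aa, stop required): a deliberate,
documented divergence from trained gene callers, justified because ORFs
serve only to assign match coordinates to genes. A match overlapping two
adjacent ORFs by ≥ 1 nt is flagged as spanning; a match overlapping none
is recorded as intergenic.

Spacer→ORF links form a bipartite network summarized by degree
histograms (distinct ORFs per spacer, distinct spacers per ORF), which
satisfy the handshake identity by construction. Geographic separation of
a spacer and its target is the haversine great-circle distance between
their samples' coordinates on a sphere of radius 6371.0088 km (the IUGG
mean Earth radius).

## Annotation enrichment

Each ORF's hits (E ≤ 1e−3) are grouped by function label and the ORF is
assigned the label with the highest **cumulative bit score** (ties:
more hits, then lexicographic). Free-text functions are collapsed into
reporting categories by an ordered, case-insensitive keyword map whose
first match wins; the shipped default covers the fifteen standard
virioplankton categories (terminase, methyltransferase, capsid, tail
fiber before tail, tape-measure before tail, polymerase, recombinase,
portal, ssDNA-binding, helicase, reductase, peptidase,
glyco(syl)transferase, and the generic phage-protein catch-all). The map
is an explicit, editable convention — no canonical grouping exists for
free-text annotations.

Expected counts come from the database-wide background: every database
ORF is sent through the identical annotation pipeline, giving frequencies
f_a (including "no hits"); for n matched ORFs, expected_a = n · f_a, so
expectations conserve the total (Σ expected = n to 1e−6). Fold change is
actual/expected, reported at one decimal rounded half away from zero
(full precision retained in machine output); expected = 0 with actual > 0
is flagged infinite rather than rounded. Under uniform draws from the
database the model is calibrated: fewer than 5% of annotations reach
fold ≥ 2 at n = 500 (asserted in the suite). No significance testing is
attached to fold changes.

## Abundance normalization

Read-level surveys report spacers per Mbp of sequenced reads. Contig-level
surveys report normalized spacer abundance: Σ over spacers of mean
per-base read depth (from SAM alignments or a coverage table), divided by
mapped Gbp — per-spacer depth proxies copy number, and dividing by mapped
gigabases makes samples of different sequencing effort comparable. NSA is
scale-equivariant (doubling depths doubles it; doubling mapped bases
halves it). Correlations with sample metadata use the product-moment
coefficient with a two-sided t test (n − 2 df), reported raw, without
multiple-testing correction.

## Synthetic data and evaluation

`make_genomes` builds uniform-random genomes (seeded) and plants arrays
(given repeat, random spacers of given lengths) and zero-gap tandem-repeat
decoys at recorded, non-overlapping offsets, emitting a truth table of
every planted spacer. `simulate_reads` draws read starts uniformly over
genomes (length-weighted), lengths Normal(450, 50) truncated at 50 bp by
default, either strand, with substitution probability rising linearly
from p₀ at the read start to p₁ at the read end — a deliberate, simple
stand-in for pyrosequencing-style 3′-degrading error profiles; indels are
off by default. Paired mode emits mates at a fixed insert (150 bp /
300 bp insert defaults).

Scoring follows the 100%-identity rule: a predicted spacer is a true
positive iff it equals a planted spacer or its reverse complement;
sensitivity = tp/(tp+fn), precision = tp/(tp+fp). Sub-unit thresholds
(e.g. 0.98 for novelty analyses) use greedy length-descending clustering
with identity measured over the shorter sequence from a global alignment.

The standard benchmark (`benchmark_fixture`) is 10 genomes × 100 kb, 5
planted arrays of 6 repeat units each (spacers 30–36 bp, repeats taken
from the packaged known-repeat database so condition (ii) can fire), and
5 decoy loci (26-bp unit × 6 copies) — a desk-scale stand-in for
multi-million-read simulations; all sizes are parameters. On error-free
contigs the pipeline achieves sensitivity and precision 1.0. On raw
450-bp reads precision sits below 1 even without sequencing error: a
read exposes only ~3 repeat instances, so array boundaries are less
pinned and occasional one-column boundary shifts produce near-miss
spacers — mirroring the general observation that contig-level discovery
is cleaner than read-level discovery. Raising the error ramp degrades
both metrics monotonically (asserted over p₁ ∈ {0, 0.02, 0.05}).

**What the synthetic benchmarks do not show**: uniform-random background
DNA has no genomic repeat structure (IS elements, rRNA operons, satellite
families beyond the planted decoys), spacers are random rather than
protospacer-derived, and the packaged repeat/Cas databases are randomly
generated stand-ins, so perfect benchmark scores bound what real
metagenomes — with real repeat families and divergent cas loci — will
give. Field-scale quantities (tens of thousands of spacers, multi-Gbp
virome searches, geographic distance distributions) are exercised only
through the scaled-down and property-based tests described above.

## Numerical and degenerate-input conventions

All coordinates are 0-based half-open on the forward strand. Degenerate
IUPAC codes other than N are rejected at ingest; N never matches a seed
word, never appears inside a reported repeat, and is excluded from GC
denominators (an all-N sequence has undefined GC). Consensus ties break
by fixed base order A<C<G<T. Translation drops trailing partial codons
and renders stops as `*`; frames with no complete codon are skipped
silently in translated search. λ is solved to a relative tolerance well
below 1e−9; the K series is truncated at 1e−6. SAM input honors @SQ
lines, mapped primary records, and M/=/X/D/I/S CIGAR operations only
(BAM/CRAM and quality-aware processing are out of scope); coverage can
equally be supplied as a plain TSV of per-interval mean depths.
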