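# Methods

## Units of analysis and coordinate conventions

The unit of analysis is the individual exon–exon junction, identified by
its intron: chromosome plus the 1-based positions of the first and last
intronic base, exactly as emitted in the tabular junction output of
spliced aligners (nine whitespace-separated columns: chrom, intron start,
intron end, strand code 0/1/2, motif code 0–6, annotated flag, unique
reads, multi-mapped reads, max overhang). All internal coordinates stay in
this 1-based closed convention; BED exports convert at the boundary
(`bedStart = intron_start − 1`, `bedEnd = intron_end`). Working at
junction resolution rather than transcript resolution makes the analysis
independent of any transcript model and lets unannotated splicing be
interrogated on equal terms with annotated splicing; the cost is that
event types (exon skip, alternative last exon, …) are not distinguished.

Ingest is deliberately permissive: no row is dropped for motif class or
annotation status. "Read coverage" always means the unique-read column;
multi-mapped counts are carried but never thresholded, since only uniquely
mapped reads give unambiguous junction evidence.

The junction *key* is strand-less. Strand for unannotated junctions is
motif-inferred and may be undefined in one strain and defined in another;
keying on coordinates alone lets those observations unify, and strands are
reconciled at merge time (unique non-undefined strand wins; both
orientations observed ⇒ flagged `conflict`, kept).

Motif dialect codes 1/2, 3/4, 5/6 are collapsed to the three biological
motif classes GT/AG, GC/AG, AT/AC (the even codes are the minus-strand
observations of the same motifs); when the strand field is 0 the code's
parity supplies the observed strand.

## Motif classification

For a junction with intron `[s, e]` the donor dinucleotide is the
plus-strand sequence at `[s, s+1]` and the acceptor at `[e−1, e]`. If
(donor, acceptor) is (GT,AG), (GC,AG) or (AT,AC) the junction is that
motif on the plus strand; if the reverse complements, swapped, match the
same set it is that motif on the minus strand; otherwise it is
non-canonical and keeps whatever strand the record carried. Dinucleotides
containing N are non-canonical by definition. Introns shorter than 4 bp
are rejected as degenerate (donor and acceptor would overlap). The plus
orientation wins if both orientations were to match.

## Annotation matching and gene overlap

The annotated-junction database is derived from an Ensembl-dialect GTF:
every transcript with k ≥ 2 exons contributes its k−1 introns
(`upstream exon end + 1` … `downstream exon start − 1`); duplicates across
transcripts collapse. Transcripts with overlapping exons are skipped with
a warning rather than guessed at. Gene intervals are the min/max span of
each gene's exons, indexed in an interval tree.

Annotation match is coordinate-exact and strand-lenient: a
coordinate-exact junction whose motif-inferred strand disagrees with the
annotated strand still counts as annotated (a strand inference should not
demote an exact coordinate match). Gene overlap uses the intron interval
(the only interval the junction record itself defines) against the gene
span, requires ≥ 1 bp of intersection and same-strandedness only when the
junction strand is known, and breaks ties deterministically by longest
overlap then lexicographic gene id.

## Conservation statistics and thresholding modes

For each coverage floor *t* the universe is every junction with coverage
≥ *t* in at least one strain; the summary reports the fraction of the
universe shared by ≥ 2 strains and by all strains. Two readings of
"conserved at ≥ t" are implemented:

* **focal** (default): the floor gates the universe; presence in a strain
  then counts at coverage ≥ 1.
* **per-strain**: a strain counts as carrying the junction only at
  coverage ≥ *t* itself.

The focal reading is the default because it is the one under which the
shared fractions of a landscape dominated by low-coverage singletons rise
monotonically with the floor — the behaviour observed in deep brain
RNA-seq panels (on the default synthetic landscape: 65% → 87% → 88%
shared-by-≥2 at floors 1/3/10). The per-strain reading is necessarily
non-monotone whenever high-coverage strain-private junctions exist,
because the all-strain count decays as *t* grows while those singletons
never leave the universe; it remains available as an option.

## Splicing phylogeny

Strain *i* is represented by row *i* of the sharing matrix (cell (i,j) =
junctions carried by both strains at the chosen floor, diagonal = strain
totals; default floor 1 so that every identified junction contributes).
Pairwise dissimilarity is the Euclidean distance between rows and strains
are merged agglomeratively; average linkage is the default, with complete
and single available since the choice of linkage is not forced by
anything in the data. Strains are processed in lexicographic label order,
which makes tie-breaking and therefore the output deterministic and
input-order invariant. The dendrogram is serialized as newick with
ultrametric branch lengths: a node merged at height *h* sits at depth
*h*/2, so two strains at distance *d* yield `(A:d/2,B:d/2);`.

## The strain-specific splicing protocol

Three filters, applied in order:

1. **Uniqueness** — the junction has coverage ≥ `focal_min` in exactly one
   strain and ≤ `require_absent_reads` unique reads in every other strain.
   The default `require_absent_reads = 0` is the strictest reading of
   "detected in only one strain"; it is configurable because sub-threshold
   tolerance is a defensible alternative.
2. **Coverage floor** — focal coverage ≥ `min_coverage`, default 10. The
   default reflects that junctions supported by ≤ 3 reads validate poorly
   and sit well below the pooled per-record coverage median (~7–8 on the
   default landscape); `coverage_median` is exposed so users can replicate
   that threshold-setting logic on their own data.
3. **Canonical motif** — the motif must be in `canonical_set`, default
   {GT/AG, GC/AG, AT/AC} (not GT/AG alone: the minor canonical classes are
   genuine splice sites). The motif used here is re-derived from the
   genome FASTA, so the filter does not depend on which aligner produced
   the table; `trust_table_motif` switches to the table's own code.

Surviving calls are tiered `high_confidence` and decorated with annotation
status and overlapping gene. High-confidence calls are a subset of
potential calls for every configuration, and call counts are non-increasing
in the coverage floor and in shrinking the canonical set.

## The synthetic landscape generator

The generator emulates the structure of a deep multi-strain junction
survey with exact bookkeeping (every junction's origin, owners, motif,
coverage, annotation and gene are recorded in a ground-truth table):

| parameter | default | rationale |
| --- | --- | --- |
| strains | the 8 founder labels | panel of interest |
| core junctions | 20 000 | present in all strains |
| partially shared junctions | 32 000 | owner subset uniform on sizes 2–7 |
| private junctions / strain | 500 | planted SSS events, coverage floored at 10 |
| noise junctions / strain | Poisson(3000) | low-coverage singleton tail |
| coverage model | Gamma–Poisson, mean 9, dispersion 2 | overdispersed counts, pooled median ~7 |
| noise coverage | 1–3 reads (0.6/0.25/0.15) | artifacts concentrate at minimal support |
| noise non-canonical fraction | 0.5 | roughly half of low-support artifacts fail the motif check |
| annotated fraction of true junctions | 0.5 | about half of an observed landscape is annotated |
| true-junction motif mix | 0.86/0.03/0.01/0.10 | GT/AG-dominated, small minor classes |

The composition is calibrated so that 52 000 of 80 000 distinct junctions
(65%) are shared by ≥ 2 strains, and the 3000:500 noise-to-private ratio
per strain reproduces the roughly two-orders-of-magnitude decline of
strain-private junction counts between coverage floors 1 and 10 that deep
data shows. Coverage uses a shared per-junction expression rate λⱼ ~
Gamma(2, 4.5) with independent Poisson draws per strain — coverage is
correlated across strains the way expression-driven depth is; fully
independent draws would make all-strain conservation at high floors
vanishingly rare. Owner strains always receive coverage ≥ 1, so the
presence matrix is exact ground truth.

Junctions are laid out in disjoint genome slots (no key collisions, no
overlapping splice dinucleotides), and each junction's donor/acceptor
dinucleotides are overwritten in the genome copy with its planted motif
(non-canonical junctions get AA..TT, which matches no canonical pair in
either orientation), so motif classification recovers the planted class
exactly. Half of the true junctions (canonical ones only, so that
annotated ⊆ canonical holds in the synthetic world) are emitted as
two-exon transcripts with 50 bp exons in the GTF. Identical spec + seed
produces byte-identical files.

What the generator deliberately does **not** model: read-level effects
(mismatches, overhang-dependent alignability), shared artifact junctions
across strains, coverage correlation along a gene, chromosome-scale gene
structure, or strain-specific genome divergence from the reference. Tests
passing on this landscape therefore demonstrate correctness of the
bookkeeping, thresholds and statistics — not robustness to alignment
artifacts that correlate across strains, which no junction-table-level
method can resolve.

Consequently the planted-recovery numbers are clean by construction: with
noise capped at 3 reads and collision-free placement, the high-confidence
caller attains recall 1.0 and precision 1.0 on planted canonical private
junctions, and lowering the floor to 3 admits noise-origin calls that the
floor of 10 removes entirely.

## Numerical and formatting choices

Medians follow the usual even-count mean-of-central-values rule.
Percentages in report tables are printed to 2 decimals with half-even
rounding of the decimal representation. Report files carry a provenance
header (package version + a hash of inputs and parameters, no timestamps)
so identical configurations yield byte-identical outputs. Empty conservation
universes report NA rather than raising. All randomness flows from a
single integer seed through `numpy.random.default_rng`.

## Scale and full-data use

The default synthetic landscape (~80 000 distinct junctions, ~330 000
per-strain records) was sized to exercise every statistic with comfortable
margins while a full test run stays in the tens of seconds. The pipeline
itself is linear in the number of junction records and runs unchanged on
real aligner junction tables with the matching genome FASTA and Ensembl
GTF (e.g. an mm9 + Ensembl 66 panel); on full deep-sequencing tables
(~370 000 junctions per strain) memory and time remain modest since all
per-junction state is a few integers.

## Known limitations

* Junction-level only: no event typing, isoform quantification or
  transcript reconstruction.
* Annotation matching is exact-coordinate; near-miss junctions (off by a
  few bases) count as unannotated.
* The phylogeny is a hierarchical clustering of sharing counts, not a
  model-based tree; no bootstrap support is computed.
* Gene overlap considers the intron interval only, not the flanking
  exonic anchors.
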