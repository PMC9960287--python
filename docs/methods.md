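# Methods

This note documents the models, conventions and design choices behind
`viroprof`, in the spirit of a methods section: what is simulated and how,
how profiling and scoring are defined, which defaults matter, and what the
synthetic benchmarks do and do not demonstrate about real data.

## 1. Synthetic metagenomes

### Genomes

Reference genomes are i.i.d. nucleotide sequences with a requested GC
content (host 0.41, bacteria 0.45–0.55, viruses drawn from U(0.35, 0.55)).
Random sequences have essentially no long shared substrings, so
cross-mapping between unrelated synthetic genomes is negligible — which is
exactly what makes the *planted* homology constructs (below) controlled
experiments. Scenario defaults: one host genome (120 kb in the fixture
scenarios; 500 kb in the benchmark run), two bacteria (60 kb / 200 kb), and
five (or twenty) viruses of 10–30 kb. These sizes keep one pipeline run in
the seconds range while leaving every stage with realistic work; they are
roughly 1000× smaller than a mammalian-host library, with the host:virus
read imbalance preserved in spirit (host dominates; viruses are a trace).

### Reads

Paired-end 2×150 nt. For fold coverage `C` over a genome of length `L`,
the simulator emits `round(C·L/(2·150))` pairs (round half away from
zero). Fragments: length ~ Normal(μ=350, σ=35) rounded and clamped to
`[150, L]`; start uniform on `[0, L − insert]`; sequenced strand chosen
uniformly, the second mate reverse-complemented. Linear genomes only — no
wraparound.

The error model is substitution-only with a per-base rate interpolated
linearly from 0.001 at the first position to 0.01 at the last, emulating
the quality decay of Illumina reads; the quality string is
`Q = clamp(round(−10·log10 e), 2, 41)` at each position, so qualities are
consistent with the simulated rate. Empirical short-read quality profiles
(instrument-specific, position×substitution matrices) are deliberately
replaced by this two-parameter model: it is dependency-free, exactly
calibratable (the test suite recovers the planted rate to within 3 binomial
σ over ≥10⁵ bases), and sufficient to exercise identity thresholds
downstream. Indels are omitted; nothing downstream consumes gap structure,
and the mapper is ungapped by design.

Every pair carries a truth record: source genome, taxid, role, fragment
coordinates (0-based half-open), strand. Mates share a pair id with `/1`
and `/2` suffixes. Composition of a multi-genome design interleaves all
pairs with a seeded Fisher–Yates shuffle; all randomness flows from one
seed through `numpy` `SeedSequence` spawning, so identical design + seed
gives byte-identical FASTQ.

### Fault constructs

Four generators create the classical error sources of homology-based virus
calling, each of which one named scenario exercises end-to-end:

- **Endogenous element** (`insert_element`): a viral sequence spliced into
  the host genome and also spiked as its own library; host filtering
  removes its reads → false negative at the preprocessing stage.
- **Shared identical region** (`plant_shared_region`): a copy of one
  genome's region written into another at a chosen identity; at identity
  1.0 the best hit ties exactly and the tie-break resolves away from the
  truth → paired FN/FP at the database-search stage.
- **Chimeric contig** (scenario `chimeric`): a contig concatenating 90% of
  one virus with a slice of another, with both genomes' reads assembled to
  it → the minor partner becomes FN at the assembly stage.
- **Hit-table injections** (`inject_hit_errors`): `decoy_homolog` adds a
  winning high-identity hit to an absent taxon (FP), `drop_query` deletes
  all hits of a query set (FN), `tie_pair` duplicates a best hit onto a
  second taxid at identical score/identity. Injected hits are tagged so the
  audit can recognise them.

## 2. Mapping

`toymap` is a minimizer-seeded, ungapped seed-and-extend mapper. Canonical
k-mers (k=15, the lexicographic minimum of forward and reverse-complement
codes) are hashed with an invertible 64-bit mixing function; within every
window of w=10 consecutive k-mers the smallest hash is kept, ties to the
leftmost position. Query minimizers are matched against the index and
grouped by (subject, relative strand, diagonal); the best-supported
diagonal per subject/strand with ≥3 seeds is extended without gaps over the
full query placement. Identity = matches/columns; score = matches −
mismatches; hits under 80% identity are dropped. Because the simulator
emits no indels, the ungapped diagonal placement is the exact alignment,
and equal planted regions produce exactly equal scores — which is what
makes tie detection deterministic rather than heuristic. Equally scoring
hits on different subjects are all reported; mapping is exactly
reverse-complement symmetric. The 80% identity floor loosely corresponds to
an assembly-to-reference mode tolerating substantial divergence, with slack
for the toy error model.

Hit tables round-trip through PAF (12 mandatory columns plus `ti`/`sc`/`id`
tags) and can also be read from BLAST outfmt-6 with a subject-taxid column,
so output of a real mapper can be substituted for the built-in one.

## 3. Profiling

- **Host filter.** Every mate is mapped against the host-only index; a pair
  is removed when either mate aligns at ≥90% identity over ≥100 bases. The
  removal log is kept for auditing. The filter can be switched off, which
  is the documented remedy when endogenous viral elements are of interest.
- **Assignment.** Contig-first: contigs assigned by best hit; assembled
  reads inherit their contig's taxon; only unassembled reads use read-level
  hits (a read-level hit for an assembled read is ignored and logged). Ties
  on score break by higher identity, then lower taxid — deterministic — and
  set an `ambiguous` flag whenever ≥2 distinct taxids share the winning
  (score, identity).
- **Abundance.** Each read (mates counted separately) is counted once under
  `ancestor_at_rank(taxid, rank)`; `no_rank` nodes are transparent and
  never returned. Reads with no ancestor at the rank fall into an unranked
  bucket excluded from the rows. The table's `total_reads` is the
  library-wide read count entering profiling (post host-filter), so
  unassigned reads dilute percentages but never appear as rows. Whether a
  production pipeline counts pairs or mates, and whether N includes
  host-filtered reads, are internal conventions here (mates; excluded) and
  are not claimed to match any external tool exactly.
- **Percentile pruning.** Rows sorted by descending count (ties: ascending
  taxid); with S the row-sum, a row is kept iff the cumulative count of
  strictly better rows is `< (1 − t/100)·S`. Equivalently: drop the maximal
  suffix of taxa lying entirely within the last t% of binned reads; a taxon
  straddling the boundary is kept (whole taxa are dropped, never partial
  read counts). The comparison is done in integers scaled by 100, so
  integer thresholds are exact. Defaults: t=1 for the virus table, t=5 for
  the bacteria table, each pruned separately with S the subtable row-sum.
  Note that pruning is a *one-shot* operation on a read distribution: it is
  monotone in t and always keeps a prefix of the sorted rows, but applying
  it again to an already pruned table rescales S and can remove further
  rows ({75, 15, 10} at t=20 drops {10}, then {15} on re-application). It
  is therefore defined — and tested, exhaustively against a
  suffix-enumeration oracle — as a single pass.
- **Contig splitting.** Virus-superkingdom contigs are split into
  bacteriophage vs eukaryotic-virus sets by testing whether any family- or
  order-ranked ancestor appears on the phage label list (case-insensitive,
  whitespace-trimmed; a plain-text file of families and orders whose
  members infect exclusively bacteria or archaea, shipped with the package
  and replaceable). Contigs with no hit form the unmapped set.

## 4. Taxonomy

A minimal rooted tree: one TSV with `taxid, parent_taxid, rank, name`, the
root being the single self-parenting row. Loading validates exactly one
root, no dangling parents, no duplicate ids and no cycles. Queries: lineage
walk, nearest-inclusive ancestor at a rank, LCA, superkingdom lookup and
phage labelling. The taxonomy is treated as a fixed snapshot; deprecated or
remapped taxids across database versions are out of scope.

## 5. Evaluation

- **Confusion.** Truth taxids are projected to the evaluated rank and
  de-duplicated; the reported `true_count` is always the projected size
  actually used (projection can collapse several genomes onto one taxon).
  Predictions are pruned (if requested), projected, optionally restricted
  to one superkingdom — virus and bacteria reports share an abundance table
  but are scored separately — and compared as sets. Percentages are rounded
  half-up to one decimal; F1 is computed from counts as `2TP/(2TP+FP+FN)`
  before rounding, which is algebraically the harmonic mean of the
  unrounded precision and recall. Pruning is never applied to the truth;
  truth exclusions are explicit edits by the caller.
- **Read binning.** Per truth genome, recall = |T∩P|/|T| and precision =
  |T∩P|/|P| on read-id sets, where P is the set of reads assigned to the
  genome's rank-level taxon. When several genomes share one taxon, their
  truth reads are pooled for the precision denominator's intersection so a
  multi-assembly species is not spuriously penalised.
- **Horizontal coverage.** Length of the union of half-open intervals over
  the genome; validated against a per-base boolean-array oracle.
- **Error audit.** A fixed cascade attributes each FN to the first matching
  stage: ≥50% of its truth pairs in the host-removal log → `host_filtered`;
  reads co-assembled with a second taxon → `chimeric_assembly`; ambiguous
  best-hit ties → `shared_region_tie`; queries absent from the hit tables →
  `dropped_hits`; present pre-prune but not post-prune →
  `pruned_low_abundance`; else `unexplained`. FPs: winner of an ambiguous
  tie paired with a tie-FN → `shared_region_tie`; injected decoy →
  `decoy_homolog`; else `unexplained`. The order encodes that preprocessing
  failures dominate downstream ones and that causes are mutually exclusive
  per taxon. All stage logs of one run are required inputs; a missing log
  raises naming the stage.

## 6. What the synthetic benchmarks show — and what they don't

Random genomes are far cleaner than real references: no repeat families, no
conserved genes, no shared ancestry between "unrelated" taxa, no database
incompleteness. The clean 20-virus benchmark consequently achieves 100%
species recall with zero false positives at both 5X and 1X virus coverage,
and read binning near 100% — better than any real pipeline on real data.
These runs therefore validate the *machinery* (each stage does exactly what
it claims, ties and faults propagate as predicted, the arithmetic matches
published report formats exactly), not real-world accuracy. Full-scale
benchmark values that depend on real reference genomes and databases —
library composition percentages, assembly-coverage medians, the behaviour
of external tools — are out of scope at desk scale and are deliberately
replaced by the property-based checks (oracle equivalence for pruning and
coverage, calibration of the simulator, audit fidelity on single-fault
fixtures).

## 7. Determinism and numerics

One integer seed drives everything; per-component and per-stage seeds are
spawned from it and kept below 2³¹. Identical spec + seed reproduces
byte-identical FASTQ, reports and checksums. Rounding: half-up via decimal
arithmetic for reported percentages; half-away-from-zero for pair counts;
integer-scaled comparisons for pruning boundaries. Degenerate inputs are
defined: empty hit tables assign `None`; precision/recall/F1 are 0 when
their denominators are 0; t=0 prunes nothing, t=100 prunes everything;
coverage of an empty interval set is 0.

## 8. Known limitations

- Substitution-only error model; no indels, GC bias, duplicates or
  long-read support.
- No assembler: contigs are perfect genome substrings with known read
  membership supplied by the fixture generator; assembly artefacts beyond
  the planted chimera are not modelled.
- Amino-acid/ORF homology search is represented only abstractly, as
  injected hit-table faults.
- The mapper is ungapped and unsuitable for real, indel-containing reads;
  external PAF/BLAST hit tables should be used for real data.
- The taxonomy dialect is a simplification of the NCBI dump format; merged
  and deleted node handling is absent.
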