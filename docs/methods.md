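# Methods

## Problem and model

`novelseq` detects long insertions (≥ 1 kb of sequence absent from the
reference genome) in short-read resequencing data. The underlying model of
the data is simple: an individual's genome equals the reference plus a set
of inserted sequences; reads drawn from inserted sequence cannot align to
the reference end to end, and read pairs straddling an insertion boundary
leave one mate mapped (an *anchor*) and one unmapped. Discovery therefore
proceeds by assembling everything that failed to map and then using
anchors to put the assembled sequence back onto reference coordinates.
The pipeline is haploid in spirit: an assembled contig represents one
haplotype, so heterozygous insertions whose reads are diluted by the
reference allele can be missed, and carrier frequencies are occurrence
frequencies, not allele frequencies.

## Stages and the parameters that matter

All thresholds live in one `PipelineConfig`; defaults are the protocol
values used throughout.

| parameter | default | meaning |
|---|---|---|
| `min_contig_len` | 1000 bp | retain contigs strictly longer than this |
| `end_window` | 500 bp | contig-end window in which reads vote |
| `unambig_window` | 2000 bp | reference window for the unambiguity test |
| `unambig_frac` | 0.95 | fraction of anchors required (strict >) |
| `min_anchor_reads` | 3 | floor on voting anchors per end |
| `end_probe_len` | 200 bp | contig-end probe for exact matching |
| `ref_flank` | 500 bp | flanks added around the candidate region |
| `min_exact_match` | 15 bp | minimum consistent exact match to place |
| `cluster_dist` | 100 bp | single-linkage gap for placement clusters |
| `merge_dist`, `merge_id`, `merge_cov` | 5 kb, 0.98, 0.95 | one-end merge |
| `dedup_id`, `dedup_cov` | 0.98, 0.95 | unplaced all-vs-all dedup |
| `crossref_id`, `crossref_cov` | 0.90, 0.80 | screen vs placed set / other genomes |
| `rare_freq` | 0.05 | rare/common cutoff (rare inclusive) |
| `upstream_len` | 5000 bp | regulator window upstream of a gene |
| `unpaired_fragment` | 300 bp | assumed fragment for both-unmapped pairs |

Coordinates are 0-based half-open everywhere internally; SAM and GFF3 are
converted once at the parser boundary; emitted BED is 0-based half-open.

### Mapping

The built-in mapper exists so the pipeline is self-contained at desk
scale; imported SAM is the production path. It indexes reference 21-mers
(sorted-array index, N-containing k-mers skipped), probes five evenly
spaced seeds per read on both strands, and accepts an end-to-end placement
with at most `floor(0.1 × read_len)` mismatches at a unique best locus.
Ambiguous-best reads map to the lowest (chrom, pos) and are flagged
`multi`, and multi-mapped reads still count as "aligned" for extraction
(no mapping-quality filter). N never matches anything, including another
N. Reads overlapping an insertion boundary by more than the mismatch
budget fail end to end and fall into the unaligned sets — this is what
creates anchor pairs at insertion flanks, mirroring the soft-clipping
behaviour of production aligners. Because there is no clipping, a read
overlapping an insertion by only a handful of bases can still map; the
only consequence is slightly shallower contig flanks.

### Assembly

A deterministic de Bruijn assembler (k = 31, odd so no k-mer is its own
reverse complement). k-mers are counted canonically (a k-mer and its
reverse complement are one unit, so a strand-symmetric read set is not
double-counted) and those seen fewer than 2 times are dropped as errors.
Two error structures survive that floor: dead-end *tips* (clipped when
shorter than 2k), and *bubble branches* that arise when two reads happen
to carry the same substitution error — at 30X and 0.2% error over ~100 kb
of inserted sequence this happens dozens of times, and each bubble would
otherwise fragment its contig below the 1 kb filter. Short attached
unitigs whose mean k-mer coverage is at or below max(2, 25% of the graph's
median) are therefore clipped too, and the graph rebuilt (two rounds).
The 25% ratio separates the error-path regime (counts near the floor)
from genuine short repeat paths (counts near graph coverage) by a wide
margin at any coverage where assembly is sensible. Contigs are the
maximal non-branching paths, emitted once per double-stranded sequence in
canonical orientation and sorted by sequence, so output is independent of
read order. The 300 bp fragment-size hint carried by both-unmapped pairs
is recorded but unused: a de Bruijn graph at this scale does not need
pairing information (a deliberate divergence from pair-aware assemblers).
Contamination screening and repeat masking are injection points
(`contamination_pred`, `mask_fn`), not implementations: both depend on
external databases.

### Alignment engine

Identity/coverage filtering throughout uses an anchor-and-chain local
aligner: maximal exact matches ≥ 15 bp (diagonal-merged k-mer seeds) are
chained by collinear dynamic programming, the chained span — symmetrically
extended up to 100 bp past the outer anchors — is aligned end to end with
edlib, and the resulting path is trimmed to its best-scoring contiguous
window under match +1, mismatch −1, gap open −4, gap extend −1. The trim
(a maximum-subarray pass over per-column scores) reproduces local-alignment
behaviour on the high-identity comparisons all pipeline thresholds target;
the test suite holds it within ±0.5% identity and ±15 bp span of a true
Smith–Waterman oracle on mutated-copy pairs (2% substitutions, up to
2 kb). On unrelated sequence pairs the aligner reports nothing or short
records — it is not a sensitive homology search, and is not meant to be.
Identity is matches / alignment columns (gaps count as columns); coverage
is aligned span / sequence length, per record; `best_combined_coverage`
takes the union of spans. For the symmetric dedup screen, "coverage
≥ 95%" is read as *either* sequence's coverage; for asymmetric screens it
is the screened contig's own coverage.

### Placement

Anchors vote per contig end (a read may vote for both ends of a contig
shorter than twice the end window). The unambiguity test finds the best
2 kb window by a sliding pass over sorted anchor starts and demands
strictly more than 95% of all anchored votes plus at least
`min_anchor_reads` = 3 (with one anchor, 1/1 would trivially pass; the
protocol is silent and a floor prevents spurious placements). Contig
orientation is inferred from the majority of (read-on-contig strand,
anchor strand) pairs — a proper pair faces inward, so opposite strands
imply a forward-oriented contig; ties break to "+". The exact-match
verification then requires the longest common substring between the
200 bp end probe and the region (±500 bp flanks) to lie on the implied
strand, to reach 15 bp, and to come within 10 bp of the probe's outer
extremity — a match floating mid-probe does not define a breakpoint. The
reported insertion point is the reference coordinate at the novel-side
edge of that match; the protocol this reimplements never defines the
reported coordinate, so this convention (and the 1 bp BED point feature)
is this package's choice. Two ends placed concordantly (same chromosome,
within `merge_dist`) collapse to a two-end record at the left end's
coordinate; discordant two-end evidence is kept as two flagged one-end
records rather than an arbitrary pick.

### Clustering, merging, trimming, screening

Single-linkage clustering is per placement group (two-end / left / right)
and chromosome; merge and dedup relations are closed transitively with
union–find (the pairwise wording of the protocol is silent on chains);
the longest contig represents, ties to the smaller id. Trimming aligns a
placed contig to the reference ±10 kb around its placement and removes
only *terminal* aligned segments (within 10 bp of a contig end) — removing
internal matches would fragment the sequence. Contigs trimmed below 50 bp
are dropped with a warning. Trimming is idempotent on clean data: the
surviving core has no reference alignment left. The unplaced screen runs
against the *untrimmed* placed sequences. All-vs-all steps skip sequence
pairs sharing no sampled 31-mer, which keeps them near-linear on
nonredundant sets.

### Presence/absence, frequency, effects

"Present" means some alignment between an individual's raw contigs and a
final sequence at 100% identity covering ≥ 95% of the shorter sequence —
literal full-length identity would fail on ordinary assembler end
trimming, and the criterion is configurable because the upstream
protocol's "annotated as identical" is not fully specified. Frequency
classes generalize the published cohort thresholds as singleton (1),
low (< n/2), high (≥ n/2, < n), fixed (n); at n = 80 these reproduce the
1 / 40 / 80 boundaries exactly, and counts 1..80 partition into class
sizes 1, 38, 40, 1. Rare means frequency ≤ 0.05 inclusive. Upstream
regulator windows are strand-aware ([start−5 kb, start) for "+",
[end, end+5 kb) for "−"; with half-open arithmetic a point exactly 5 kb
before the start is inside); strandless genes are rejected at parse time.
A single insertion may hit several genes and all hits are reported; gene
bodies never suppress upstream calls of other genes.

## The simulator

`SimConfig` defaults define the validation conditions: a 1 Mb i.i.d.
random chromosome at GC 0.36 (typical for walnut-family nuclear genomes),
33 insertions with lengths uniform on [1000, 5000] (the observed placed
insertions in the motivating cohort average ~1.6 kb with a ~4.9 kb
maximum), positions uniform subject to pairwise separation
≥ 2 × fragment mean (800 bp, so anchor evidence of neighbouring
insertions cannot mix), 30X coverage, 150 bp reads, fragments
Normal(400, 50) clamped at the read length, and substitution errors at
0.2% per base. Insertion sequences are re-drawn until none of their
31-mers (either strand) occurs in the reference, making "novel" exact
rather than probabilistic. The simulation is a pure function of the
config including its seed.

What it does not emulate: indel and quality-profile sequencing errors,
PCR duplicates, repetitive or low-complexity genomic context,
heterozygosity, and real insertion sequence content (transposable
elements). Passing the benchmark therefore shows the pipeline's logic is
sound on well-separated unique-sequence insertions in a unique reference
— the regime its thresholds were designed for — not that it is robust to
repeats or heterozygous variation.

## Problem sizes in the shipped tests

The validation replica in the test suite and acceptance script uses the
full 1 Mb / 33-insertion / 30X configuration (≈ 110k read pairs; about a
minute on one CPU). Unit and property tests use 50–200 kb references,
2–10 planted insertions, 100-element clustering instances, and 100
aligner-oracle pairs up to 2 kb. Oracles are independent implementations:
Smith–Waterman via Biopython's `PairwiseAligner`, longest common
substring by dynamic programming, interval unions by per-base marking,
transitive closures by repeated sweeps.

## Known limitations

- The built-in mapper has no clipping, split reads or MAPQ; imported SAM
  from a production aligner is preferred on real data.
- The assembler targets unique inserted sequence; insertions consisting
  largely of high-copy repeats will assemble collapsed or fragmented.
- Placement requires assembled reference flanks on the contig; an
  assembler that trims contigs exactly at the novelty boundary would
  leave nothing for the 15 bp exact match (the built-in assembler keeps
  ~100 bp flanks from boundary-spanning reads).
- One-end placements carry no insertion-length information on the
  reference; two-end placements were not observed to disagree by design
  construction, and discordant evidence is only flagged, not resolved.
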