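# novelseq

Discovery of **long insertions** — sequences of 1 kb and more that are
present in a sequenced individual but absent from the reference genome —
from ordinary short-read resequencing data. Long insertions are a class of
structural variant that standard read-mapping pipelines cannot see: the
reads carrying them simply fail to align. `novelseq` turns exactly those
reads into evidence, for population resequencing cohorts (the design target
is plant cohorts such as walnut-family species sequenced at ~30X with
150 bp paired-end reads) where long-read sequencing of every individual is
not an option.

## Method

The pipeline works in file-mediated stages, each replaceable by an external
tool's output:

1. **Map & extract.** Read pairs are aligned to the reference (built-in
   seed-and-extend mapper, or import a SAM produced by any aligner). Pairs
   with *both* mates unmapped are kept as paired reads; pairs with exactly
   one unmapped mate contribute the unmapped read plus its mate's reference
   position as an *anchor*. Duplicate-flagged pairs are excluded.
2. **Assemble.** All unaligned reads are assembled with a de Bruijn graph
   (k = 31, k-mers seen ≥ 2 times, short error structures clipped); only
   contigs **longer than 1000 bp** are kept. An external assembly can be
   imported instead.
3. **Place.** Unmapped-with-anchor reads are aligned to the contigs. Reads
   landing within 500 bp of a contig end vote with their anchors: if
   **> 95%** of an end's anchors fall inside one **2 kb** window of one
   chromosome ("region unambiguous") and the 200 bp end probe shares a
   consistent exact match of **≥ 15 bases** with that region ± 500 bp
   flanks, the end is placed; the inner edge of the exact match is the
   reported insertion point (a 1 bp BED feature).
4. **Cluster & filter.** Placements within 100 bp collapse to their longest
   contig; representatives within 5 kb merge when alignments reach ≥ 98%
   identity and ≥ 95% coverage; surviving contigs are trimmed of terminal
   reference-aligned sequence. Unplaced contigs are deduplicated
   (≥ 98% / ≥ 95%) and screened against the placed set (≥ 90% / ≥ 80%).
5. **Presence/absence.** Each final sequence is called present in an
   individual when that individual's raw contigs contain it (100% identity
   over ≥ 95% of the shorter sequence), giving a contigs × individuals
   matrix, carrier-frequency classes (singleton / low / high / fixed, with
   rare defined as frequency ≤ 0.05) and cross-species sharing.
6. **Effects.** Placed insertion points are classified against a GFF3
   annotation as gene body, regulator region (5 kb upstream, strand-aware)
   or intergenic.

A built-in simulator generates the ground-truth benchmark the pipeline is
validated on: random insertions planted into a random reference, 30X paired
reads drawn from the resulting haplotype.

## Worked example

Plant 4 insertions (1–5 kb) into a 120 kb random chromosome, simulate 30X
reads at 0.2% error, and rediscover them:

```python
from novelseq import SimConfig, run_validation

report = run_validation(seed=1, sim_cfg=SimConfig(ref_len=120_000,
                                                  n_insertions=4, rng_seed=1))
print(report.n_matched_contigs, report.precision, report.recall)
print(report.mean_truth_coverage, report.placement_errors)
```

which logs the stage progress and prints:

```
[novelseq] mapped 12882 pairs in 4.0s
[novelseq] extracted 829 both-unmapped pairs, 205 unpaired unaligned reads
[novelseq] assembled 4 contigs, 4 pass the > 1000 bp filter
[novelseq] placed 4 contig ends/contigs, 0 unplaced
[novelseq] final: 4 placed, 0 unplaced (5.1s total)
4 1.0 1.0
1.0 {'ins000': 1, 'ins001': 0, 'ins002': 0, 'ins003': 0}
```

All 4 planted insertions are recovered as nonredundant contigs (precision
and recall 1.0), each fully covered (mean truth coverage 1.0), and every
placed insertion point lands within 1 bp of where the insertion was
planted.

The same stages are available from the shell:

```sh
novelseq simulate --ref-len 120000 --n-ins 4 --seed 1 --out-dir sim/
novelseq run-all --simulate --seed 1 --out-dir run/
novelseq extract --ref ref.fa --sam aln.sam --out-dir ex/   # import BWA output
```

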