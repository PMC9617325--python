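"""End-to-end validation experiment: plant insertions, rediscover them.

Replicates the pipeline's ground-truth benchmark at desk scale: random
insertions (default 33, lengths uniform on 1-5 kb) are planted into a
random 1 Mb reference chromosome, ~30X 150 bp paired-end reads are
simulated from the resulting haplotype, and the discovery chain is run.
Assembled nonredundant contigs are matched back to the planted truth at
>= 90% identity / >= 80% truth coverage, and placements are compared with
the true insertion points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .alignment import best_combined_coverage, local_align
from .assembly import NovelContig
from .cluster_filter import dedupe_unplaced
from .core_io import PipelineConfig, ReferenceGenome, SeqRecord
from .pipeline import DiscoveryResult, discover
from .simulate import SimConfig, SimTruth, simulate_experiment


@dataclass
class ValidationReport:
    n_truth: int
    n_contigs: int
    n_nonredundant: int
    n_matched_contigs: int
    n_matched_truths: int
    precision: float
    recall: float
    mean_truth_coverage: float            # fraction of truth covered, mean
    placement_errors: dict[str, int]      # truth id -> |insert_pos - ref_pos|
    placement_recall: float
    n_placed: int
    result: DiscoveryResult = field(repr=False, default=None)
    truth: list[SimTruth] = field(repr=False, default_factory=list)


def _best_truth_match(contig_seq: str, contig_id: str,
                      truth: list[SimTruth], min_id: float,
                      min_cov: float) -> Optional[tuple[str, float]]:
    """Best-matching truth insertion for a contig, with truth coverage."""
    best: Optional[tuple[str, float]] = None
    query = SeqRecord(contig_id, contig_seq)
    for t in truth:
        recs = [r for r in local_align(query, SeqRecord(t.insertion_id,
                                                        t.sequence))
                if r.identity >= min_id]
        if not recs:
            continue
        cov = best_combined_coverage(recs, on="target")
        if cov >= min_cov and (best is None or cov > best[1]):
            best = (t.insertion_id, cov)
    return best


def run_validation(seed: int = 0,
                   sim_cfg: Optional[SimConfig] = None,
                   cfg: Optional[PipelineConfig] = None,
                   match_id: float = 0.90,
                   match_cov: float = 0.80) -> ValidationReport:
    """Run the full planted-insertion benchmark and score it against truth."""
    sim_cfg = sim_cfg or SimConfig(rng_seed=seed)
    cfg = cfg or PipelineConfig(rng_seed=seed)
    ref_rec, truth, hap, reads1, reads2 = simulate_experiment(sim_cfg)
    reference = ReferenceGenome([ref_rec])
    result = discover(reference, reads1, reads2, cfg)

    nonred = dedupe_unplaced(result.contigs, cfg.dedup_id, cfg.dedup_cov)
    matches: dict[str, tuple[str, float]] = {}
    for c in nonred:
        m = _best_truth_match(c.seq, c.contig_id, truth, match_id, match_cov)
        if m is not None:
            matches[c.contig_id] = m
    matched_truths: dict[str, float] = {}
    for tid, cov in matches.values():
        matched_truths[tid] = max(matched_truths.get(tid, 0.0), cov)

    precision = len(matches) / len(nonred) if nonred else 0.0
    recall = len(matched_truths) / len(truth) if truth else 0.0
    mean_cov = (sum(matched_truths.values()) / len(matched_truths)
                if matched_truths else 0.0)

    truth_by_id = {t.insertion_id: t for t in truth}
    placement_errors: dict[str, int] = {}
    for p in result.final_placed:
        m = _best_truth_match(p.seq, p.contig_id, truth, match_id, match_cov)
        if m is None:
            continue
        t = truth_by_id[m[0]]
        err = abs(p.insert_pos - t.ref_pos)
        if m[0] not in placement_errors or err < placement_errors[m[0]]:
            placement_errors[m[0]] = err
    placement_recall = (len(placement_errors) / len(truth)) if truth else 0.0

    return ValidationReport(
        n_truth=len(truth), n_contigs=len(result.contigs),
        n_nonredundant=len(nonred), n_matched_contigs=len(matches),
        n_matched_truths=len(matched_truths), precision=precision,
        recall=recall, mean_truth_coverage=mean_cov,
        placement_errors=placement_errors,
        placement_recall=placement_recall,
        n_placed=len(result.final_placed),
        result=result, truth=truth)
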