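"""Clustering, merging, trimming and redundancy filtering of novel contigs.

Placed contigs at approximately the same insertion point are clustered
(single linkage, gap <= 100 bp) and represented by their longest member;
representatives within 5 kb whose alignments reach >= 98% identity and
>= 95% coverage are merged (transitive closure); surviving contigs are
trimmed of terminal segments that align to the reference around their
placement.  Unplaced contigs are deduplicated all-vs-all at >= 98% identity
/ >= 95% coverage and screened against the placed set at >= 90% / >= 80%.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

from .alignment import local_align
from .assembly import NovelContig
from .core_io import PipelineConfig, ReferenceGenome, SeqRecord, revcomp
from .placement import PlacedContig


class UnionFind:
    def __init__(self, items: Iterable):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self) -> dict:
        comps: dict = {}
        for x in self.parent:
            comps.setdefault(self.find(x), []).append(x)
        return comps


def _longest(group: Sequence, seq_of, id_of):
    return min(group, key=lambda g: (-len(seq_of(g)), id_of(g)))


def cluster_placed(placements: Sequence[PlacedContig],
                   dist: int = 100) -> list[PlacedContig]:
    """Single-linkage clustering of placements; longest contig represents.

    Clustering is per placement group (two-end / left / right) and per
    chromosome; two placements chain when their insertion points differ by
    at most ``dist``.  Ties on length break to the smaller contig_id.
    """
    by_group: dict[tuple[str, str], list[PlacedContig]] = {}
    for p in placements:
        by_group.setdefault((p.side, p.chrom), []).append(p)
    reps: list[PlacedContig] = []
    for key in sorted(by_group):
        members = sorted(by_group[key], key=lambda p: (p.insert_pos, p.contig_id))
        cluster: list[PlacedContig] = []
        for p in members:
            if cluster and p.insert_pos - cluster[-1].insert_pos > dist:
                reps.append(_longest(cluster, lambda g: g.seq,
                                     lambda g: g.contig_id))
                cluster = []
            cluster.append(p)
        if cluster:
            reps.append(_longest(cluster, lambda g: g.seq,
                                 lambda g: g.contig_id))
    reps.sort(key=lambda p: (p.chrom, p.insert_pos, p.contig_id))
    return reps


def _pair_redundant(a_seq: str, b_seq: str, min_id: float, min_cov: float,
                    cov_side: str, min_anchor: int = 15) -> bool:
    """Does any alignment of a vs b reach the identity/coverage thresholds?

    cov_side: "shorter" (coverage of the shorter sequence), "either"
    (coverage of either sequence) or "query" (coverage of a).
    """
    recs = local_align(SeqRecord("a", a_seq), SeqRecord("b", b_seq),
                       min_anchor=min_anchor)
    for r in recs:
        if r.identity < min_id:
            continue
        if cov_side == "shorter":
            cov = r.q_cov if len(a_seq) <= len(b_seq) else r.t_cov
        elif cov_side == "either":
            cov = max(r.q_cov, r.t_cov)
        else:
            cov = r.q_cov
        if cov >= min_cov:
            return True
    return False


def _kmer_profile(seq: str, k: int = 31, step: int = 4) -> set[str]:
    fwd = {seq[i:i + k] for i in range(0, len(seq) - k + 1, step)}
    rc = revcomp(seq)
    return fwd | {rc[i:i + k] for i in range(0, len(rc) - k + 1, step)}


def _shares_kmer(seq: str, profile: set[str], k: int = 31) -> bool:
    return any(seq[i:i + k] in profile for i in range(len(seq) - k + 1))


def merge_one_end(reps: Sequence[PlacedContig], merge_dist: int = 5000,
                  min_id: float = 0.98, min_cov: float = 0.95
                  ) -> list[PlacedContig]:
    """Merge representatives placed within merge_dist whose sequences match.

    A pair merges when some alignment reaches min_id identity and min_cov
    coverage of the shorter contig; the relation is closed transitively and
    the longest contig per merged cluster survives.
    """
    uf = UnionFind(range(len(reps)))
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            a, b = reps[i], reps[j]
            if a.chrom != b.chrom:
                continue
            if abs(a.insert_pos - b.insert_pos) > merge_dist:
                continue
            if uf.find(i) == uf.find(j):
                continue
            if _pair_redundant(a.seq, b.seq, min_id, min_cov, "shorter"):
                uf.union(i, j)
    out = []
    for comp in uf.components().values():
        out.append(_longest([reps[i] for i in comp], lambda g: g.seq,
                            lambda g: g.contig_id))
    out.sort(key=lambda p: (p.chrom, p.insert_pos, p.contig_id))
    return out


def trim_placed(placed: PlacedContig, reference: ReferenceGenome,
                window: int = 10000, min_final_len: int = 50,
                end_tol: int = 10) -> Optional[PlacedContig]:
    """Trim terminal contig segments that align to the reference.

    The contig is aligned to the reference around its placement; merged
    aligned intervals touching a contig end (within end_tol) are removed
    from that end.  Internal aligned segments are left alone — removing
    them would fragment the contig.  Contigs trimmed below min_final_len
    are dropped (returns None).  Idempotent on clean data: the surviving
    novel core has no reference alignment left to trim.
    """
    chrom = placed.chrom
    lo = max(0, placed.insert_pos - window)
    hi = min(reference.length(chrom), placed.insert_pos + window)
    region = reference.fetch(chrom, lo, hi)
    seq = placed.final_seq
    recs = local_align(SeqRecord(placed.contig_id, seq),
                       SeqRecord(chrom, region))
    ivs = sorted((r.q_start, r.q_end) for r in recs)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    start, end = 0, len(seq)
    for s, e in merged:
        if s <= start + end_tol:
            start = max(start, e)
        if e >= end - end_tol:
            end = min(end, s)
    if end - start < min_final_len:
        warnings.warn(
            f"{placed.contig_id}: trimmed to {max(end - start, 0)} bp "
            "(< minimum); dropped")
        return None
    placed.trimmed_seq = seq[start:end]
    return placed


def dedupe_unplaced(unplaced: Sequence[NovelContig], min_id: float = 0.98,
                    min_cov: float = 0.95) -> list[NovelContig]:
    """All-vs-all redundancy removal of unplaced contigs.

    Two contigs are redundant when some alignment reaches min_id identity
    and min_cov coverage of either sequence; within each connected
    component the longest contig remains (ties to the smaller id).  Pairs
    sharing no sampled 31-mer are skipped without alignment.
    """
    n = len(unplaced)
    profiles = [_kmer_profile(c.seq) for c in unplaced]
    uf = UnionFind(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            if not _shares_kmer(unplaced[i].seq, profiles[j]):
                continue
            if _pair_redundant(unplaced[i].seq, unplaced[j].seq,
                               min_id, min_cov, "either"):
                uf.union(i, j)
    out = []
    for comp in uf.components().values():
        out.append(_longest([unplaced[i] for i in comp], lambda g: g.seq,
                            lambda g: g.contig_id))
    out.sort(key=lambda c: c.contig_id)
    return out


def screen_against(set_a: Sequence[NovelContig], set_b: Sequence[SeqRecord],
                   min_id: float = 0.90, min_cov: float = 0.80,
                   mode: str = "remove") -> list[NovelContig]:
    """Screen contigs in set_a for matches in set_b.

    A contig matches when some alignment to a set_b sequence reaches min_id
    identity and min_cov coverage of the contig itself.  mode="remove"
    returns the non-matching contigs (redundancy filtering); mode="report"
    returns the matching ones (cross-genome consistency reporting).
    """
    if mode not in ("remove", "report"):
        raise ValueError("mode must be 'remove' or 'report'")
    profiles = [_kmer_profile(b.seq) for b in set_b]
    out = []
    for a in set_a:
        hit = False
        for b, prof in zip(set_b, profiles):
            if not _shares_kmer(a.seq, prof):
                continue
            if _pair_redundant(a.seq, b.seq, min_id, min_cov, "query"):
                hit = True
                break
        if hit == (mode == "report"):
            out.append(a)
    return out


def finalize_sets(placed: Sequence[PlacedContig],
                  unplaced: Sequence[NovelContig],
                  reference: ReferenceGenome,
                  cfg: Optional[PipelineConfig] = None
                  ) -> tuple[list[PlacedContig], list[NovelContig]]:
    """The whole post-placement stage: cluster, merge, trim, dedupe, screen."""
    cfg = cfg or PipelineConfig()
    reps = cluster_placed(placed, cfg.cluster_dist)
    merged = merge_one_end(reps, cfg.merge_dist, cfg.merge_id, cfg.merge_cov)
    trimmed = [t for p in merged
               if (t := trim_placed(p, reference)) is not None]
    nonred = dedupe_unplaced(unplaced, cfg.dedup_id, cfg.dedup_cov)
    # screening uses the untrimmed placed sequences
    placed_seqs = [SeqRecord(p.contig_id, p.seq) for p in merged]
    final_unplaced = screen_against(nonred, placed_seqs,
                                    cfg.crossref_id, cfg.crossref_cov)
    return trimmed, final_unplaced
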