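"""Anchor contigs to the reference with mate-pair evidence.

The core placement algorithm: unaligned reads whose mates mapped to the
reference are aligned to the assembled contigs; reads landing within 500 bp
of a contig end vote with their mates' reference positions.  If > 95% of an
end's anchor mates fall in one 2 kb window of one chromosome (the
region-unambiguity test, strict inequality) the end is a placement
candidate, verified by requiring a consistent exact match of >= 15 bp
between the 200 bp contig-end probe and the candidate region plus 500 bp
flanks.  The reported insertion point is the reference coordinate at the
novel-side boundary of that exact match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .alignment import longest_consistent_exact_match
from .assembly import NovelContig
from .core_io import (GenomicInterval, PipelineConfig, ReferenceGenome,
                      SeqRecord)
from .mapping import SeedExtendMapper, UnalignedSets


@dataclass
class ContigReadAln:
    read_id: str
    start: int      # on the contig, 0-based
    end: int
    strand: str     # read orientation relative to the contig


@dataclass
class EndEvidence:
    """Anchor-mate votes for one contig end.

    The denominator of the region-unambiguity fraction is the number of
    contributing reads whose mates have a reference anchor; mates without an
    anchor cannot vote for any region.
    """

    contig_id: str
    end: str  # "left" | "right"
    mate_anchors: list[GenomicInterval] = field(default_factory=list)
    read_strands: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return len(self.mate_anchors)

    def majority_orientation(self) -> str:
        """Inferred contig orientation relative to the reference.

        A properly oriented mate pair faces inward, so a read aligned to the
        contig on strand s with an anchor on reference strand t implies
        contig orientation "+" when s != t.  Ties break to "+".
        """
        plus = sum(1 for s, a in zip(self.read_strands, self.mate_anchors)
                   if s != a.strand)
        return "+" if plus * 2 >= len(self.read_strands) else "-"


@dataclass
class PlacedContig:
    contig_id: str
    side: str  # "left" | "right" | "two_end"
    chrom: str
    insert_pos: int
    strand: str
    exact_match_len: int
    support: int
    seq: str = ""
    trimmed_seq: Optional[str] = None
    discordant: bool = False

    @property
    def final_seq(self) -> str:
        return self.trimmed_seq if self.trimmed_seq is not None else self.seq


def align_anchor_reads(contigs: Sequence[NovelContig],
                       unpaired_reads: Sequence[SeqRecord],
                       k: int = 21) -> dict[str, list[ContigReadAln]]:
    """Align unpaired unaligned reads to the contigs; per-contig hit lists."""
    out: dict[str, list[ContigReadAln]] = {c.contig_id: [] for c in contigs}
    if not contigs or not unpaired_reads:
        return out
    mapper = SeedExtendMapper([c.to_seqrecord() for c in contigs], k=k)
    for read in unpaired_reads:
        hit = mapper.map_read(read.seq)
        if hit is not None:
            out[hit.chrom].append(
                ContigReadAln(read.id, hit.pos, hit.pos + len(read.seq),
                              hit.strand))
    return out


def gather_end_evidence(contig: NovelContig,
                        read_alns: Sequence[ContigReadAln],
                        anchors: dict[str, GenomicInterval],
                        end_window: int = 500
                        ) -> tuple[EndEvidence, EndEvidence]:
    """Collect anchor mates of reads aligned within end_window of each end.

    A read may vote for both ends of a short contig.  Only reads whose mate
    has a reference anchor contribute.
    """
    left = EndEvidence(contig.contig_id, "left")
    right = EndEvidence(contig.contig_id, "right")
    clen = contig.length
    for aln in read_alns:
        anchor = anchors.get(aln.read_id)
        if anchor is None:
            continue
        if aln.start < end_window:
            left.mate_anchors.append(anchor)
            left.read_strands.append(aln.strand)
        if aln.end > clen - end_window:
            right.mate_anchors.append(anchor)
            right.read_strands.append(aln.strand)
    return left, right


def region_unambiguous(evidence: EndEvidence, window: int = 2000,
                       frac: float = 0.95, min_reads: int = 3
                       ) -> Optional[GenomicInterval]:
    """The region-unambiguity test for one contig end.

    Finds the chromosome and window (anchor starts spanning <= window bp,
    inclusive) holding the most anchors; the minimal interval spanning those
    anchors is returned iff their count strictly exceeds frac of all anchors
    and reaches min_reads.
    """
    n = evidence.n_total
    if n == 0 or n < min_reads:
        return None
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for a in evidence.mate_anchors:
        by_chrom.setdefault(a.chrom, []).append(a)
    best: Optional[tuple[int, str, list[GenomicInterval]]] = None
    for chrom in sorted(by_chrom):
        anchors = sorted(by_chrom[chrom], key=lambda a: a.start)
        starts = [a.start for a in anchors]
        j = 0
        for i in range(len(anchors)):
            if j < i + 1:
                j = i + 1
            while j < len(anchors) and starts[j] - starts[i] <= window:
                j += 1
            count = j - i
            if best is None or count > best[0]:
                best = (count, chrom, anchors[i:j])
    count, chrom, members = best
    if count <= frac * n:
        return None
    start = min(a.start for a in members)
    end = max(a.end for a in members)
    return GenomicInterval(chrom, start, end)


def verify_and_place(contig: NovelContig, end: str,
                     unambig_region: GenomicInterval,
                     orientation: str,
                     reference: ReferenceGenome,
                     cfg: Optional[PipelineConfig] = None,
                     support: int = 0) -> Optional[PlacedContig]:
    """Exact-match verification of one contig end against its region.

    The 200 bp terminal probe must share an exact run of >=
    cfg.min_exact_match bases with the region (plus 500 bp flanks), on the
    strand the anchor evidence implies, abutting the contig's outer
    extremity (within 10 bp) so that the run's inner edge defines the
    breakpoint.
    """
    cfg = cfg or PipelineConfig()
    probe = (contig.seq[:cfg.end_probe_len] if end == "left"
             else contig.seq[-cfg.end_probe_len:])
    chrom = unambig_region.chrom
    reg_start = max(0, unambig_region.start - cfg.ref_flank)
    reg_end = min(reference.length(chrom), unambig_region.end + cfg.ref_flank)
    if reg_start >= reg_end:
        return None
    region = reference.fetch(chrom, reg_start, reg_end)
    abut = "start" if end == "left" else "end"
    m = longest_consistent_exact_match(probe, region, abut=abut,
                                       strands=(orientation,))
    if m is None or m.length < cfg.min_exact_match:
        return None
    # the exact run is reference flank sequence; its inner (novel-side) edge
    # on the reference is the insertion point
    if (end == "left") == (m.strand == "+"):
        insert_pos = reg_start + m.region_start + m.length
    else:
        insert_pos = reg_start + m.region_start
    insert_pos = min(max(insert_pos, 0), reference.length(chrom) - 1)
    return PlacedContig(contig.contig_id, end, chrom, insert_pos, m.strand,
                        m.length, support, seq=contig.seq)


def classify_sides(left: Optional[PlacedContig], right: Optional[PlacedContig],
                   merge_dist: int = 5000) -> list[PlacedContig]:
    """Combine per-end placements into two-end / one-end / discordant records.

    Concordant two-end evidence (same chromosome, within merge_dist)
    collapses to one record at the left end's coordinate; discordant two-end
    evidence is preserved as two flagged one-end records.
    """
    if left is None and right is None:
        return []
    if left is not None and right is not None:
        if (left.chrom == right.chrom
                and abs(left.insert_pos - right.insert_pos) <= merge_dist):
            combined = PlacedContig(
                left.contig_id, "two_end", left.chrom, left.insert_pos,
                left.strand, max(left.exact_match_len, right.exact_match_len),
                left.support + right.support, seq=left.seq)
            return [combined]
        left.discordant = True
        right.discordant = True
        return [left, right]
    return [left if left is not None else right]


def place_contigs(contigs: Sequence[NovelContig],
                  unaligned: UnalignedSets,
                  reference: ReferenceGenome,
                  cfg: Optional[PipelineConfig] = None
                  ) -> tuple[list[PlacedContig], list[NovelContig]]:
    """Run the full placement stage; returns (placed, unplaced contigs)."""
    cfg = cfg or PipelineConfig()
    read_alns = align_anchor_reads(contigs, unaligned.unpaired_unaligned)
    placed: list[PlacedContig] = []
    unplaced: list[NovelContig] = []
    for contig in contigs:
        ends: dict[str, Optional[PlacedContig]] = {"left": None, "right": None}
        left_ev, right_ev = gather_end_evidence(
            contig, read_alns[contig.contig_id], unaligned.anchor_pairs,
            cfg.end_window)
        for ev in (left_ev, right_ev):
            region = region_unambiguous(ev, cfg.unambig_window,
                                        cfg.unambig_frac, cfg.min_anchor_reads)
            if region is None:
                continue
            ends[ev.end] = verify_and_place(
                contig, ev.end, region, ev.majority_orientation(), reference,
                cfg, support=ev.n_total)
        records = classify_sides(ends["left"], ends["right"], cfg.merge_dist)
        if records:
            placed.extend(records)
        else:
            unplaced.append(contig)
    return placed, unplaced
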