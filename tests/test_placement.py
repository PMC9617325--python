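"""placement: end evidence windows, region unambiguity, exact-match
verification and side classification."""

from __future__ import annotations

import numpy as np
import pytest

from novelseq.assembly import NovelContig
from novelseq.core_io import (GenomicInterval, PipelineConfig,
                              ReferenceGenome, SeqRecord, revcomp)
from novelseq.placement import (ContigReadAln, EndEvidence, PlacedContig,
                                classify_sides, gather_end_evidence,
                                region_unambiguous, verify_and_place)

from conftest import random_seq


def _contig(seq: str, cid="c1") -> NovelContig:
    return NovelContig(cid, seq)


def _aln(rid, start, end, strand="+"):
    return ContigReadAln(rid, start, end, strand)


def _anchor(pos, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, pos, pos + 150, strand)


class TestGatherEndEvidence:
    def setup_method(self):
        self.contig = _contig("A" * 2000)
        self.anchors = {f"r{i}": _anchor(1000 + i) for i in range(10)}

    def test_read_near_left_end_votes_left_only(self):
        left, right = gather_end_evidence(
            self.contig, [_aln("r0", 480, 630)], self.anchors)
        assert left.n_total == 1 and right.n_total == 0

    def test_read_near_right_end_votes_right_only(self):
        left, right = gather_end_evidence(
            self.contig, [_aln("r0", 1500, 1650)], self.anchors)
        assert left.n_total == 0 and right.n_total == 1

    def test_interior_read_votes_neither(self):
        left, right = gather_end_evidence(
            self.contig, [_aln("r0", 700, 850)], self.anchors)
        assert left.n_total == 0 and right.n_total == 0

    def test_short_contig_read_may_vote_both_ends(self):
        short = _contig("A" * 900)
        left, right = gather_end_evidence(
            short, [_aln("r0", 450, 600)], self.anchors)
        assert left.n_total == 1 and right.n_total == 1

    def test_read_without_anchor_does_not_vote(self):
        left, _ = gather_end_evidence(
            self.contig, [_aln("nomate", 10, 160)], self.anchors)
        assert left.n_total == 0


def _evidence(positions, chrom="chr1", strands=None):
    ev = EndEvidence("c1", "left")
    for i, p in enumerate(positions):
        st = strands[i] if strands else "+"
        ev.mate_anchors.append(_anchor(p, chrom=chrom, strand=st))
        ev.read_strands.append("-")
    return ev


def brute_force_best_window(positions, window):
    """Max anchors with starts spanning <= window, by pair enumeration."""
    best = 0
    for p in positions:
        best = max(best, sum(1 for q in positions if p <= q <= p + window))
    return best


class TestRegionUnambiguous:
    def test_all_in_window_unambiguous(self):
        ev = _evidence([5000 + 10 * i for i in range(20)])
        region = region_unambiguous(ev)
        assert region is not None
        assert region.chrom == "chr1"
        assert region.start == 5000

    def test_exactly_95_percent_fails_strict(self):
        # 19/20 = 0.95 exactly: strict > 95% rejects
        ev = _evidence([5000 + 10 * i for i in range(19)] + [900_000])
        assert region_unambiguous(ev) is None

    def test_24_of_25_passes(self):
        ev = _evidence([5000 + 10 * i for i in range(24)] + [900_000])
        assert region_unambiguous(ev) is not None

    def test_split_across_chromosomes_ambiguous(self):
        ev = EndEvidence("c1", "left")
        for i in range(10):
            ev.mate_anchors.append(_anchor(1000 + i, chrom="chr1"))
            ev.read_strands.append("+")
        for i in range(10):
            ev.mate_anchors.append(_anchor(1000 + i, chrom="chr2"))
            ev.read_strands.append("+")
        assert region_unambiguous(ev) is None

    def test_min_reads_floor(self):
        ev = _evidence([100, 110])
        assert region_unambiguous(ev, min_reads=3) is None
        assert region_unambiguous(ev, min_reads=2) is not None

    def test_monotone_in_thresholds(self):
        """Raising min_reads or frac never turns an ambiguous end placed."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(3, 30))
            pos = rng.integers(0, 50_000, size=n).tolist()
            ev = _evidence(pos)
            placed = [region_unambiguous(ev, frac=f, min_reads=m) is not None
                      for f, m in ((0.90, 3), (0.95, 3), (0.95, 5),
                                   (0.99, 5))]
            # once lost, never regained along the tightening sequence
            assert placed == sorted(placed, reverse=True)

    def test_best_window_count_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = int(rng.integers(4, 40))
            pos = sorted(int(p) for p in rng.integers(0, 20_000, size=n))
            ev = _evidence(pos)
            best = brute_force_best_window(pos, 2000)
            region = region_unambiguous(ev, frac=0.0, min_reads=1)
            members = [p for p in pos
                       if region.start <= p and p + 150 <= region.end]
            assert len(members) >= best  # minimal spanning interval covers it

    def test_majority_orientation_vote(self):
        ev = EndEvidence("c1", "left")
        for st_read, st_anchor in (("+", "-"), ("+", "-"), ("-", "-")):
            ev.mate_anchors.append(_anchor(100, strand=st_anchor))
            ev.read_strands.append(st_read)
        assert ev.majority_orientation() == "+"


@pytest.fixture(scope="module")
def planted():
    """A reference and a contig with a known-position novel insertion."""
    rng = np.random.default_rng(77)
    ref_seq = random_seq(rng, 30_000)
    insert_pos = 12_000
    novel = random_seq(rng, 1500)
    # contig carries 120 bp of true flank on each side
    contig_seq = (ref_seq[insert_pos - 120:insert_pos] + novel
                  + ref_seq[insert_pos:insert_pos + 120])
    reference = ReferenceGenome([SeqRecord("chr1", ref_seq)])
    region = GenomicInterval("chr1", insert_pos - 1000, insert_pos + 1000)
    return dict(reference=reference, insert_pos=insert_pos, novel=novel,
                contig=_contig(contig_seq), region=region, rng=rng)


class TestVerifyAndPlace:
    def test_left_end_places_at_truth(self, planted):
        p = verify_and_place(planted["contig"], "left", planted["region"],
                             "+", planted["reference"])
        assert p is not None
        assert abs(p.insert_pos - planted["insert_pos"]) <= 5
        assert p.exact_match_len >= 100

    def test_right_end_places_at_truth(self, planted):
        p = verify_and_place(planted["contig"], "right", planted["region"],
                             "+", planted["reference"])
        assert p is not None
        assert abs(p.insert_pos - planted["insert_pos"]) <= 5

    def test_reverse_oriented_contig_places(self, planted):
        rc = _contig(revcomp(planted["contig"].seq), cid="c1rc")
        p = verify_and_place(rc, "left", planted["region"], "-",
                             planted["reference"])
        assert p is not None
        assert p.strand == "-"
        assert abs(p.insert_pos - planted["insert_pos"]) <= 5

    def test_exact_match_boundary_15_vs_14(self, planted):
        """A contig end sharing exactly 15 bases places; 14 does not."""
        rng = np.random.default_rng(123)
        ref = planted["reference"]
        ip = planted["insert_pos"]
        for flank_len, ok in ((15, True), (14, False)):
            seq = (ref.fetch("chr1", ip - flank_len, ip)
                   + random_seq(rng, 1500))
            c = _contig(seq, cid=f"f{flank_len}")
            p = verify_and_place(c, "left", planted["region"], "+", ref)
            if ok:
                assert p is not None and p.exact_match_len == 15
                assert p.insert_pos == ip
            else:
                assert p is None

    def test_unrelated_contig_not_placed(self, planted):
        rng = planted["rng"]
        c = _contig(random_seq(rng, 1500), cid="junk")
        assert verify_and_place(c, "left", planted["region"], "+",
                                planted["reference"]) is None


class TestClassifySides:
    def _placed(self, side, chrom="chr1", pos=100, cid="c1"):
        return PlacedContig(cid, side, chrom, pos, "+", 20, 5, seq="A" * 10)

    def test_left_only(self):
        (p,) = classify_sides(self._placed("left"), None)
        assert p.side == "left"

    def test_concordant_two_end(self):
        out = classify_sides(self._placed("left", pos=100),
                             self._placed("right", pos=400))
        assert len(out) == 1 and out[0].side == "two_end"
        assert out[0].support == 10

    def test_discordant_chromosomes_two_flagged_records(self):
        out = classify_sides(self._placed("left", chrom="chr1"),
                             self._placed("right", chrom="chr2"))
        assert len(out) == 2
        assert all(p.discordant for p in out)
        assert {p.side for p in out} == {"left", "right"}

    def test_discordant_distance(self):
        out = classify_sides(self._placed("left", pos=100),
                             self._placed("right", pos=50_000))
        assert len(out) == 2 and all(p.discordant for p in out)

    def test_none(self):
        assert classify_sides(None, None) == []
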