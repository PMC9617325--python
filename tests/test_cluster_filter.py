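"""cluster_filter: single-linkage clustering, sequence merging, trimming
and redundancy screens, each against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from novelseq.assembly import NovelContig
from novelseq.cluster_filter import (cluster_placed, dedupe_unplaced,
                                     merge_one_end, screen_against,
                                     trim_placed)
from novelseq.core_io import ReferenceGenome, SeqRecord
from novelseq.placement import PlacedContig

from conftest import mutate, random_seq


def _placed(cid, pos, seq, chrom="chr1", side="left"):
    return PlacedContig(cid, side, chrom, pos, "+", 20, 5, seq=seq)


def brute_force_components(n, related) -> list[set]:
    """Transitive closure by repeated sweeps over the pair relation."""
    comp = [{i} for i in range(n)]
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                ci = next(c for c in comp if i in c)
                cj = next(c for c in comp if j in c)
                if ci is not cj and related(i, j):
                    ci |= cj
                    comp.remove(cj)
                    changed = True
    return comp


class TestClusterPlaced:
    def test_gap_rule(self):
        ps = [_placed("a", 100, "A" * 10), _placed("b", 150, "A" * 10),
              _placed("c", 400, "A" * 10)]
        reps = cluster_placed(ps, dist=100)
        assert len(reps) == 2

    def test_chained_positions_one_cluster(self):
        ps = [_placed("a", 100, "A" * 10), _placed("b", 200, "A" * 10),
              _placed("c", 300, "A" * 10)]
        assert len(cluster_placed(ps, dist=100)) == 1

    def test_longest_represents(self):
        ps = [_placed("a", 100, "A" * 1200), _placed("b", 150, "A" * 1500)]
        (rep,) = cluster_placed(ps, dist=100)
        assert rep.contig_id == "b"

    def test_length_tie_breaks_to_smaller_id(self):
        ps = [_placed("b", 100, "A" * 10), _placed("a", 120, "A" * 10)]
        (rep,) = cluster_placed(ps, dist=100)
        assert rep.contig_id == "a"

    def test_groups_and_chromosomes_separate(self):
        ps = [_placed("a", 100, "A" * 10, side="left"),
              _placed("b", 120, "A" * 10, side="right"),
              _placed("c", 100, "A" * 10, chrom="chr2")]
        assert len(cluster_placed(ps, dist=100)) == 3

    def test_matches_transitive_closure_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 60))
            pos = sorted(int(p) for p in rng.integers(0, 5000, size=n))
            ps = [_placed(f"c{i:03d}", p, "A" * int(rng.integers(5, 50)))
                  for i, p in enumerate(pos)]
            reps = cluster_placed(ps, dist=100)
            comps = brute_force_components(
                n, lambda i, j: abs(pos[i] - pos[j]) <= 100)
            assert len(reps) == len(comps)


class TestMergeOneEnd:
    def _pair(self, rng, sub_rate, pos_b=3000, chrom_b="chr1", trunc=0):
        src = random_seq(rng, 2000)
        a = _placed("a", 0, src)
        b_seq = mutate(rng, src, sub_rate)
        if trunc:
            b_seq = b_seq[:-trunc]
        b = _placed("b", pos_b, b_seq, chrom=chrom_b)
        return a, b

    def test_high_identity_high_cov_merges(self, rng):
        a, b = self._pair(rng, 0.005)
        assert len(merge_one_end([a, b])) == 1

    def test_low_coverage_does_not_merge(self, rng):
        # only 90% of the shorter sequence alignable
        src = random_seq(rng, 2000)
        a = _placed("a", 0, src)
        b = _placed("b", 3000, src[:1350] + random_seq(rng, 150))
        merged = merge_one_end([a, b])
        assert len(merged) == 2

    def test_distance_gate(self, rng):
        a, b = self._pair(rng, 0.0, pos_b=6000)
        assert len(merge_one_end([a, b])) == 2

    def test_chromosome_gate(self, rng):
        a, b = self._pair(rng, 0.0, chrom_b="chr2")
        assert len(merge_one_end([a, b])) == 2

    def test_transitive_chain_collapses(self, rng):
        # A~B and B~C at high identity; A vs C slightly worse but the
        # closure still groups all three
        src = random_seq(rng, 2000)
        a = _placed("a", 0, src)
        b = _placed("b", 1000, mutate(rng, src, 0.008))
        c = _placed("c", 2000, mutate(rng, b.seq, 0.008))
        merged = merge_one_end([a, b, c])
        assert len(merged) == 1
        assert merged[0].contig_id in {"a", "b", "c"}


@pytest.fixture(scope="module")
def ref():
    rng = np.random.default_rng(5)
    return ReferenceGenome([SeqRecord("chr1", random_seq(rng, 40_000))]), rng


class TestTrimPlaced:

    def test_flanks_trimmed_to_novel_core(self, ref):
        reference, rng = ref
        ip = 20_000
        novel = random_seq(rng, 1200)
        seq = (reference.fetch("chr1", ip - 300, ip) + novel
               + reference.fetch("chr1", ip, ip + 250))
        p = _placed("c", ip, seq)
        out = trim_placed(p, reference)
        assert out is not None
        assert abs(len(out.trimmed_seq) - len(novel)) <= 10
        assert novel[20:-20] in out.trimmed_seq

    def test_no_reference_alignment_unchanged(self, ref):
        reference, rng = ref
        seq = random_seq(rng, 1200)
        p = _placed("c", 20_000, seq)
        out = trim_placed(p, reference)
        assert out.trimmed_seq == seq

    def test_idempotent(self, ref):
        reference, rng = ref
        ip = 10_000
        seq = (reference.fetch("chr1", ip - 400, ip) + random_seq(rng, 1500))
        p = _placed("c", ip, seq)
        once = trim_placed(p, reference).trimmed_seq
        again = trim_placed(_placed("c", ip, once), reference).trimmed_seq
        assert once == again

    def test_all_reference_contig_dropped(self, ref):
        reference, rng = ref
        seq = reference.fetch("chr1", 19_000, 20_500)
        p = _placed("c", 20_000, seq)
        with pytest.warns(UserWarning, match="dropped"):
            assert trim_placed(p, reference) is None


class TestDedupeUnplaced:
    def test_exact_duplicate_longest_survives(self, rng):
        s = random_seq(rng, 1500)
        a = NovelContig("a", s + random_seq(rng, 100))
        b = NovelContig("b", s)
        out = dedupe_unplaced([a, b])
        assert [c.contig_id for c in out] == ["a"]

    def test_containment_longest_survives(self, rng):
        s = random_seq(rng, 2000)
        a = NovelContig("a", s)
        b = NovelContig("b", s[300:1800])  # fully covered at 100% identity
        out = dedupe_unplaced([a, b])
        assert [c.contig_id for c in out] == ["a"]

    def test_distinct_sequences_both_kept(self, rng):
        a = NovelContig("a", random_seq(rng, 1500))
        b = NovelContig("b", random_seq(rng, 1500))
        assert len(dedupe_unplaced([a, b])) == 2

    def test_planted_duplicates_match_component_oracle(self, rng):
        sources = [random_seq(rng, 1200) for _ in range(6)]
        contigs = []
        membership = []
        for i in range(30):
            j = int(rng.integers(0, 6))
            membership.append(j)
            contigs.append(NovelContig(
                f"c{i:02d}", mutate(rng, sources[j], 0.004)))
        out = dedupe_unplaced(contigs)
        # one survivor per source family, and it is that family's longest
        assert len(out) == 6
        survivors = {c.contig_id for c in out}
        for j in range(6):
            fam = [c for c, m in zip(contigs, membership) if m == j]
            best = min(fam, key=lambda c: (-c.length, c.contig_id))
            assert best.contig_id in survivors


class TestScreenAgainst:
    def test_identical_removed(self, rng):
        s = random_seq(rng, 1500)
        out = screen_against([NovelContig("a", s)], [SeqRecord("p", s)])
        assert out == []

    def test_85_percent_identity_kept(self, rng):
        s = random_seq(rng, 1500)
        a = NovelContig("a", mutate(rng, s, 0.15))
        out = screen_against([a], [SeqRecord("p", s)])
        assert [c.contig_id for c in out] == ["a"]

    def test_report_mode_returns_matches(self, rng):
        s = random_seq(rng, 1500)
        a = NovelContig("a", s)
        b = NovelContig("b", random_seq(rng, 1500))
        out = screen_against([a, b], [SeqRecord("p", s)], mode="report")
        assert [c.contig_id for c in out] == ["a"]

    def test_coverage_is_of_screened_contig(self, rng):
        # only 60% of the contig aligns: kept at the 80% coverage gate
        s = random_seq(rng, 1500)
        a = NovelContig("a", s[:900] + random_seq(rng, 600))
        out = screen_against([a], [SeqRecord("p", s[:900])])
        assert [c.contig_id for c in out] == ["a"]

    def test_planted_overlap_fixture_matches_pair_oracle(self, rng):
        placed = [SeqRecord(f"p{i}", random_seq(rng, 1500)) for i in range(4)]
        contigs, expect_removed = [], set()
        for i in range(12):
            if i % 3 == 0:
                src = placed[i % 4].seq
                contigs.append(NovelContig(f"c{i:02d}", mutate(rng, src, 0.02)))
                expect_removed.add(f"c{i:02d}")
            else:
                contigs.append(NovelContig(f"c{i:02d}", random_seq(rng, 1400)))
        out = screen_against(contigs, placed)
        assert {c.contig_id for c in out} == \
            {c.contig_id for c in contigs} - expect_removed
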