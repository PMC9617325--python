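"""Minimal seed-and-extend read mapper and unaligned-read extraction.

The built-in mapper exists to make the pipeline self-contained at desk scale;
imported SAM alignments are the production path.  A read is "mapped" iff some
seed k-mer places it at a locus where an end-to-end comparison has at most
floor(0.1 * read_len) mismatches, at a unique best locus; ambiguous-best
reads map to the lowest (chrom, pos) and are flagged multi.  Reads straddling
an insertion breakpoint usually fail the end-to-end budget and fall into the
unaligned sets — exactly the behaviour that creates anchor mate pairs at
insertion flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core_io import (GenomicInterval, MateAln, ReadPair, ReferenceGenome,
                      SeqRecord, revcomp)

_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i

_MAX_SEED_HITS = 50  # seeds hitting more loci than this are skipped as repetitive


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]


class KmerIndex:
    """Sorted k-mer index over a set of named sequences.

    Sequences are concatenated with k 'N' separators; k-mers containing N are
    never indexed, so no k-mer spans two sequences.
    """

    def __init__(self, records: Sequence[SeqRecord], k: int = 21):
        if not records:
            raise ValueError("empty reference")
        if any(k > len(r.seq) for r in records):
            # short sequences simply contribute no k-mers
            pass
        self.k = k
        self.names = [r.id for r in records]
        sep = "N" * k
        cat = sep.join(r.seq for r in records)
        self.cat_bytes = np.frombuffer(cat.encode(), dtype=np.uint8)
        self.offsets = np.empty(len(records), dtype=np.int64)
        self.lengths = np.empty(len(records), dtype=np.int64)
        off = 0
        for i, r in enumerate(records):
            self.offsets[i] = off
            self.lengths[i] = len(r.seq)
            off += len(r.seq) + k
        self.total = len(cat)

        codes = _LUT[self.cat_bytes]
        n_kmers = len(codes) - k + 1
        if n_kmers <= 0:
            raise ValueError("reference shorter than k")
        kmers = np.zeros(n_kmers, dtype=np.int64)
        for j in range(k):
            kmers = kmers * 4 + codes[j:j + n_kmers]
        invalid = codes < 0
        bad = np.convolve(invalid.astype(np.int64), np.ones(k, dtype=np.int64),
                          mode="valid") > 0
        valid_pos = np.nonzero(~bad)[0]
        valid = kmers[valid_pos]
        order = np.argsort(valid, kind="stable")
        self.sorted_kmers = valid[order]
        self.kmer_pos = valid_pos[order]

    def locate(self, global_pos: int) -> tuple[str, int]:
        """Map a concatenated coordinate back to (name, local position)."""
        i = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        return self.names[i], int(global_pos - self.offsets[i])

    def in_bounds(self, global_start: int, length: int) -> bool:
        if global_start < 0 or global_start + length > self.total:
            return False
        i = int(np.searchsorted(self.offsets, global_start, side="right")) - 1
        return global_start + length <= self.offsets[i] + self.lengths[i]


@dataclass
class Hit:
    chrom: str
    pos: int           # 0-based start on the target
    strand: str        # orientation of the read relative to the target
    mismatches: int
    multi: bool


class SeedExtendMapper:
    """End-to-end mapper over a KmerIndex with a 10% mismatch budget."""

    def __init__(self, records: Sequence[SeqRecord], k: int = 21,
                 n_seeds: int = 5, mismatch_frac: float = 0.10):
        self.index = KmerIndex(records, k=k)
        self.n_seeds = n_seeds
        self.mismatch_frac = mismatch_frac
        self._pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)

    def _seed_offsets(self, read_len: int) -> np.ndarray:
        k = self.index.k
        if k > read_len:
            raise ValueError(f"k={k} exceeds read length {read_len}")
        return np.unique(np.linspace(0, read_len - k, self.n_seeds).astype(int))

    def _seed_ints(self, codes: np.ndarray, offs: np.ndarray) -> np.ndarray:
        k = self.index.k
        windows = codes[offs[:, None] + np.arange(k)]
        seeds = windows @ self._pow4
        seeds[np.any(windows < 0, axis=1)] = -1  # N in seed: unusable
        return seeds

    def map_read(self, seq: str) -> Optional[Hit]:
        """Best end-to-end placement of a read, or None if unmapped."""
        L = len(seq)
        idx = self.index
        codes = _encode(seq)
        rc_codes = np.where(codes[::-1] >= 0, 3 - codes[::-1], -1)
        offs = self._seed_offsets(L)
        fwd_seeds = self._seed_ints(codes, offs)
        rc_seeds = self._seed_ints(rc_codes, offs)

        read_b = np.frombuffer(seq.encode(), dtype=np.uint8)
        rc_b = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
        has_n = bool(np.any(codes < 0))

        candidates: set[tuple[str, int]] = set()
        for strand, seeds, rb in (("+", fwd_seeds, read_b), ("-", rc_seeds, rc_b)):
            lo = np.searchsorted(idx.sorted_kmers, seeds, side="left")
            hi = np.searchsorted(idx.sorted_kmers, seeds, side="right")
            for si in range(len(seeds)):
                if seeds[si] < 0 or hi[si] - lo[si] > _MAX_SEED_HITS:
                    continue
                for p in idx.kmer_pos[lo[si]:hi[si]]:
                    start = int(p) - int(offs[si])
                    if idx.in_bounds(start, L):
                        candidates.add((strand, start))

        budget = int(self.mismatch_frac * L)
        best: Optional[tuple[int, str, int]] = None
        n_best = 0
        for strand, start in sorted(candidates, key=lambda c: (c[1], c[0])):
            rb = read_b if strand == "+" else rc_b
            ref_slice = idx.cat_bytes[start:start + L]
            if ref_slice.tobytes() == rb.tobytes():
                mm = 0
            else:
                mm = int(np.count_nonzero(ref_slice != rb))
            if has_n:
                mm += int(np.count_nonzero((ref_slice == ord("N")) & (rb == ord("N"))))
            if mm > budget:
                continue
            if best is None or mm < best[0]:
                best = (mm, strand, start)
                n_best = 1
            elif mm == best[0]:
                n_best += 1
        if best is None:
            return None
        chrom, pos = idx.locate(best[2])
        return Hit(chrom, pos, best[1], best[0], multi=n_best > 1)


def map_reads(reference: ReferenceGenome | Sequence[SeqRecord],
              reads1: Sequence[SeqRecord], reads2: Sequence[SeqRecord],
              k: int = 21) -> list[ReadPair]:
    """Align read pairs to the reference with the built-in mapper."""
    if isinstance(reference, ReferenceGenome):
        records = list(reference.records.values())
    else:
        records = list(reference)
    mapper = SeedExtendMapper(records, k=k)
    pairs: list[ReadPair] = []
    for r1, r2 in zip(reads1, reads2):
        pid = r1.id
        for suffix in ("/1", "/2"):
            if pid.endswith(suffix):
                pid = pid[:-2]
        pairs.append(ReadPair(pid, r1, r2,
                              _hit_to_aln(mapper.map_read(r1.seq), len(r1.seq)),
                              _hit_to_aln(mapper.map_read(r2.seq), len(r2.seq))))
    return pairs


def _hit_to_aln(hit: Optional[Hit], read_len: int) -> MateAln:
    if hit is None:
        return MateAln(mapped=False)
    return MateAln(mapped=True, chrom=hit.chrom, pos=hit.pos,
                   end=hit.pos + read_len, strand=hit.strand, multi=hit.multi)


@dataclass
class UnalignedSets:
    """The partition of read pairs feeding assembly and placement."""

    paired_unaligned: list[ReadPair] = field(default_factory=list)
    unpaired_unaligned: list[SeqRecord] = field(default_factory=list)
    anchor_pairs: dict[str, GenomicInterval] = field(default_factory=dict)
    assumed_fragment: int = 300

    def all_reads(self) -> list[SeqRecord]:
        """Every unaligned read, paired first, for assembly input."""
        out: list[SeqRecord] = []
        for p in self.paired_unaligned:
            out.append(p.read1)
            out.append(p.read2)
        out.extend(self.unpaired_unaligned)
        return out


def extract_unaligned(pairs: Iterable[ReadPair]) -> UnalignedSets:
    """Partition pairs by mate alignment state.

    Both mates unmapped: kept as a paired set (downstream assembly assumes a
    300 bp fragment).  Exactly one mate unmapped: the unmapped read is kept
    unpaired and its mapped mate's interval becomes its anchor.  Both mapped:
    dropped.  Duplicate-flagged pairs are excluded entirely, and multi-mapped
    reads count as aligned (no mapping-quality filter).
    """
    out = UnalignedSets()
    for pair in pairs:
        if pair.aln1 is None or pair.aln2 is None:
            raise ValueError(f"pair {pair.pair_id!r} lacks alignment state")
        if pair.is_duplicate:
            continue
        m1, m2 = pair.aln1.mapped, pair.aln2.mapped
        if not m1 and not m2:
            out.paired_unaligned.append(pair)
        elif m1 != m2:
            if m1:
                anchor_aln, unread = pair.aln1, pair.read2
            else:
                anchor_aln, unread = pair.aln2, pair.read1
            out.unpaired_unaligned.append(unread)
            out.anchor_pairs[unread.id] = GenomicInterval(
                anchor_aln.chrom, anchor_aln.pos, anchor_aln.end,
                anchor_aln.strand)
    return out
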