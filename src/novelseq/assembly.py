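"""De Bruijn assembly of unaligned reads into novel contigs.

A deliberately small, deterministic assembler: k-mers (default k=31) seen at
least twice (canonical counting, so an error k-mer on one strand is not
rescued by its own reverse complement) form the graph; short dead-end tips
are clipped; maximal non-branching paths are emitted as contigs in canonical
orientation, sorted by sequence.  For unique-sequence insertions covered at
~30X this recovers each insertion, plus whatever reference flank the
breakpoint-straddling reads contribute, as a single contig.  Production
users can import an external assembly as FASTA and skip this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .core_io import PipelineConfig, SeqRecord, revcomp
from .mapping import _LUT

_B = "ACGT"


@dataclass
class NovelContig:
    """An assembled reference-absent sequence with provenance."""

    contig_id: str
    seq: str
    individual_id: str = ""
    passed_contamination: bool = True
    mask_intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)

    def to_seqrecord(self) -> SeqRecord:
        return SeqRecord(self.contig_id, self.seq)


def _read_kmers(seq: str, k: int) -> np.ndarray:
    """Forward-strand k-mer integers of a read; windows containing N dropped."""
    codes = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    kmers = np.zeros(n, dtype=np.int64)
    for j in range(k):
        kmers = kmers * 4 + np.where(codes[j:j + n] >= 0, codes[j:j + n], 0)
    bad = np.convolve((codes < 0).astype(np.int64), np.ones(k, dtype=np.int64),
                      mode="valid") > 0
    return kmers[~bad]


def _rc_kmers(kmers: np.ndarray, k: int) -> np.ndarray:
    comp = (~kmers) & ((1 << (2 * k)) - 1)
    rc = np.zeros_like(kmers)
    cur = comp
    for _ in range(k):
        rc = (rc << 2) | (cur & 3)
        cur >>= 2
    return rc


def _decode(kmer: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_B[kmer & 3])
        kmer >>= 2
    return "".join(reversed(out))


def assemble(reads: Sequence[SeqRecord], k: int = 31,
             min_count: int = 2, clean_rounds: int = 2) -> list[SeqRecord]:
    """Assemble reads into contigs via a de Bruijn graph.

    Singleton k-mers (canonical count < min_count) are dropped as sequencing
    errors.  Short error structures that survive the count filter — dead-end
    tips, and low-coverage bubble branches created when two reads happen to
    share the same error — are removed by clipping unitigs shorter than 2k
    that either dead-end or fall far below the graph's median coverage,
    rebuilding the graph after each clipping round.  Contigs are the maximal
    non-branching paths, reported once per double-stranded sequence in
    canonical (lexicographically smaller) orientation.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (avoids self-reverse-complement k-mers)")
    chunks = [_read_kmers(r.seq, k) for r in reads]
    if not chunks or sum(len(c) for c in chunks) == 0:
        return []
    fwd = np.concatenate(chunks)
    canon = np.minimum(fwd, _rc_kmers(fwd, k))
    uniq, counts = np.unique(canon, return_counts=True)
    kept = counts >= min_count
    if not np.any(kept):
        return []
    count_of: dict[int, int] = dict(zip(uniq[kept].tolist(),
                                        counts[kept].tolist()))
    median_cov = float(np.median(counts[kept]))
    low_cov = max(min_count, int(0.25 * median_cov))
    keep = uniq[kept]
    nodes: set[int] = set(keep.tolist()) | set(_rc_kmers(keep, k).tolist())

    mask = (1 << (2 * (k - 1))) - 1
    shift = 2 * (k - 1)

    def succs(v: int) -> list[int]:
        base = (v & mask) << 2
        return [base | b for b in range(4) if (base | b) in nodes]

    def preds(v: int) -> list[int]:
        base = v >> 2
        return [base | (b << shift) for b in range(4)
                if (base | (b << shift)) in nodes]

    def cov(v: int) -> int:
        return count_of.get(v, count_of.get(_rc_kmers(np.array([v]), k)[0], 0))

    unitigs = _unitigs(nodes, succs, preds)
    for _ in range(clean_rounds):
        bad = _error_unitigs(unitigs, succs, preds, min_len=2 * k, k=k,
                             cov=cov, low_cov=low_cov)
        if not bad:
            break
        for path in bad:
            nodes.difference_update(path)
            nodes.difference_update(_rc_kmers(np.array(path), k).tolist())
        unitigs = _unitigs(nodes, succs, preds)

    seen: set[str] = set()
    contigs: list[str] = []
    for path in unitigs:
        seq = _decode(path[0], k) + "".join(_B[v & 3] for v in path[1:])
        canon_seq = min(seq, revcomp(seq))
        if canon_seq not in seen:
            seen.add(canon_seq)
            contigs.append(canon_seq)
    contigs.sort()
    return [SeqRecord(f"ctg{i + 1:05d}", s) for i, s in enumerate(contigs)]


def _unitigs(nodes: set[int], succs, preds) -> list[list[int]]:
    starts = sorted(
        v for v in nodes
        if len(preds(v)) != 1 or len(succs(preds(v)[0])) != 1
    )
    visited: set[int] = set()
    paths: list[list[int]] = []
    for s in starts:
        if s in visited:
            continue
        path = [s]
        visited.add(s)
        while True:
            nxt = succs(path[-1])
            if len(nxt) != 1:
                break
            v = nxt[0]
            if len(preds(v)) != 1 or v in visited:
                break
            path.append(v)
            visited.add(v)
        paths.append(path)
    # isolated cycles: every node has in/out degree 1
    for v in sorted(nodes - visited):
        if v in visited:
            continue
        path = [v]
        visited.add(v)
        cur = v
        while True:
            nxt = succs(cur)[0]
            if nxt == v or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        paths.append(path)
    return paths


def _error_unitigs(unitigs: list[list[int]], succs, preds, min_len: int,
                   k: int, cov, low_cov: int) -> list[list[int]]:
    """Short unitigs that look like error artefacts.

    Tips: shorter than min_len and dead at exactly one side.  Bubble
    branches: shorter than min_len, attached at both sides, with mean
    coverage at or below low_cov (a genuine short repeat path sits at graph
    coverage; a duplicated-error path sits at the count floor).
    """
    bad = []
    for path in unitigs:
        seq_len = k + len(path) - 1
        if seq_len >= min_len:
            continue
        dead_start = len(preds(path[0])) == 0
        dead_end = len(succs(path[-1])) == 0
        if dead_start != dead_end:
            bad.append(path)
        elif not dead_start and not dead_end:
            mean_cov = sum(cov(v) for v in path) / len(path)
            if mean_cov <= low_cov:
                bad.append(path)
    return bad


def filter_contigs(contigs: Iterable[SeqRecord], cfg: Optional[PipelineConfig] = None,
                   contamination_pred: Optional[Callable[[SeqRecord], bool]] = None,
                   mask_fn: Optional[Callable[[SeqRecord],
                                              list[tuple[int, int]]]] = None,
                   individual_id: str = "") -> list[NovelContig]:
    """Length-filter contigs and apply optional screening hooks.

    Only contigs strictly longer than cfg.min_contig_len are retained.  The
    contamination predicate (returns True to keep) and the masking function
    (returns intervals to record; the sequence is never altered) are
    injection points for external screens such as taxonomic classifiers or
    repeat maskers.
    """
    cfg = cfg or PipelineConfig()
    out: list[NovelContig] = []
    for rec in contigs:
        if len(rec.seq) <= cfg.min_contig_len:
            continue
        if contamination_pred is not None and not contamination_pred(rec):
            continue
        masks = list(mask_fn(rec)) if mask_fn is not None else []
        cid = f"{individual_id}:{rec.id}" if individual_id else rec.id
        out.append(NovelContig(cid, rec.seq, individual_id=individual_id,
                               passed_contamination=True,
                               mask_intervals=masks))
    return out
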