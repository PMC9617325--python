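"""Pairwise local alignment with identity/coverage semantics.

An anchor-and-chain aligner in the MUMmer mould: exact matches of at least
``min_anchor`` bp are found on both strands, chained collinearly, and the
chained span is aligned end to end (edit-distance alignment via edlib); the
resulting path is trimmed to its best-scoring contiguous stretch under
affine scores (match +1, mismatch -1, gap open -4, gap extend -1), which
reproduces local-alignment behaviour on the high-identity comparisons the
pipeline's thresholds target.  Identity is matches over alignment columns,
coverage is aligned span over sequence length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np

from .core_io import AlnRecord, SeqRecord, revcomp

_CIG_RE = re.compile(r"(\d+)([=XIDM])")

_MAX_ANCHORS = 5000
_MAX_RECORDS = 20


# ---------------------------------------------------------------------------
# exact-match anchors


def _maximal_anchors(query: str, target: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches >= k bp as (q_start, t_start, length).

    Seeded with k-mers of the target, merged along diagonals.  'N' never
    matches anything, including another 'N'.
    """
    if len(query) < k or len(target) < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(target) - k + 1):
        km = target[j:j + k]
        if "N" not in km:
            index.setdefault(km, []).append(j)
    by_diag: dict[int, list[int]] = {}
    for i in range(len(query) - k + 1):
        km = query[i:i + k]
        hits = index.get(km)
        if hits:
            for j in hits:
                by_diag.setdefault(j - i, []).append(i)
    anchors: list[tuple[int, int, int]] = []
    for diag, qpos in by_diag.items():
        qpos.sort()
        run_start = qpos[0]
        prev = qpos[0]
        for q in qpos[1:] + [qpos[-1] + 2]:  # sentinel closes the final run
            if q == prev + 1:
                prev = q
                continue
            anchors.append((run_start, run_start + diag, prev - run_start + k))
            run_start = q
            prev = q
        if len(anchors) > _MAX_ANCHORS:
            break
    return anchors[:_MAX_ANCHORS]


def _chain(anchors: list[tuple[int, int, int]]) -> list[list[tuple[int, int, int]]]:
    """Collinear chains of anchors by quadratic DP, best chains first."""
    chains = []
    remaining = sorted(anchors)
    while remaining and len(chains) < _MAX_RECORDS:
        n = len(remaining)
        score = [a[2] for a in remaining]
        back = [-1] * n
        for i in range(n):
            qi, ti, li = remaining[i]
            for j in range(i):
                qj, tj, lj = remaining[j]
                if qj + lj <= qi + li and tj + lj <= ti + li and qj <= qi and tj <= ti:
                    gap = max(qi - (qj + lj), ti - (tj + lj), 0)
                    s = score[j] + li - gap // 4
                    if s > score[i]:
                        score[i] = s
                        back[i] = j
        best = max(range(n), key=lambda i: score[i])
        chain = []
        i = best
        while i != -1:
            chain.append(remaining[i])
            i = back[i]
        chain.reverse()
        chains.append(chain)
        qs, qe = chain[0][0], chain[-1][0] + chain[-1][2]
        ts, te = chain[0][1], chain[-1][1] + chain[-1][2]
        remaining = [a for a in remaining
                     if (a[0] + a[2] <= qs or a[0] >= qe)
                     and (a[1] + a[2] <= ts or a[1] >= te)]
    return chains


# ---------------------------------------------------------------------------
# gap closing + local trimming


def _cigar_columns(cigar: str) -> np.ndarray:
    """Per-column codes: 0 match, 1 mismatch, 2 insertion(query), 3 deletion."""
    code = {"=": 0, "X": 1, "I": 2, "D": 3}
    parts = []
    for num, op in _CIG_RE.findall(cigar):
        parts.append(np.full(int(num), code[op], dtype=np.int8))
    return np.concatenate(parts) if parts else np.empty(0, dtype=np.int8)


def _best_window(cols: np.ndarray,
                 match=1.0, mismatch=-1.0, gap_open=-4.0, gap_extend=-1.0
                 ) -> tuple[int, int]:
    """Best-scoring contiguous column range [lo, hi) of an alignment path."""
    score = np.where(cols == 0, match, np.where(cols == 1, mismatch, gap_extend))
    is_gap = cols >= 2
    gap_start = is_gap & ~np.concatenate([[False], is_gap[:-1]])
    score = score + np.where(gap_start, gap_open, 0.0)
    best, best_lo, best_hi = 0.0, 0, 0
    cur, cur_lo = 0.0, 0
    for i, s in enumerate(score.tolist()):
        if cur <= 0:
            cur, cur_lo = 0.0, i
        cur += s
        if cur > best:
            best, best_lo, best_hi = cur, cur_lo, i + 1
    return best_lo, best_hi


def _align_span(qseq: str, tseq: str) -> tuple[int, int, int, int, int, int]:
    """Edit-distance alignment of two spans, trimmed to best local window.

    Returns (q_off, q_len, t_off, t_len, matches, aln_len) relative to the
    given spans.
    """
    res = edlib.align(qseq, tseq, mode="NW", task="path")
    cols = _cigar_columns(res["cigar"])
    lo, hi = _best_window(cols)
    if hi <= lo:
        return 0, 0, 0, 0, 0, 0
    adv_q = np.isin(cols, (0, 1, 2)).astype(np.int64)
    adv_t = np.isin(cols, (0, 1, 3)).astype(np.int64)
    q_off = int(adv_q[:lo].sum())
    t_off = int(adv_t[:lo].sum())
    q_len = int(adv_q[lo:hi].sum())
    t_len = int(adv_t[lo:hi].sum())
    matches = int((cols[lo:hi] == 0).sum())
    return q_off, q_len, t_off, t_len, matches, hi - lo


def local_align(query: SeqRecord, target: SeqRecord,
                min_anchor: int = 15) -> list[AlnRecord]:
    """Anchor-chained local alignments of query against target, both strands.

    Records are sorted by descending alignment length.  For strand "-",
    query coordinates refer to the forward query sequence.
    """
    if not query.seq or not target.seq:
        raise ValueError("empty sequence")
    records: list[AlnRecord] = []
    qlen, tlen = len(query.seq), len(target.seq)
    for strand in ("+", "-"):
        qseq = query.seq if strand == "+" else revcomp(query.seq)
        for chain in _chain(_maximal_anchors(qseq, target.seq, min_anchor)):
            qs, qe = chain[0][0], chain[-1][0] + chain[-1][2]
            ts, te = chain[0][1], chain[-1][1] + chain[-1][2]
            # extend past the outermost anchors so terminal stretches that
            # score positively despite mismatches are kept (local semantics);
            # symmetric extension avoids forced terminal gaps, and the
            # best-window trim removes bad extensions again
            ext0 = min(qs, ts, 100)
            ext1 = min(qlen - qe, tlen - te, 100)
            qs, ts = qs - ext0, ts - ext0
            qe, te = qe + ext1, te + ext1
            q_off, q_len, t_off, t_len, matches, aln_len = _align_span(
                qseq[qs:qe], target.seq[ts:te])
            if aln_len == 0 or matches == 0:
                continue
            aq_s, aq_e = qs + q_off, qs + q_off + q_len
            at_s, at_e = ts + t_off, ts + t_off + t_len
            if strand == "-":
                aq_s, aq_e = qlen - aq_e, qlen - aq_s
            records.append(AlnRecord(
                query_id=query.id, target_id=target.id,
                q_start=aq_s, q_end=aq_e, t_start=at_s, t_end=at_e,
                strand=strand, matches=matches, aln_len=aln_len,
                query_length=qlen, target_length=tlen))
    records.sort(key=lambda r: (-r.aln_len, r.q_start, r.t_start, r.strand))
    return records


# ---------------------------------------------------------------------------
# coverage


def best_combined_coverage(records: Iterable[AlnRecord], on: str = "query") -> float:
    """Fraction of the chosen sequence covered by the union of aligned spans."""
    if on not in ("query", "target"):
        raise ValueError("on must be 'query' or 'target'")
    records = list(records)
    if not records:
        return 0.0
    if on == "query":
        ids = {r.query_id for r in records}
        length = records[0].query_length
        ivs = sorted((r.q_start, r.q_end) for r in records)
    else:
        ids = {r.target_id for r in records}
        length = records[0].target_length
        ivs = sorted((r.t_start, r.t_end) for r in records)
    if len(ids) != 1:
        raise ValueError(f"records cover multiple {on} sequences: {sorted(ids)}")
    covered = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return covered / length


# ---------------------------------------------------------------------------
# longest exact match (breakpoint verification primitive)


@dataclass(frozen=True)
class ExactMatch:
    length: int
    probe_start: int   # on the forward probe
    region_start: int
    strand: str


def longest_consistent_exact_match(
        probe: str, region: str,
        abut: Optional[str] = None, abut_tol: int = 10,
        strands: Sequence[str] = ("+", "-")) -> Optional[ExactMatch]:
    """Longest common substring of probe and region, optionally constrained.

    ``abut`` = "start" or "end" requires the match to come within
    ``abut_tol`` bp of that side of the *forward* probe — a match floating in
    the middle of an end probe does not define a breakpoint.  Both strands
    of the probe are searched unless restricted; ties prefer "+", then the
    smaller region coordinate.  Exact means exact: N matches nothing.
    """
    best: Optional[ExactMatch] = None
    for strand in strands:
        pseq = probe if strand == "+" else revcomp(probe)
        side = abut
        if strand == "-" and abut is not None:
            side = "end" if abut == "start" else "start"
        m = _lcs_constrained(pseq, region, side, abut_tol)
        if m is None:
            continue
        length, p_start, r_start = m
        if strand == "-":
            p_start = len(probe) - p_start - length
        cand = ExactMatch(length, p_start, r_start, strand)
        if (best is None or cand.length > best.length
                or (cand.length == best.length and cand.strand == "+"
                    and best.strand == "-")):
            best = cand
    return best


def _lcs_constrained(probe: str, region: str, abut: Optional[str],
                     tol: int) -> Optional[tuple[int, int, int]]:
    plen = len(probe)
    reg = np.frombuffer(region.encode(), dtype=np.uint8)
    not_n = reg != ord("N")
    prev = np.zeros(len(reg), dtype=np.int64)
    best_len, best_p, best_r = 0, -1, -1
    for i, ch in enumerate(probe.encode()):
        if ch == ord("N"):
            row = np.zeros(len(reg), dtype=np.int64)
        else:
            eq = (reg == ch) & not_n
            shifted = np.concatenate([[0], prev[:-1]])
            row = np.where(eq, shifted + 1, 0)
        if abut == "start":
            # match starting at probe position i-L+1 must satisfy start <= tol
            ok = row >= (i + 1 - tol)
            cand = np.where(ok, row, 0)
        elif abut == "end":
            cand = row if i + 1 >= plen - tol else np.zeros(1, dtype=np.int64)
        else:
            cand = row
        mx = int(cand.max()) if cand.size else 0
        if mx > best_len:
            j = int(np.argmax(cand))
            best_len = mx
            best_p = i - mx + 1
            best_r = j - mx + 1
        prev = row
    if best_len == 0:
        return None
    return best_len, best_p, best_r
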