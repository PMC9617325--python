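"""Domain types and readers/writers for the formats the pipeline touches.

All internal coordinates are 0-based half-open.  1-based inputs (SAM, GFF3)
are converted exactly once, at the parser boundary; emitted BED is 0-based
half-open.  This module is the single home for those conventions.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised on malformed input files; carries file/line context in the message."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, stored uppercase."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("SeqRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"SeqRecord {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"SeqRecord {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        return replace(self, seq=revcomp(self.seq))


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open 0-based interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """A gene with a mandatory strand (upstream is strand-dependent)."""

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand is required (got "
                f"{self.interval.strand!r}); upstream is undefined without it"
            )


@dataclass(frozen=True)
class AlnRecord:
    """A pairwise local alignment with identity/coverage semantics.

    identity = matches / alignment columns (gaps count as columns);
    q_cov / t_cov = aligned span over the full sequence length.
    Coordinates are half-open on the respective sequence; for strand "-",
    query coordinates refer to the forward (as given) query sequence.
    """

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    matches: int
    aln_len: int
    query_length: int
    target_length: int

    def __post_init__(self):
        if self.matches > self.aln_len:
            raise ValueError("matches cannot exceed alignment length")

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len if self.aln_len else 0.0

    @property
    def q_cov(self) -> float:
        return (self.q_end - self.q_start) / self.query_length

    @property
    def t_cov(self) -> float:
        return (self.t_end - self.t_start) / self.target_length


@dataclass
class MateAln:
    """Primary alignment state of one mate."""

    mapped: bool
    chrom: Optional[str] = None
    pos: Optional[int] = None  # 0-based leftmost
    end: Optional[int] = None  # half-open end on the reference
    strand: str = "."
    is_duplicate: bool = False
    multi: bool = False


@dataclass
class ReadPair:
    pair_id: str
    read1: SeqRecord
    read2: SeqRecord
    aln1: Optional[MateAln] = None
    aln2: Optional[MateAln] = None

    @property
    def is_duplicate(self) -> bool:
        return bool(
            (self.aln1 and self.aln1.is_duplicate)
            or (self.aln2 and self.aln2.is_duplicate)
        )


@dataclass
class PipelineConfig:
    """Every numeric knob of the pipeline, defaulting to the published protocol."""

    min_contig_len: int = 1000     # retain contigs strictly longer than this
    end_window: int = 500          # bp from a contig end within which reads vote
    unambig_window: int = 2000     # width of the region-unambiguity window
    unambig_frac: float = 0.95     # strict > on the fraction of anchors in window
    min_anchor_reads: int = 3      # floor on anchors voting for an end
    end_probe_len: int = 200       # contig-end probe length for exact matching
    ref_flank: int = 500           # reference flank added around the region
    min_exact_match: int = 15      # minimum consistent exact match to place
    cluster_dist: int = 100        # single-linkage gap for placed-contig clusters
    merge_dist: int = 5000         # max distance for merging one-end representatives
    merge_id: float = 0.98
    merge_cov: float = 0.95
    dedup_id: float = 0.98
    dedup_cov: float = 0.95
    crossref_id: float = 0.90
    crossref_cov: float = 0.80
    rare_freq: float = 0.05        # inclusive cutoff for "rare"
    upstream_len: int = 5000       # regulator-region window upstream of a gene
    unpaired_fragment: int = 300   # assumed fragment size for both-unmapped pairs
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("unambig_frac", "merge_id", "merge_cov", "dedup_id",
                     "dedup_cov", "crossref_id", "crossref_cov", "rare_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("min_contig_len", "end_window", "unambig_window",
                     "end_probe_len", "ref_flank", "min_exact_match",
                     "cluster_dist", "merge_dist", "upstream_len",
                     "unpaired_fragment", "min_anchor_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class ReferenceGenome:
    """Named sequences with lengths; coordinate authority for placements."""

    def __init__(self, records: Iterable[SeqRecord]):
        self.records: dict[str, SeqRecord] = {}
        for rec in records:
            if rec.id in self.records:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            self.records[rec.id] = rec

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def __getitem__(self, chrom: str) -> SeqRecord:
        return self.records[chrom]

    def length(self, chrom: str) -> int:
        return len(self.records[chrom])

    def names(self) -> list[str]:
        return list(self.records)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence with bounds clamped to the chromosome."""
        n = self.length(chrom)
        return self.records[chrom].seq[max(0, start):min(n, end)]

    def check_bounds(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self.records:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self.length(iv.chrom):
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.length(iv.chrom)}"
            )


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[SeqRecord]:
    """Parse FASTA into SeqRecords, uppercased, order preserved.

    Duplicate ids and empty sequences are rejected.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r} (record {i + 1})")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for {rec.id!r} (record {i + 1})")
        try:
            records.append(SeqRecord(rec.id, seq, rec.description))
        except ValueError as e:
            raise ParseError(f"{path}: record {i + 1}: {e}") from e
    return records


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    bio = (
        _BioSeqRecord(Seq(r.seq), id=r.id,
                      description=r.description if r.description != r.id else "")
        for r in records
    )
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_fastq(path) -> list[SeqRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(SeqRecord(rec.id, str(rec.seq).upper(), rec.description))
    return out


def write_fastq(records: Iterable[SeqRecord], path, quality: int = 35) -> None:
    with open(path, "w") as fh:
        qchar = chr(quality + 33)
        for r in records:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qchar * len(r.seq)}\n")


# ---------------------------------------------------------------------------
# SAM

_FLAG_PAIRED = 0x1
_FLAG_UNMAPPED = 0x4
_FLAG_REVERSE = 0x10
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80
_FLAG_SECONDARY = 0x100
_FLAG_DUP = 0x400
_FLAG_SUPPLEMENTARY = 0x800


def read_sam(path) -> Iterator[ReadPair]:
    """Stream mate-joined ReadPairs from a text SAM file.

    Secondary (0x100) and supplementary (0x800) records never contribute to a
    mate's aligned status; the duplicate flag (0x400) is recorded.  Orphan
    mates at EOF are dropped with a warning.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=True)
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e
    with sam:
        if not sam.header.get("SQ"):
            raise ParseError(f"{path}: SAM file has no @SQ header lines")
        for seg in sam:
            if seg.is_secondary or seg.is_supplementary:
                continue
            name = seg.query_name
            if name in pending:
                first = pending.pop(name)
                yield _join_mates(name, first, seg, sam)
            else:
                pending[name] = seg
    if pending:
        warnings.warn(
            f"{path}: dropped {len(pending)} orphan mate(s) without a pair at EOF"
        )


def _mate_aln(seg: pysam.AlignedSegment, sam) -> MateAln:
    if seg.is_unmapped:
        return MateAln(mapped=False, is_duplicate=seg.is_duplicate)
    return MateAln(
        mapped=True,
        chrom=seg.reference_name,
        pos=seg.reference_start,
        end=seg.reference_end if seg.reference_end is not None
        else seg.reference_start + (seg.query_length or len(seg.query_sequence or "")),
        strand="-" if seg.is_reverse else "+",
        is_duplicate=seg.is_duplicate,
    )


def _seg_seq(seg: pysam.AlignedSegment) -> str:
    seq = seg.query_sequence or "N"
    seq = seq.upper()
    # mapped reverse-strand records store the reverse complement; undo it so
    # read1/read2 hold the original sequenced strand
    if seg.is_reverse and not seg.is_unmapped:
        seq = revcomp(seq)
    return seq


def _join_mates(name, a, b, sam) -> ReadPair:
    if a.is_read2 and not b.is_read2:
        a, b = b, a
    r1 = SeqRecord(f"{name}/1", _seg_seq(a))
    r2 = SeqRecord(f"{name}/2", _seg_seq(b))
    return ReadPair(name, r1, r2, _mate_aln(a, sam), _mate_aln(b, sam))


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[GeneModel]:
    """Parse gene features from GFF3 into 0-based half-open GeneModels.

    Strandless genes are rejected: the upstream regulator window is undefined
    without an orientation.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if feat.strand not in ("+", "-"):
            raise ParseError(
                f"{path}: gene {feat.id!r} has no strand; upstream is undefined"
            )
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        genes.append(GeneModel(feat.id, iv))
    return genes


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tnovelseq\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED / TSV


def write_bed(placements, path, reference: Optional[ReferenceGenome] = None) -> None:
    """Write placements as BED6 point features (insertion coordinate, 1 bp).

    One-end placements define a point, not a span, so every record is
    [insert_pos, insert_pos + 1).  Deterministic sort by (chrom, start, name).
    """
    rows = []
    for p in placements:
        if reference is not None:
            if p.insert_pos < 0 or p.insert_pos >= reference.length(p.chrom):
                raise ValueError(
                    f"{p.contig_id}: insertion point {p.chrom}:{p.insert_pos} "
                    "outside chromosome bounds"
                )
        rows.append((p.chrom, p.insert_pos, p.insert_pos + 1, p.contig_id, ".",
                     p.strand))
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def write_tsv(rows: Iterable[dict], path, columns: Optional[list[str]] = None) -> None:
    rows = list(rows)
    if columns is None:
        columns = list(rows[0]) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def log(msg: str) -> None:
    print(f"[novelseq] {msg}", file=sys.stderr)
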