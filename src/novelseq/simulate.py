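"""Synthetic references, insertion haplotypes and paired-end reads with truth.

The generator emulates a standard validation design for insertion discovery:
random DNA sequences are planted into a random reference chromosome to form a
haplotype, and short paired-end reads are drawn from that haplotype at fixed
fold coverage.  Every draw is a pure function of SimConfig, including its
seed, so the whole experiment is reproducible byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import SeqRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

NOVELTY_K = 31  # k-mer size of the insertion-novelty screen


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one planted insertion.

    ref_pos is the 0-based reference base *before which* the insertion sits;
    hap_pos is its 0-based start in the haplotype.
    """

    insertion_id: str
    sequence: str
    hap_pos: int
    ref_pos: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimConfig:
    ref_len: int = 1_000_000
    gc_frac: float = 0.36          # typical for walnut-family nuclear genomes
    n_insertions: int = 33
    ins_len_min: int = 1000
    ins_len_max: int = 5000
    coverage: float = 30.0
    read_len: int = 150
    frag_mean: float = 400.0
    frag_sd: float = 50.0
    subst_error_rate: float = 0.002
    rng_seed: int = 0
    chrom_name: str = "chr1"

    def __post_init__(self):
        for name in ("gc_frac", "subst_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frag_mean < 2 * self.read_len:
            warnings.warn(
                f"frag_mean={self.frag_mean} < 2*read_len={2 * self.read_len}: "
                "mates will overlap"
            )

    @property
    def min_separation(self) -> int:
        # keeps anchor evidence of adjacent insertions from mixing
        return int(2 * self.frag_mean)


def _random_seq(rng: np.random.Generator, n: int, gc_frac: float) -> str:
    p = np.array([(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2])
    codes = rng.choice(4, size=n, p=p)
    return _BASES[codes].tobytes().decode()


def make_reference(cfg: SimConfig) -> SeqRecord:
    """I.i.d. random chromosome at the configured GC fraction."""
    if cfg.ref_len < 10 * cfg.ins_len_max:
        raise ValueError(
            f"ref_len={cfg.ref_len} too small for ins_len_max={cfg.ins_len_max} "
            "(need at least 10x)"
        )
    rng = np.random.default_rng(cfg.rng_seed)
    return SeqRecord(cfg.chrom_name, _random_seq(rng, cfg.ref_len, cfg.gc_frac))


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def make_insertions(cfg: SimConfig, reference: SeqRecord,
                    max_attempts: int = 1000) -> list[SimTruth]:
    """Draw insertion sequences and well-separated reference positions.

    Sequences are random draws re-sampled until none of their 31-mers occurs
    in the reference (so the planted sequence is genuinely novel); positions
    are uniform, rejected until all pairwise separations reach
    2 x frag_mean.  Truth records are sorted by ref_pos.
    """
    rng = np.random.default_rng((cfg.rng_seed, 1))
    if cfg.n_insertions == 0:
        return []
    if cfg.n_insertions * cfg.ins_len_max > cfg.ref_len // 2:
        raise ValueError("insertions would occupy more than half the reference")

    ref_kmers = _kmer_set(reference.seq, NOVELTY_K)
    sequences: list[str] = []
    for _ in range(cfg.n_insertions):
        for attempt in range(max_attempts):
            ln = int(rng.integers(cfg.ins_len_min, cfg.ins_len_max + 1))
            seq = _random_seq(rng, ln, cfg.gc_frac)
            both = _kmer_set(seq, NOVELTY_K) | _kmer_set(revcomp(seq), NOVELTY_K)
            if not (both & ref_kmers):
                sequences.append(seq)
                break
        else:
            raise RuntimeError("could not draw a novel insertion sequence")

    sep = cfg.min_separation
    lo, hi = sep, cfg.ref_len - sep
    for attempt in range(max_attempts):
        pos = np.sort(rng.integers(lo, hi, size=cfg.n_insertions))
        if cfg.n_insertions < 2 or np.all(np.diff(pos) >= sep):
            break
    else:
        raise RuntimeError(
            f"could not place {cfg.n_insertions} insertions with separation "
            f">= {sep} in {cfg.ref_len} bp"
        )

    truth: list[SimTruth] = []
    offset = 0
    for i, (p, seq) in enumerate(zip(pos.tolist(), sequences)):
        truth.append(SimTruth(f"ins{i:03d}", seq, hap_pos=p + offset, ref_pos=p))
        offset += len(seq)
    return truth


def apply_insertions(reference: SeqRecord, truth: list[SimTruth]) -> SeqRecord:
    """Splice the truth sequences into the reference to form the haplotype."""
    ordered = sorted(truth, key=lambda t: t.ref_pos)
    for a, b in zip(ordered, ordered[1:]):
        if a.ref_pos == b.ref_pos:
            raise ValueError(f"overlapping insertions at ref_pos {a.ref_pos}")
    parts = []
    prev = 0
    for t in ordered:
        parts.append(reference.seq[prev:t.ref_pos])
        parts.append(t.sequence)
        prev = t.ref_pos
    parts.append(reference.seq[prev:])
    hap = SeqRecord(reference.id + "_hap", "".join(parts))
    for t in ordered:
        assert hap.seq[t.hap_pos:t.hap_pos + t.length] == t.sequence
    return hap


def simulate_reads(haplotype: SeqRecord, cfg: SimConfig
                   ) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Paired-end reads at fixed fold coverage with substitution errors.

    read1 is the fragment prefix on the forward strand, read2 the reverse
    complement of the fragment suffix.  Read names record the fragment
    coordinates (debugging aid only; nothing downstream reads them).
    """
    if cfg.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng((cfg.rng_seed, 2))
    L = len(haplotype.seq)
    n_pairs = int(np.ceil(cfg.coverage * L / (2 * cfg.read_len)))

    frag = np.rint(rng.normal(cfg.frag_mean, cfg.frag_sd, size=n_pairs)).astype(int)
    frag = np.clip(frag, cfg.read_len, L)
    starts = (rng.random(n_pairs) * (L - frag + 1)).astype(int)

    hap = np.frombuffer(haplotype.seq.encode(), dtype=np.uint8)
    reads1: list[SeqRecord] = []
    reads2: list[SeqRecord] = []
    rl = cfg.read_len
    for i in range(n_pairs):
        s, f = int(starts[i]), int(frag[i])
        fwd = hap[s:s + rl]
        rev = hap[s + f - rl:s + f]
        name = f"frag{i:07d}_{s}_{s + f}"
        r1 = _with_errors(fwd, rng, cfg.subst_error_rate)
        r2 = _with_errors(rev, rng, cfg.subst_error_rate)
        reads1.append(SeqRecord(name + "/1", r1.tobytes().decode()))
        reads2.append(SeqRecord(name + "/2", revcomp(r2.tobytes().decode())))
    return reads1, reads2


def _with_errors(read: np.ndarray, rng: np.random.Generator,
                 rate: float) -> np.ndarray:
    if rate <= 0:
        return read
    n_err = rng.binomial(len(read), rate)
    if n_err == 0:
        return read
    read = read.copy()
    pos = rng.choice(len(read), size=n_err, replace=False)
    for p in pos:
        choices = [b for b in b"ACGT" if b != read[p]]
        read[p] = choices[rng.integers(3)]
    return read


def simulate_experiment(cfg: SimConfig):
    """Reference + truth + haplotype + read pairs in one call."""
    ref = make_reference(cfg)
    truth = make_insertions(cfg, ref)
    hap = apply_insertions(ref, truth)
    reads1, reads2 = simulate_reads(hap, cfg)
    return ref, truth, hap, reads1, reads2
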