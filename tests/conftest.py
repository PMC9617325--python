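"""Shared fixtures: small simulated datasets and a session-scoped replica
of the planted-insertion validation experiment."""

from __future__ import annotations

import numpy as np
import pytest

from novelseq.core_io import ReferenceGenome, SeqRecord
from novelseq.simulate import SimConfig
from novelseq.validation import ValidationReport, run_validation

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate(rng: np.random.Generator, seq: str, sub_rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < sub_rate:
            out[i] = rng.choice([b for b in BASES if b != out[i]])
    return "".join(out)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_sim():
    """A 120 kb reference with 4 planted insertions, full pipeline inputs."""
    from novelseq.simulate import simulate_experiment
    cfg = SimConfig(ref_len=120_000, n_insertions=4, rng_seed=7)
    ref, truth, hap, r1, r2 = simulate_experiment(cfg)
    return dict(cfg=cfg, ref=ref, truth=truth, hap=hap, reads1=r1, reads2=r2,
                reference=ReferenceGenome([ref]))


@pytest.fixture(scope="session")
def replica() -> ValidationReport:
    """The scaled validation replica: 1 Mb reference, 33 insertions, 30X."""
    return run_validation(seed=1)


def make_sam(path, records: list[tuple], chrom_lengths: dict[str, int]):
    """Write a minimal SAM file.

    records: (qname, flag, rname, pos1, seq) tuples; pos1 is 1-based or 0
    for unmapped.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, ln in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{ln}\n")
        for qname, flag, rname, pos1, seq in records:
            cigar = "*" if flag & 0x4 else f"{len(seq)}M"
            mapq = 0 if flag & 0x4 else 60
            fh.write(f"{qname}\t{flag}\t{rname}\t{pos1}\t{mapq}\t{cigar}\t*"
                     f"\t0\t0\t{seq}\t{'I' * len(seq)}\n")
    return path
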