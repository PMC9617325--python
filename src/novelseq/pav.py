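"""Presence/absence calling, frequency classes and species sharing.

Each final novel sequence is called present in an individual when some
alignment between that individual's raw assembled contigs and the sequence
is effectively identical (default: 100% identity over >= 95% of the shorter
sequence; literal full-length identity would fail on ordinary assembler
end-trimming, so the criterion is configurable).  Carrier counts are then
binned into singleton / low / high / fixed classes, generalizing the
published cohort thresholds (1, < n/2, >= n/2 but < n, n; at n=80 these are
1, < 40, 40-79, 80), and contigs are split rare/common at carrier frequency
0.05 (rare inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import local_align
from .assembly import NovelContig
from .cluster_filter import _kmer_profile, _pair_redundant, _shares_kmer
from .core_io import SeqRecord


@dataclass
class PresenceMatrix:
    """Contigs x individuals boolean occupancy with species labels."""

    contig_ids: list[str]
    individual_ids: list[str]
    present: np.ndarray  # bool, shape (n_contigs, n_individuals)
    species_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.contig_ids), len(self.individual_ids)):
            raise ValueError("presence matrix shape mismatch")
        missing = [i for i in self.individual_ids if i not in self.species_of]
        if self.species_of and missing:
            raise ValueError(f"individuals without species label: {missing}")

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def carrier_counts(self) -> dict[str, int]:
        sums = self.present.sum(axis=1)
        return {c: int(s) for c, s in zip(self.contig_ids, sums)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.present.astype(int), index=self.contig_ids,
                            columns=self.individual_ids)


@dataclass(frozen=True)
class FrequencyClass:
    label: str  # singleton | low | high | fixed
    count: int
    n: int

    @property
    def freq(self) -> float:
        return self.count / self.n


CLASS_ORDER = ("singleton", "low", "high", "fixed")


def call_presence(individual_contigs: dict[str, Sequence[NovelContig]],
                  final_contigs: Sequence[SeqRecord],
                  min_identity: float = 1.0,
                  min_cov: float = 0.95,
                  species_of: Optional[dict[str, str]] = None
                  ) -> PresenceMatrix:
    """Presence matrix from per-individual raw contigs vs the final sets.

    present[c][i] is true iff some alignment between a raw contig of
    individual i and final contig c reaches min_identity over min_cov of
    the shorter sequence.
    """
    individuals = list(individual_contigs)
    mat = np.zeros((len(final_contigs), len(individuals)), dtype=bool)
    profiles = [_kmer_profile(f.seq) for f in final_contigs]
    for ii, ind in enumerate(individuals):
        for raw in individual_contigs[ind]:
            for ci, (final, prof) in enumerate(zip(final_contigs, profiles)):
                if mat[ci, ii]:
                    continue
                if not _shares_kmer(raw.seq, prof):
                    continue
                if _pair_redundant(raw.seq, final.seq, min_identity, min_cov,
                                   "shorter"):
                    mat[ci, ii] = True
    return PresenceMatrix([f.id for f in final_contigs], individuals, mat,
                          species_of or {})


def classify_frequency(count: int, n: int) -> FrequencyClass:
    """Frequency class of a contig carried by `count` of `n` individuals.

    singleton: exactly one carrier; low: more than one but fewer than n/2;
    high: at least n/2 but not all; fixed: all n.
    """
    if not 1 <= count <= n:
        raise ValueError(f"count {count} outside 1..{n}")
    if count == n:
        label = "fixed"
    elif count == 1:
        label = "singleton"
    elif count < n / 2:
        label = "low"
    else:
        label = "high"
    return FrequencyClass(label, count, n)


def rare_common(freq: float, cutoff: float = 0.05) -> str:
    """Rare iff carrier frequency <= cutoff (inclusive), else common."""
    if not 0 < freq <= 1:
        raise ValueError(f"frequency {freq} outside (0, 1]")
    return "rare" if freq <= cutoff else "common"


@dataclass
class SharingSummary:
    species_sets: dict[str, frozenset]        # contig -> species with a carrier
    venn: dict[frozenset, int]                # species subset -> contig count
    single_species: list[str]
    multi_species: list[str]
    carriers_per_species: dict[str, list[int]]


def species_sharing(matrix: PresenceMatrix) -> SharingSummary:
    """Per-contig species sets, Venn cell counts and sharing partition."""
    if not matrix.species_of:
        raise ValueError("presence matrix has no species labels")
    species = sorted(set(matrix.species_of.values()))
    ind_species = [matrix.species_of[i] for i in matrix.individual_ids]
    sets: dict[str, frozenset] = {}
    venn: dict[frozenset, int] = {}
    single, multi = [], []
    per_species: dict[str, list[int]] = {s: [] for s in species}
    for ci, cid in enumerate(matrix.contig_ids):
        row = matrix.present[ci]
        s = frozenset(sp for sp, p in zip(ind_species, row) if p)
        sets[cid] = s
        if s:
            venn[s] = venn.get(s, 0) + 1
            (single if len(s) == 1 else multi).append(cid)
        for sp in species:
            per_species[sp].append(
                int(sum(1 for isp, p in zip(ind_species, row)
                        if p and isp == sp)))
    return SharingSummary(sets, venn, single, multi, per_species)


def frequency_table(matrix: PresenceMatrix, rare_cutoff: float = 0.05
                    ) -> pd.DataFrame:
    """Per-contig carrier counts, classes and rare/common calls."""
    rows = []
    for cid, count in matrix.carrier_counts().items():
        if count == 0:
            rows.append(dict(contig_id=cid, count=0, n=matrix.n, freq=0.0,
                             frequency_class="absent", rarity="absent"))
            continue
        fc = classify_frequency(count, matrix.n)
        rows.append(dict(contig_id=cid, count=count, n=matrix.n,
                         freq=round(fc.freq, 6), frequency_class=fc.label,
                         rarity=rare_common(fc.freq, rare_cutoff)))
    return pd.DataFrame(rows)
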