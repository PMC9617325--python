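"""Genomic-context classification of placed insertions.

Each insertion point is tested against a gene annotation and classified as
gene body (inside a gene), regulator region (within the 5 kb window upstream
of a gene's transcription start, strand-aware) or intergenic (no hit).  One
insertion may hit several genes; all hits are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_io import GeneModel
from .placement import PlacedContig


@dataclass(frozen=True)
class ContextHit:
    contig_id: str
    chrom: str
    pos: int
    context: str          # gene_body | upstream | intergenic
    gene_id: str = ""


def upstream_interval(gene: GeneModel, upstream_len: int = 5000
                      ) -> tuple[int, int]:
    """The regulator window of a gene, half-open, clamped at zero.

    For a "+" gene spanning [start, end) this is [start - upstream_len,
    start); for "-" it is [end, end + upstream_len).  With the half-open
    convention a point exactly upstream_len bases before the start is
    inside the window.
    """
    iv = gene.interval
    if iv.strand == "+":
        return max(0, iv.start - upstream_len), iv.start
    return iv.end, iv.end + upstream_len


def classify_context(placement: PlacedContig, genes: Sequence[GeneModel],
                     upstream_len: int = 5000) -> list[ContextHit]:
    """All gene-relative classifications of one insertion point.

    Returns one hit per (gene, relation); a single record with context
    "intergenic" if the point touches no gene body or upstream window.
    """
    hits: list[ContextHit] = []
    pos = placement.insert_pos
    for g in genes:
        iv = g.interval
        if iv.chrom != placement.chrom:
            continue
        if iv.start <= pos < iv.end:
            hits.append(ContextHit(placement.contig_id, placement.chrom, pos,
                                   "gene_body", g.gene_id))
        us, ue = upstream_interval(g, upstream_len)
        if us <= pos < ue:
            hits.append(ContextHit(placement.contig_id, placement.chrom, pos,
                                   "upstream", g.gene_id))
    if not hits:
        hits.append(ContextHit(placement.contig_id, placement.chrom, pos,
                               "intergenic"))
    return hits


def classify_all(placements: Iterable[PlacedContig],
                 genes: Sequence[GeneModel],
                 upstream_len: int = 5000) -> list[ContextHit]:
    out: list[ContextHit] = []
    for p in placements:
        out.extend(classify_context(p, genes, upstream_len))
    return out


def affected_gene_lists(reports: Iterable[ContextHit]
                        ) -> tuple[list[str], list[str]]:
    """Deduplicated (gene-body-hit, upstream-hit) gene id lists.

    A gene hit in its body by one insertion and upstream by another appears
    in both lists.
    """
    body: dict[str, None] = {}
    upstream: dict[str, None] = {}
    for h in reports:
        if h.context == "gene_body":
            body.setdefault(h.gene_id)
        elif h.context == "upstream":
            upstream.setdefault(h.gene_id)
    return sorted(body), sorted(upstream)
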