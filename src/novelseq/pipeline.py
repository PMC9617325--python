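"""File-mediated pipeline stages and the in-memory end-to-end driver.

Every stage reads and writes plain files, so stages can be rerun or replaced
independently (imported SAM alignments instead of the built-in mapper,
an external assembly instead of the built-in assembler).  ``discover`` runs
the whole chain in memory and is what the validation experiment and the
acceptance measurements use.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import assembly, cluster_filter, mapping, placement, simulate
from .assembly import NovelContig
from .core_io import (GenomicInterval, PipelineConfig, ReferenceGenome,
                      SeqRecord, log, read_fasta, read_fastq, read_sam,
                      write_bed, write_fasta, write_fastq, write_tsv)
from .placement import PlacedContig


@dataclass
class DiscoveryResult:
    n_pairs: int
    unaligned: mapping.UnalignedSets
    contigs: list[NovelContig]
    placed_raw: list[PlacedContig]
    unplaced_raw: list[NovelContig]
    final_placed: list[PlacedContig]
    final_unplaced: list[NovelContig]


def discover(reference: ReferenceGenome,
             reads1: Sequence[SeqRecord], reads2: Sequence[SeqRecord],
             cfg: Optional[PipelineConfig] = None,
             map_k: int = 21, asm_k: int = 31,
             pairs: Optional[list] = None,
             external_contigs: Optional[list[SeqRecord]] = None,
             individual_id: str = "") -> DiscoveryResult:
    """Run mapping, extraction, assembly, placement and filtering in memory.

    ``pairs`` (pre-aligned ReadPairs, e.g. from SAM) bypasses the built-in
    mapper; ``external_contigs`` bypasses the built-in assembler.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.time()
    if pairs is None:
        pairs = mapping.map_reads(reference, reads1, reads2, k=map_k)
        log(f"mapped {len(pairs)} pairs in {time.time() - t0:.1f}s")
    unaligned = mapping.extract_unaligned(pairs)
    log(f"extracted {len(unaligned.paired_unaligned)} both-unmapped pairs, "
        f"{len(unaligned.unpaired_unaligned)} unpaired unaligned reads")
    if external_contigs is None:
        raw = assembly.assemble(unaligned.all_reads(), k=asm_k)
    else:
        raw = external_contigs
    contigs = assembly.filter_contigs(raw, cfg, individual_id=individual_id)
    log(f"assembled {len(raw)} contigs, {len(contigs)} pass the "
        f"> {cfg.min_contig_len} bp filter")
    placed_raw, unplaced_raw = placement.place_contigs(
        contigs, unaligned, reference, cfg)
    log(f"placed {len(placed_raw)} contig ends/contigs, "
        f"{len(unplaced_raw)} unplaced")
    final_placed, final_unplaced = cluster_filter.finalize_sets(
        placed_raw, unplaced_raw, reference, cfg)
    log(f"final: {len(final_placed)} placed, {len(final_unplaced)} unplaced "
        f"({time.time() - t0:.1f}s total)")
    return DiscoveryResult(len(pairs), unaligned, contigs, placed_raw,
                           unplaced_raw, final_placed, final_unplaced)


# ---------------------------------------------------------------------------
# file-based stages


def stage_simulate(cfg: simulate.SimConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref, truth, hap, r1, r2 = simulate.simulate_experiment(cfg)
    write_fasta([ref], out / "reference.fa")
    write_fasta([hap], out / "haplotype.fa")
    write_fastq(r1, out / "reads_1.fq")
    write_fastq(r2, out / "reads_2.fq")
    write_tsv(
        [dict(insertion_id=t.insertion_id, ref_chrom=ref.id,
              ref_pos=t.ref_pos, hap_pos=t.hap_pos, length=t.length,
              sequence=t.sequence) for t in truth],
        out / "truth.tsv",
        ["insertion_id", "ref_chrom", "ref_pos", "hap_pos", "length",
         "sequence"])
    return dict(n_insertions=len(truth), n_pairs=len(r1))


def stage_extract(reference_fa, out_dir, fastq1=None, fastq2=None,
                  sam=None, map_k: int = 21) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sam is not None:
        pairs = list(read_sam(sam))
    else:
        reference = ReferenceGenome(read_fasta(reference_fa))
        pairs = mapping.map_reads(reference, read_fastq(fastq1),
                                  read_fastq(fastq2), k=map_k)
    un = mapping.extract_unaligned(pairs)
    write_fastq([p.read1 for p in un.paired_unaligned],
                out / "unaligned_paired_1.fq")
    write_fastq([p.read2 for p in un.paired_unaligned],
                out / "unaligned_paired_2.fq")
    write_fastq(un.unpaired_unaligned, out / "unaligned_unpaired.fq")
    write_tsv(
        [dict(read_id=rid, chrom=iv.chrom, start=iv.start, end=iv.end,
              strand=iv.strand) for rid, iv in un.anchor_pairs.items()],
        out / "anchors.tsv", ["read_id", "chrom", "start", "end", "strand"])
    return dict(n_pairs=len(pairs),
                n_paired_unaligned=len(un.paired_unaligned),
                n_unpaired_unaligned=len(un.unpaired_unaligned))


def load_unaligned(extract_dir) -> mapping.UnalignedSets:
    d = Path(extract_dir)
    un = mapping.UnalignedSets()
    p1 = read_fastq(d / "unaligned_paired_1.fq")
    p2 = read_fastq(d / "unaligned_paired_2.fq")
    for r1, r2 in zip(p1, p2):
        pid = r1.id[:-2] if r1.id.endswith("/1") else r1.id
        un.paired_unaligned.append(mapping.ReadPair(pid, r1, r2))
    un.unpaired_unaligned = read_fastq(d / "unaligned_unpaired.fq")
    with open(d / "anchors.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            un.anchor_pairs[row["read_id"]] = GenomicInterval(
                row["chrom"], int(row["start"]), int(row["end"]),
                row["strand"])
    return un


def stage_assemble(extract_dir, out_dir, cfg: Optional[PipelineConfig] = None,
                   asm_k: int = 31, import_fasta=None,
                   individual_id: str = "") -> dict:
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if import_fasta is not None:
        raw = read_fasta(import_fasta)
    else:
        un = load_unaligned(extract_dir)
        raw = assembly.assemble(un.all_reads(), k=asm_k)
    contigs = assembly.filter_contigs(raw, cfg, individual_id=individual_id)
    write_fasta([c.to_seqrecord() for c in contigs], out / "contigs.fa")
    write_tsv(
        [dict(contig_id=r.id, length=len(r.seq),
              kept=int(any(c.contig_id.endswith(r.id) for c in contigs)))
         for r in raw],
        out / "contig_filter.tsv", ["contig_id", "length", "kept"])
    return dict(n_raw=len(raw), n_kept=len(contigs))


def stage_place(reference_fa, contigs_fa, extract_dir, out_dir,
                cfg: Optional[PipelineConfig] = None) -> dict:
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = ReferenceGenome(read_fasta(reference_fa))
    contigs = [NovelContig(r.id, r.seq) for r in read_fasta(contigs_fa)]
    un = load_unaligned(extract_dir)
    placed, unplaced = placement.place_contigs(contigs, un, reference, cfg)
    write_placements(placed, out / "placements.tsv")
    write_bed(placed, out / "placements.bed", reference)
    write_fasta([c.to_seqrecord() for c in unplaced], out / "unplaced.fa")
    return dict(n_placed=len(placed), n_unplaced=len(unplaced))


def write_placements(placed: Sequence[PlacedContig], path) -> None:
    write_tsv(
        [dict(contig_id=p.contig_id, side=p.side, chrom=p.chrom,
              insert_pos=p.insert_pos, strand=p.strand,
              exact_match_len=p.exact_match_len, support=p.support,
              discordant=int(p.discordant)) for p in placed],
        path, ["contig_id", "side", "chrom", "insert_pos", "strand",
               "exact_match_len", "support", "discordant"])


def read_placements(path, seqs: Optional[dict[str, str]] = None
                    ) -> list[PlacedContig]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(PlacedContig(
                row["contig_id"], row["side"], row["chrom"],
                int(row["insert_pos"]), row["strand"],
                int(row["exact_match_len"]), int(row["support"]),
                seq=(seqs or {}).get(row["contig_id"], ""),
                discordant=bool(int(row.get("discordant", "0")))))
    return out


def stage_cluster(reference_fa, placements_tsv, contigs_fa, unplaced_fa,
                  out_dir, cfg: Optional[PipelineConfig] = None) -> dict:
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = ReferenceGenome(read_fasta(reference_fa))
    seqs = {r.id: r.seq for r in read_fasta(contigs_fa)}
    placed = read_placements(placements_tsv, seqs)
    unplaced = [NovelContig(r.id, r.seq) for r in read_fasta(unplaced_fa)]
    final_placed, final_unplaced = cluster_filter.finalize_sets(
        placed, unplaced, reference, cfg)
    write_fasta([SeqRecord(p.contig_id, p.final_seq) for p in final_placed],
                out / "final_placed.fa")
    write_placements(final_placed, out / "final_placed.tsv")
    write_bed(final_placed, out / "final_placed.bed", reference)
    write_fasta([c.to_seqrecord() for c in final_unplaced],
                out / "final_unplaced.fa")
    return dict(n_final_placed=len(final_placed),
                n_final_unplaced=len(final_unplaced))


def stage_pav(final_placed_fa, final_unplaced_fa, individual_fastas: dict,
              species_map: dict, out_dir, rare_cutoff: float = 0.05) -> dict:
    from . import pav as pav_mod
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    final = read_fasta(final_placed_fa) + read_fasta(final_unplaced_fa)
    per_ind = {ind: [NovelContig(r.id, r.seq, individual_id=ind)
                     for r in read_fasta(fa)]
               for ind, fa in individual_fastas.items()}
    matrix = pav_mod.call_presence(per_ind, final, species_of=species_map)
    matrix.to_frame().to_csv(out / "presence_matrix.tsv", sep="\t")
    pav_mod.frequency_table(matrix, rare_cutoff).to_csv(
        out / "frequency_classes.tsv", sep="\t", index=False)
    if species_map:
        sharing = pav_mod.species_sharing(matrix)
        write_tsv(
            [dict(contig_id=c, species=",".join(sorted(s)),
                  n_species=len(s)) for c, s in sharing.species_sets.items()],
            out / "species_sharing.tsv", ["contig_id", "species", "n_species"])
    return dict(n_final=len(final), n_individuals=len(per_ind))


def stage_effects(placements_tsv, gff_path, out_dir,
                  upstream_len: int = 5000) -> dict:
    from . import effects as eff
    from .core_io import read_gff3
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    placed = read_placements(placements_tsv)
    genes = read_gff3(gff_path)
    hits = eff.classify_all(placed, genes, upstream_len)
    write_tsv(
        [dict(contig_id=h.contig_id, chrom=h.chrom, pos=h.pos,
              context=h.context, gene_id=h.gene_id) for h in hits],
        out / "effects.tsv", ["contig_id", "chrom", "pos", "context",
                              "gene_id"])
    body, upstream = eff.affected_gene_lists(hits)
    write_tsv([dict(gene_id=g, relation="gene_body") for g in body]
              + [dict(gene_id=g, relation="upstream") for g in upstream],
              out / "affected_genes.tsv", ["gene_id", "relation"])
    return dict(n_hits=len(hits), n_body_genes=len(body),
                n_upstream_genes=len(upstream))


# ---------------------------------------------------------------------------
# run-all


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(out_dir, sim_cfg: Optional[simulate.SimConfig] = None,
            cfg: Optional[PipelineConfig] = None,
            reference_fa=None, fastq1=None, fastq2=None, sam=None,
            contigs_fa=None, gff=None) -> dict:
    """End-to-end driver: optional simulation, then every discovery stage.

    With sim_cfg the inputs are generated; otherwise reference_fa plus
    either FASTQs or a SAM must be given.  A manifest with the
    configuration, seed, per-stage counts and output hashes is written.
    """
    cfg = cfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict] = {}
    if sim_cfg is not None:
        counts["simulate"] = stage_simulate(sim_cfg, out / "sim")
        reference_fa = out / "sim" / "reference.fa"
        fastq1, fastq2 = out / "sim" / "reads_1.fq", out / "sim" / "reads_2.fq"
    if reference_fa is None:
        raise ValueError("need a reference (or sim_cfg) to run the pipeline")
    counts["extract"] = stage_extract(reference_fa, out / "extract",
                                      fastq1=fastq1, fastq2=fastq2, sam=sam)
    counts["assemble"] = stage_assemble(out / "extract", out / "assemble",
                                        cfg, import_fasta=contigs_fa)
    counts["place"] = stage_place(reference_fa, out / "assemble" / "contigs.fa",
                                  out / "extract", out / "place", cfg)
    counts["cluster"] = stage_cluster(
        reference_fa, out / "place" / "placements.tsv",
        out / "assemble" / "contigs.fa", out / "place" / "unplaced.fa",
        out / "cluster", cfg)
    if gff is not None:
        counts["effects"] = stage_effects(
            out / "cluster" / "final_placed.tsv", gff, out / "effects")
    manifest = dict(
        seed=sim_cfg.rng_seed if sim_cfg is not None else cfg.rng_seed,
        pipeline_config=vars(cfg),
        sim_config=vars(sim_cfg) if sim_cfg is not None else None,
        stage_counts=counts,
        files={str(p.relative_to(out)): _sha256(p)
               for p in sorted(out.rglob("*")) if p.is_file()
               and p.name != "manifest.json"},
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
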