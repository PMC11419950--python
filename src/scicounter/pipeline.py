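"""End-to-end orchestration: demux -> regions -> assignments -> counts ->
organelle -> cell calling -> pseudobulk.

Stages are pure functions over explicit files: each stage reads its inputs
from disk, writes its outputs, and can be skipped on resume when its
outputs already exist.  Region-level work is parallelizable with worker
processes; results are independent of the worker count because regions are
processed as independent units and re-sorted afterwards.
"""

from __future__ import annotations

import multiprocessing
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from scicounter import assignments as asg
from scicounter import cells as cells_mod
from scicounter import counting, demux, gtf, organelle, regions as regions_mod
from scicounter.models import GenomicInterval, ReadAssignment, TranscriptModel


@dataclass
class RunConfig:
    sample_id: str
    out_dir: str
    fastq: list[str] = field(default_factory=list)
    gtf_path: Optional[str] = None
    known_assignments: Optional[str] = None
    novel_assignments: Optional[str] = None
    organelle_alignments: Optional[str] = None
    organelle_chroms: list[str] = field(default_factory=list)
    group_file: Optional[str] = None
    adapter: str = "TCAGACGATG"
    bc_len: int = 16
    umi_len: int = 12
    min_reads: int = 20
    max_droplets: int = 100_000
    whitelist: Optional[str] = None
    region_target: int = regions_mod.DEFAULT_TARGET
    region_free_window: int = regions_mod.DEFAULT_FREE_WINDOW
    short_frac: float = 0.5
    cell_lower: int = 100
    cell_n_iter: int = 1000
    cell_fdr: float = 0.01
    pseudobulk_flavor: str = "weighted"
    seed: int = 0
    workers: int = 1

    def validate(self) -> None:
        for path in [
            *self.fastq,
            self.gtf_path,
            self.known_assignments,
            self.novel_assignments,
            self.organelle_alignments,
            self.group_file,
            self.whitelist,
        ]:
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"input does not exist: {path}")
        if not (0 < self.short_frac <= 1):
            raise ValueError("short_frac must be in (0, 1]")


def _outputs_exist(paths: Sequence[str]) -> bool:
    return all(os.path.exists(p) for p in paths)


def _partition_by_region(
    rows: Sequence[ReadAssignment], region_list: Sequence[GenomicInterval]
) -> list[list[ReadAssignment]]:
    buckets: list[list[ReadAssignment]] = [[] for _ in region_list]
    index = {}
    for i, r in enumerate(region_list):
        index.setdefault(r.chrom, []).append((r.start, r.end, i))
    leftover: list[ReadAssignment] = []
    for row in rows:
        pos = row.aligned_span.start
        placed = False
        for start, end, i in index.get(row.chrom, []):
            if start <= pos < end:
                buckets[i].append(row)
                placed = True
                break
        if not placed:
            leftover.append(row)
    if leftover:
        buckets.append(leftover)
    return [b for b in buckets if b]


def _process_one_region(args) -> list:
    rows, short_frac = args
    processed, _ = asg.process_assignments(rows, short_frac=short_frac)
    return processed


def process_by_region(
    rows: Sequence[ReadAssignment],
    region_list: Sequence[GenomicInterval],
    short_frac: float = 0.5,
    workers: int = 1,
) -> list[ReadAssignment]:
    """Resolve assignments per region and concatenate.

    Equals the unsplit run row-for-row after the final location sort,
    because region boundaries never cut through gene territory and hence
    never split a molecule block.
    """
    buckets = _partition_by_region(rows, region_list)
    jobs = [(b, short_frac) for b in buckets]
    if workers > 1 and len(jobs) > 1:
        with multiprocessing.Pool(workers) as pool:
            parts = pool.map(_process_one_region, jobs)
    else:
        parts = [_process_one_region(j) for j in jobs]
    merged = [row for part in parts for row in part]
    return list(asg.sort_by_location(merged))


def run_pipeline(config: RunConfig, resume: bool = False) -> dict[str, float]:
    """Execute every configured stage; returns the run summary metrics."""
    config.validate()
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    summary: dict[str, float] = {}

    # --- demux -------------------------------------------------------------
    tagged_path = os.path.join(out, "tagged.fastq")
    unmatched_path = os.path.join(out, "unmatched.fastq")
    summary_path = os.path.join(out, "barcode_summary.tsv")
    if config.fastq:
        if not (resume and _outputs_exist([tagged_path, unmatched_path, summary_path])):
            reads = []
            for path in config.fastq:
                reads.extend(demux.read_fastq(path))
            per_read = demux.extract_all(
                reads, config.adapter, config.bc_len, config.umi_len
            )
            table = demux.BarcodeCountTable.from_barcodes(
                bc for bc, _ in per_read.values()
            )
            whitelist = None
            if config.whitelist:
                with open(config.whitelist) as fh:
                    whitelist = frozenset(line.strip() for line in fh if line.strip())
            params = demux.DemuxParams(
                min_reads=config.min_reads,
                max_droplets=config.max_droplets,
                whitelist=whitelist,
            )
            assignment = demux.detect_droplets(table, params)
            assignment.validate()
            n_tag, n_un = demux.tag_fastq(
                config.fastq, per_read, assignment, tagged_path, unmatched_path
            )
            with open(summary_path, "w") as fh:
                fh.write("#barcode\treads\tn_absorbed\tstatus\n")
                for row in demux.barcode_summary(table, assignment):
                    fh.write("\t".join(map(str, row)) + "\n")
            summary["reads_in"] = n_tag + n_un
            summary["reads_tagged"] = n_tag
            summary["droplets_detected"] = len(assignment.droplet_barcodes)

    # --- regions -----------------------------------------------------------
    genes = []
    region_list: list[GenomicInterval] = []
    regions_path = os.path.join(out, "regions.bed")
    if config.gtf_path:
        genes = gtf.read_gtf(config.gtf_path)
        chrom_lengths: dict[str, int] = {}
        for g in genes:
            chrom_lengths[g.interval.chrom] = max(
                chrom_lengths.get(g.interval.chrom, 0), g.interval.end + 1000
            )
        region_list = regions_mod.split_regions(
            chrom_lengths, genes, config.region_target, config.region_free_window
        )
        if not (resume and _outputs_exist([regions_path])):
            gtf.write_bed(region_list, regions_path)
        summary["regions"] = len(region_list)

    # --- assignments + counting --------------------------------------------
    adapted_path = os.path.join(out, "assignments_adapted.tsv")
    iso_path = os.path.join(out, "counts", "isoform_counts.tsv")
    gene_path = os.path.join(out, "counts", "gene_counts.tsv")
    gene_counts = pd.DataFrame()
    iso_counts = pd.DataFrame()
    if config.known_assignments:
        if resume and _outputs_exist([adapted_path, iso_path, gene_path]):
            # round_trip parsing: resumed counts must equal the in-memory
            # floats exactly or downstream outputs would drift by ulps
            iso_counts = pd.read_csv(iso_path, sep="\t", float_precision="round_trip")
            gene_counts = pd.read_csv(gene_path, sep="\t", float_precision="round_trip")
        else:
            known = list(asg.read_assignment_table(config.known_assignments))
            novel = (
                list(asg.read_assignment_table(config.novel_assignments))
                if config.novel_assignments
                else []
            )
            merged = asg.merge_known_novel(known, novel)
            if region_list:
                rows = process_by_region(
                    merged, region_list, config.short_frac, config.workers
                )
                blocks = [
                    asg.resolve_block(b, config.short_frac)
                    for b in asg.group_blocks(asg.sort_by_molecule(merged))
                ]
            else:
                rows, blocks = asg.process_assignments(
                    merged, short_frac=config.short_frac
                )
            asg.write_assignment_table(rows, adapted_path)
            iso_counts = counting.count_isoforms(blocks)
            gene_counts = counting.count_genes(blocks)
            counting.write_counts(iso_counts, os.path.join(out, "counts"), "isoform")
            counting.write_counts(gene_counts, os.path.join(out, "counts"), "gene")
        summary["features_isoform"] = iso_counts["feature_id"].nunique() if len(iso_counts) else 0
        summary["features_gene"] = gene_counts["gene_id"].nunique() if len(gene_counts) else 0

    # --- organelle ----------------------------------------------------------
    org_path = os.path.join(out, "organelle_counts.tsv")
    org_asg_path = os.path.join(out, "organelle_assignments.tsv")
    if config.organelle_alignments:
        if not (resume and _outputs_exist([org_path, org_asg_path])):
            records = organelle.read_alignment_tsv(config.organelle_alignments)
            org_genes = [
                g for g in genes if g.interval.chrom in set(config.organelle_chroms)
            ] or genes
            pairs = organelle.assign_all(records, org_genes)
            org_counts = organelle.count_organelle(pairs)
            org_counts.to_csv(org_path, sep="\t", index=False)
            asg.write_assignment_table(
                organelle.organelle_to_assignments(pairs), org_asg_path
            )
            summary["organelle_genes"] = (
                org_counts["gene_id"].nunique() if len(org_counts) else 0
            )

    # --- cell calling -------------------------------------------------------
    cells_path = os.path.join(out, "cells.tsv")
    called: set[str] = set()
    if len(gene_counts):
        if resume and _outputs_exist([cells_path]):
            with open(cells_path) as fh:
                called = {line.strip() for line in fh if line.strip()}
        else:
            mat, _, barcodes = cells_mod.counts_to_profiles(gene_counts)
            try:
                result = cells_mod.call_cells(
                    mat,
                    barcodes,
                    cells_mod.CellCallParams(
                        lower=config.cell_lower,
                        n_iter=config.cell_n_iter,
                        fdr=config.cell_fdr,
                        seed=config.seed,
                    ),
                )
                called = result.cells
            except ValueError:
                # too few ambient barcodes to estimate a profile: keep all
                called = set(barcodes)
            with open(cells_path, "w") as fh:
                for bc in sorted(called):
                    fh.write(bc + "\n")
        summary["cells_called"] = len(called)

    # --- pseudobulk ---------------------------------------------------------
    pb_gene_path = os.path.join(out, "pseudobulk_gene.tsv")
    pb_iso_path = os.path.join(out, "pseudobulk_isoform.tsv")
    if len(gene_counts):
        if not (resume and _outputs_exist([pb_gene_path, pb_iso_path])):
            groups = (
                cells_mod.read_group_file(config.group_file)
                if config.group_file
                else {bc: "all" for bc in called}
            )
            keep_g = gene_counts[gene_counts["cell"].isin(called)] if called else gene_counts
            keep_i = iso_counts[iso_counts["cell"].isin(called)] if called else iso_counts
            gene_flavor = (
                config.pseudobulk_flavor
                if config.pseudobulk_flavor in keep_g.columns
                else "count"
            )
            cells_mod.write_pseudobulk(
                cells_mod.pseudobulk(keep_g, groups, gene_flavor), pb_gene_path
            )
            cells_mod.write_pseudobulk(
                cells_mod.pseudobulk(keep_i, groups, config.pseudobulk_flavor),
                pb_iso_path,
            )

    with open(os.path.join(out, "summary.tsv"), "w") as fh:
        fh.write("#metric\tvalue\n")
        for k in sorted(summary):
            fh.write(f"{k}\t{summary[k]:g}\n")
    return summary
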