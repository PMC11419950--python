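"""Split chromosomes into independent work units for parallel isoform calling.

Boundaries may only fall inside gene-free stretches of at least
``free_window`` bases and are placed at the stretch midpoint, guaranteeing
half a window of clearance on both sides so no read-scale alignment
straddles two regions.  Regions tile each chromosome exactly and each is at
least ``target`` long unless no legal boundary exists before the chromosome
end.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from scicounter.models import GeneModel, GenomicInterval

DEFAULT_TARGET = 5_000_000
DEFAULT_FREE_WINDOW = 250_000


def _merged_gene_spans(genes: Sequence[GeneModel], chrom: str) -> list[tuple[int, int]]:
    ivs = sorted(
        (g.interval.start, g.interval.end)
        for g in genes
        if g.interval.chrom == chrom
    )
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _free_runs(
    gene_spans: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Gene-free stretches of [0, length), in order."""
    runs = []
    cursor = 0
    for s, e in gene_spans:
        if s > cursor:
            runs.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < length:
        runs.append((cursor, length))
    return runs


def split_regions(
    chrom_lengths: Mapping[str, int],
    genes: Sequence[GeneModel],
    target: int = DEFAULT_TARGET,
    free_window: int = DEFAULT_FREE_WINDOW,
) -> list[GenomicInterval]:
    """Tile each chromosome into regions with gene-free boundaries.

    A legal split point is the midpoint of any gene-free run of at least
    ``free_window`` bases; a boundary is placed at the first legal midpoint
    at or beyond ``current_start + target`` (greedy left-to-right pass).
    """
    if target < 1 or free_window < 1:
        raise ValueError("target and free_window must be positive")
    for g in genes:
        chrom = g.interval.chrom
        if chrom not in chrom_lengths:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {chrom}")
        if g.interval.end > chrom_lengths[chrom]:
            raise ValueError(
                f"gene {g.gene_id} extends past the end of {chrom} "
                f"({g.interval.end} > {chrom_lengths[chrom]})"
            )

    regions: list[GenomicInterval] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        spans = _merged_gene_spans(genes, chrom)
        midpoints = [
            (s + e) // 2 for s, e in _free_runs(spans, length) if e - s >= free_window
        ]
        start = 0
        for mid in midpoints:
            if mid <= start or mid >= length:
                continue
            if mid - start >= target:
                regions.append(GenomicInterval(chrom, start, mid))
                start = mid
        regions.append(GenomicInterval(chrom, start, length))
    return regions


def region_of(
    regions: Sequence[GenomicInterval], chrom: str, pos: int
) -> GenomicInterval:
    """The region containing (chrom, pos); raises KeyError if none."""
    for r in regions:
        if r.chrom == chrom and r.contains_point(pos):
            return r
    raise KeyError(f"no region contains {chrom}:{pos}")
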