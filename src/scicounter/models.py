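"""Shared domain types.

All genomic coordinates are 0-based half-open internally; GTF input/output
converts to and from the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class TranscriptModel:
    """An exon structure on one strand of one chromosome.

    ``exons`` are sorted, pairwise disjoint intervals.  The intron chain —
    the ordered (donor, acceptor) pairs between consecutive exons — is the
    identity key used to match novel isoforms across samples.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start < prev.end:
                raise ValueError(
                    f"exons of {self.transcript_id} out of order or overlapping"
                )
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"exon on {e.chrom} but transcript on {self.chrom}"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def length(self) -> int:
        return sum(len(e) for e in self.exons)

    def chain_hash(self) -> str:
        """Stable short hash of the intron chain (empty chain hashes too)."""
        payload = ";".join(f"{d}-{a}" for d, a in self.intron_chain)
        return hashlib.md5(payload.encode()).hexdigest()[:8]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    strand: str
    is_rRNA: bool = False
    transcripts: tuple[TranscriptModel, ...] = ()

    def __post_init__(self) -> None:
        for t in self.transcripts:
            s = t.span
            if s.start < self.interval.start or s.end > self.interval.end:
                raise ValueError(
                    f"transcript {t.transcript_id} outside gene {self.gene_id}"
                )


@dataclass
class ReadAssignment:
    """One read's link to a transcript and/or gene.

    ``transcript_id`` set implies ``gene_id`` set.  ``covered_pct`` is the
    fraction of the assigned isoform covered by the read and is only
    meaningful when a transcript is assigned.  ``intronic`` marks reads that
    hit a gene without matching any of its isoforms.
    """

    read_name: str
    chrom: str
    strand: str
    aligned_span: GenomicInterval
    barcode: Optional[str] = None
    umi: Optional[str] = None
    transcript_id: Optional[str] = None
    gene_id: Optional[str] = None
    is_novel: bool = False
    assignment_events: str = "."
    covered_pct: float = 0.0
    inconsistency: int = 0
    polya_detected: bool = False
    intronic: bool = False
    # per-read correction factors, annotated by block resolution
    umicount: int = 1
    ambiguity: int = 1
    gambiguity: int = 1

    def __post_init__(self) -> None:
        if self.transcript_id is not None and self.gene_id is None:
            raise ValueError(
                f"{self.read_name}: transcript without gene assignment"
            )

    @property
    def aligned_length(self) -> int:
        return len(self.aligned_span)

    def block_key(self) -> tuple[str, str]:
        """Molecule grouping key: (barcode, umi), or the read name alone."""
        if self.barcode is not None and self.umi is not None:
            return (self.barcode, self.umi)
        return (self.read_name, "")


@dataclass
class MoleculeBlock:
    """All assignments sharing one (barcode, UMI) — one cDNA molecule.

    ``umicount`` is the number of distinct reads in the block; ``ambiguity``
    and ``gambiguity`` summarize the distinct transcripts and genes/loci
    among the retained assignments.
    """

    key: tuple[str, str]
    assignments: list[ReadAssignment] = field(default_factory=list)
    umicount: int = 0
    ambiguity: int = 0
    gambiguity: int = 0

    @property
    def barcode(self) -> Optional[str]:
        a = self.assignments[0] if self.assignments else None
        return a.barcode if a is not None else None

    def read_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.assignments:
            seen.setdefault(a.read_name, None)
        return list(seen)
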