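"""Gene-level counting for organelle chromosomes.

Organelle transcripts (mitochondrial, plastid) are mono-exonic and dense,
so isoform calling is bypassed: each read alignment's reference regions are
derived from its CIGAR string and matched against gene locations directly.
Only gene locations are held in memory; reads are processed one by one.

Each assigned read records how it relates to the gene:

* ``mono_exon_match`` — both alignment ends within 3 bases of the gene ends
* ``mono_exon_enclosed`` — alignment entirely inside the gene (not a match)
* ``mono_exon_overlap`` — overlapping at least 5 % of the gene

Overlap-only reads enter the weighted count but are excluded from unique
counts.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from scicounter.models import GeneModel, GenomicInterval, ReadAssignment

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

EVENT_MATCH = "mono_exon_match"
EVENT_ENCLOSED = "mono_exon_enclosed"
EVENT_OVERLAP = "mono_exon_overlap"
EVENT_NONE = "none"

_EVENT_RANK = {EVENT_MATCH: 0, EVENT_ENCLOSED: 1, EVENT_OVERLAP: 2, EVENT_NONE: 3}


@dataclass(frozen=True)
class AlignmentRecord:
    read_name: str
    chrom: str
    pos: int
    cigar: str
    barcode: Optional[str] = None
    umi: Optional[str] = None


@dataclass(frozen=True)
class OrganelleAssignment:
    read_name: str
    gene_id: Optional[str]
    event: str
    overlap_pct: float

    def __post_init__(self) -> None:
        if (self.event == EVENT_NONE) != (self.gene_id is None):
            raise ValueError("event 'none' iff no gene assigned")


def alignment_regions(cigar: str, pos: int) -> list[GenomicInterval]:
    """Maximal reference intervals covered by a CIGAR string starting at pos.

    M/=/X/D extend the current region, N (splice gap) closes it, and
    S/H/I/P consume no reference.  Raises ValueError with the character
    offset on malformed input.
    """
    if not cigar or cigar == "*":
        raise ValueError("empty CIGAR at offset 0")
    regions: list[tuple[int, int]] = []
    cursor = pos
    region_start = pos
    consumed = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != consumed:
            raise ValueError(f"malformed CIGAR at offset {consumed}: {cigar!r}")
        consumed = m.end()
        n, op = int(m.group(1)), m.group(2)
        if op in "M=XD":
            cursor += n
        elif op == "N":
            if cursor > region_start:
                regions.append((region_start, cursor))
            cursor += n
            region_start = cursor
        # S, H, I, P: no reference consumed
    if consumed != len(cigar):
        raise ValueError(f"malformed CIGAR at offset {consumed}: {cigar!r}")
    if cursor > region_start:
        regions.append((region_start, cursor))
    chrom_placeholder = "."  # chrom attached by the caller
    return [GenomicInterval(chrom_placeholder, s, e) for s, e in regions]


def _regions_for(aln: AlignmentRecord) -> list[GenomicInterval]:
    return [
        GenomicInterval(aln.chrom, r.start, r.end)
        for r in alignment_regions(aln.cigar, aln.pos)
    ]


def assign_organelle(
    aln: AlignmentRecord,
    genes: Sequence[GeneModel],
    min_read_overlap: float = 0.05,
    min_gene_overlap: float = 0.05,
    end_slop: int = 3,
) -> OrganelleAssignment:
    """Assign one alignment to the best-overlapping organelle gene.

    ``overlap_pct`` is the overlapping fraction of the read's aligned
    reference bases; a gene is a candidate when that fraction reaches
    ``min_read_overlap`` and the overlap also covers ``min_gene_overlap``
    of the gene.  Among candidates the non-rRNA gene with the highest
    overlap_pct wins; rRNA genes are used only when no non-rRNA candidate
    exists.
    """
    regions = _regions_for(aln)
    total_aligned = sum(len(r) for r in regions)
    if total_aligned == 0:
        return OrganelleAssignment(aln.read_name, None, EVENT_NONE, 0.0)
    aln_start, aln_end = regions[0].start, regions[-1].end

    candidates: list[tuple[float, GeneModel]] = []
    for g in genes:
        if g.interval.chrom != aln.chrom:
            continue
        ov = sum(r.overlap(g.interval) for r in regions)
        if ov == 0:
            continue
        pct = ov / total_aligned
        if pct >= min_read_overlap and ov >= min_gene_overlap * len(g.interval):
            candidates.append((pct, g))
    if not candidates:
        return OrganelleAssignment(aln.read_name, None, EVENT_NONE, 0.0)
    non_rrna = [c for c in candidates if not c[1].is_rRNA]
    pool = non_rrna if non_rrna else candidates
    pct, gene = max(pool, key=lambda c: (c[0], c[1].gene_id))

    gs, ge = gene.interval.start, gene.interval.end
    if abs(aln_start - gs) <= end_slop and abs(aln_end - ge) <= end_slop:
        event = EVENT_MATCH
    elif aln_start >= gs and aln_end <= ge:
        event = EVENT_ENCLOSED
    else:
        event = EVENT_OVERLAP
    return OrganelleAssignment(aln.read_name, gene.gene_id, event, pct)


def assign_all(
    alignments: Iterable[AlignmentRecord],
    genes: Sequence[GeneModel],
    **kwargs,
) -> list[tuple[AlignmentRecord, OrganelleAssignment]]:
    return [(a, assign_organelle(a, genes, **kwargs)) for a in alignments]


def count_organelle(
    pairs: Iterable[tuple[AlignmentRecord, OrganelleAssignment]],
) -> pd.DataFrame:
    """Per-cell organelle gene counts from (alignment, assignment) pairs.

    Weighted ``count``: each assigned read adds 1/umicount to its gene, so
    a molecule contributes unit mass.  ``unique``: molecules whose reads
    agree on one gene with at least one match/enclosed event (overlap-only
    molecules are excluded).
    """
    # per-molecule summaries only; memory bounded by molecule count
    molecules: dict[tuple, dict] = defaultdict(
        lambda: {"cell": ".", "reads": {}, "genes": set()}
    )
    for aln, asg in pairs:
        if asg.gene_id is None:
            continue
        if aln.barcode is not None and aln.umi is not None:
            key = (aln.barcode, aln.umi)
            cell = aln.barcode
        else:
            key = (aln.read_name, "")
            cell = "."
        mol = molecules[key]
        mol["cell"] = cell
        mol["reads"][aln.read_name] = (asg.gene_id, asg.event)
        mol["genes"].add(asg.gene_id)

    acc: dict[tuple[str, str], list[float]] = defaultdict(lambda: [0.0, 0])
    for mol in molecules.values():
        umicount = len(mol["reads"])
        for gene_id, _ in mol["reads"].values():
            acc[(gene_id, mol["cell"])][0] += 1.0 / umicount
        if len(mol["genes"]) == 1:
            (gene_id,) = mol["genes"]
            best = min(
                (_EVENT_RANK[ev] for _, ev in mol["reads"].values()), default=3
            )
            if best < _EVENT_RANK[EVENT_OVERLAP]:
                acc[(gene_id, mol["cell"])][1] += 1
    rows = [
        {"gene_id": g, "cell": c, "count": v[0], "unique": int(v[1])}
        for (g, c), v in acc.items()
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "cell", "count", "unique"])
    return df.sort_values(["gene_id", "cell"], ignore_index=True)


def organelle_to_assignments(
    pairs: Iterable[tuple[AlignmentRecord, OrganelleAssignment]],
) -> list[ReadAssignment]:
    """Express organelle assignments in the adapted read-assignment dialect."""
    out = []
    for aln, asg in pairs:
        if asg.gene_id is None:
            continue
        regions = _regions_for(aln)
        out.append(
            ReadAssignment(
                read_name=aln.read_name,
                chrom=aln.chrom,
                strand="+",
                aligned_span=GenomicInterval(
                    aln.chrom, regions[0].start, regions[-1].end
                ),
                barcode=aln.barcode,
                umi=aln.umi,
                transcript_id=asg.gene_id,
                gene_id=asg.gene_id,
                assignment_events=asg.event,
                covered_pct=asg.overlap_pct,
            )
        )
    return out


# ---------------------------------------------------------------------------
# plain-text I/O (SAM-convention fields as TSV)


def read_alignment_tsv(path: str) -> list[AlignmentRecord]:
    """Read records as TSV: read_name, chrom, pos, cigar[, barcode, umi]."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            bc = parts[4] if len(parts) > 4 and parts[4] != "." else None
            umi = parts[5] if len(parts) > 5 and parts[5] != "." else None
            out.append(
                AlignmentRecord(
                    read_name=parts[0],
                    chrom=parts[1],
                    pos=int(parts[2]),
                    cigar=parts[3],
                    barcode=bc,
                    umi=umi,
                )
            )
    return out


def write_alignment_tsv(records: Iterable[AlignmentRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#read_name\tchrom\tpos\tcigar\tbarcode\tumi\n")
        for r in records:
            fh.write(
                f"{r.read_name}\t{r.chrom}\t{r.pos}\t{r.cigar}\t"
                f"{r.barcode or '.'}\t{r.umi or '.'}\n"
            )
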