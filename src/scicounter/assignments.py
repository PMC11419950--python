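"""Read-assignment post-processing.

Consumes read-to-isoform assignment tables in a tab-separated dialect
(``#``-prefixed header; columns read_id, chrom, strand, isoform_id,
gene_id, assignment_type, assignment_events, exons, additional_info),
merges reference (known) and novel-model calls, renames novel features by
genomic locus so independently processed regions never collide, groups rows
into per-molecule blocks keyed by (barcode, UMI), filters uninformative
assignments within a block, and annotates the correction factors
(umicount, ambiguity, gambiguity) that drive the counting formulas.

Coordinates in the exons column are 0-based half-open, matching the rest of
the package.
"""

from __future__ import annotations

import gzip
import heapq
import os
import pickle
import tempfile
from typing import Callable, Iterable, Iterator, Optional, Sequence

from scicounter.models import (
    GenomicInterval,
    MoleculeBlock,
    ReadAssignment,
    TranscriptModel,
)

ADAPTED_COLUMNS = [
    "read_id", "chrom", "strand", "isoform_id", "gene_id",
    "assignment_type", "assignment_events", "exons",
    "barcode", "umi", "covered_pct", "polya", "inconsistency",
    "umicount", "ambiguity", "gambiguity",
]

NOVEL_TX_PREFIX = "novelt_"
NOVEL_GENE_PREFIX = "novelg_"


def _opener(path: str | os.PathLike, mode: str = "rt"):
    path = str(path)
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def parse_tagged_name(name: str) -> tuple[Optional[str], Optional[str], str]:
    """Split ``<barcode>_<umi>_<rest>`` read names; (None, None, name) if untagged."""
    parts = name.split("_", 2)
    if len(parts) == 3 and parts[0] and parts[1]:
        bc, umi = parts[0], parts[1]
        if all(c in "ACGTN" for c in bc) and all(c in "ACGTN" for c in umi):
            return bc, umi, parts[2]
    return None, None, name


def _parse_exons(chrom: str, text: str) -> tuple[GenomicInterval, ...]:
    out = []
    for token in text.split(","):
        if not token or token == ".":
            continue
        s, e = token.split("-")
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return tuple(out)


def _format_exons(blocks: Sequence[GenomicInterval]) -> str:
    return ",".join(f"{b.start}-{b.end}" for b in blocks) or "."


# ---------------------------------------------------------------------------
# dialect reading / writing


def read_assignment_table(path: str | os.PathLike) -> Iterator[ReadAssignment]:
    """Stream a raw or adapted assignment table (gzip transparent)."""
    with _opener(path) as fh:
        header: Optional[list[str]] = None
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                raise ValueError(f"{path}: missing '#'-prefixed header")
            yield _row_to_assignment(dict(zip(header, line.split("\t"))))


def _row_to_assignment(row: dict[str, str]) -> ReadAssignment:
    read_id = row["read_id"]
    chrom = row["chrom"]
    exons = _parse_exons(chrom, row.get("exons", "."))
    if exons:
        span = GenomicInterval(chrom, exons[0].start, exons[-1].end)
    else:
        raise ValueError(f"read {read_id}: assignment without aligned exons")
    tx = row.get("isoform_id", ".")
    gene = row.get("gene_id", ".")
    tx = None if tx in {".", ""} else tx
    gene = None if gene in {".", ""} else gene
    barcode = row.get("barcode") or None
    umi = row.get("umi") or None
    if barcode in {".", ""}:
        barcode = None
    if umi in {".", ""}:
        umi = None
    info = row.get("additional_info", "")
    kv = {}
    for token in info.split(";"):
        token = token.strip()
        if "=" in token:
            k, v = token.split("=", 1)
            kv[k.strip()] = v.strip()
    if barcode is None and umi is None:
        barcode, umi, _ = parse_tagged_name(read_id)
    covered = row.get("covered_pct") or kv.get("covered_pct", "")
    polya = row.get("polya") or kv.get("PolyA", "")
    inconsistency = row.get("inconsistency") or kv.get("inconsistency", "0")
    events = row.get("assignment_events", ".") or "."
    atype = row.get("assignment_type", ".")
    ra = ReadAssignment(
        read_name=read_id,
        chrom=chrom,
        strand=row.get("strand", "+"),
        aligned_span=span,
        barcode=barcode,
        umi=umi,
        transcript_id=tx,
        gene_id=gene,
        is_novel=bool(tx) and (tx.startswith(NOVEL_TX_PREFIX) or kv.get("novel") == "True"),
        assignment_events=events,
        covered_pct=float(covered) if covered not in {"", "."} else 0.0,
        inconsistency=int(float(inconsistency)) if inconsistency not in {"", "."} else 0,
        polya_detected=str(polya).lower() in {"true", "1", "yes"},
        intronic="intronic" in atype or "intronic" in events,
    )
    if "umicount" in row:
        ra.umicount = int(row["umicount"])
        ra.ambiguity = int(row["ambiguity"])
        ra.gambiguity = int(row["gambiguity"])
    return ra


def write_assignment_table(
    rows: Iterable[ReadAssignment], path: str | os.PathLike
) -> int:
    """Write the adapted dialect with correction-factor columns."""
    n = 0
    with _opener(path, "wt") as fh:
        fh.write("#" + "\t".join(ADAPTED_COLUMNS) + "\n")
        for ra in rows:
            fh.write(
                "\t".join(
                    [
                        ra.read_name,
                        ra.chrom,
                        ra.strand,
                        ra.transcript_id or ".",
                        ra.gene_id or ".",
                        "intronic" if ra.intronic else ("unique" if ra.ambiguity == 1 else "ambiguous"),
                        ra.assignment_events or ".",
                        f"{ra.aligned_span.start}-{ra.aligned_span.end}",
                        ra.barcode or ".",
                        ra.umi or ".",
                        f"{ra.covered_pct:.4f}",
                        str(ra.polya_detected),
                        str(ra.inconsistency),
                        str(ra.umicount),
                        str(ra.ambiguity),
                        str(ra.gambiguity),
                    ]
                )
                + "\n"
            )
            n += 1
    return n


# ---------------------------------------------------------------------------
# novel-feature renaming


def novel_ids_for(model: TranscriptModel) -> tuple[str, str]:
    """Locus-stable (transcript_id, gene_id) for a novel model.

    The transcript ID embeds the span plus an intron-chain hash, so models
    discovered independently in different region partitions coincide while
    distinct chains at one locus never collide.
    """
    s = model.span
    base = f"{s.chrom}_{s.start}_{s.end}_{model.strand}"
    return (
        f"{NOVEL_TX_PREFIX}{base}_{model.chain_hash()}",
        f"{NOVEL_GENE_PREFIX}{base}",
    )


def rename_novel(
    assignments: Iterable[ReadAssignment],
    models: Iterable[TranscriptModel],
) -> tuple[list[ReadAssignment], list[TranscriptModel], dict[str, str]]:
    """Replace provisional novel IDs with locus-based stable IDs.

    ``models`` is the stream of novel transcript models; assignments whose
    transcript_id matches a model are rewritten (reference IDs pass through
    untouched).  Returns the rewritten streams and the old→new ID map.
    """
    tx_map: dict[str, str] = {}
    gene_map: dict[str, str] = {}
    new_models: list[TranscriptModel] = []
    for m in models:
        new_tx, new_gene = novel_ids_for(m)
        tx_map[m.transcript_id] = new_tx
        gene_map[m.gene_id] = new_gene
        new_models.append(
            TranscriptModel(
                transcript_id=new_tx,
                gene_id=new_gene,
                chrom=m.chrom,
                strand=m.strand,
                exons=m.exons,
            )
        )
    out: list[ReadAssignment] = []
    for ra in assignments:
        if ra.transcript_id in tx_map:
            ra.transcript_id = tx_map[ra.transcript_id]
            ra.gene_id = gene_map.get(ra.gene_id, ra.gene_id)
            ra.is_novel = True
        elif ra.gene_id in gene_map:
            ra.gene_id = gene_map[ra.gene_id]
            ra.is_novel = True
        out.append(ra)
    return out, new_models, tx_map


# ---------------------------------------------------------------------------
# known/novel merging


def _check_no_conflicts(rows: list[ReadAssignment], label: str) -> None:
    seen: set[tuple[str, Optional[str]]] = set()
    dups = []
    for r in rows:
        key = (r.read_name, r.transcript_id)
        if key in seen:
            dups.append(r.read_name)
        seen.add(key)
    if dups:
        raise ValueError(
            f"{label} table has conflicting duplicate rows for reads: "
            + ", ".join(sorted(set(dups))[:10])
        )


def merge_known_novel(
    known: Iterable[ReadAssignment],
    novel: Iterable[ReadAssignment],
) -> list[ReadAssignment]:
    """Unify reference and novel-model assignment tables.

    A read present in the novel table has its assignment replaced by the
    novel model's; every other read keeps its reference assignment.
    """
    known = list(known)
    novel = list(novel)
    _check_no_conflicts(known, "known")
    _check_no_conflicts(novel, "novel")
    novel_reads = {r.read_name for r in novel}
    out = [r for r in known if r.read_name not in novel_reads]
    out.extend(novel)
    return out


# ---------------------------------------------------------------------------
# sorting (chunked external merge sort, bounded memory)


def _external_sort(
    rows: Iterable[ReadAssignment],
    key: Callable[[ReadAssignment], tuple],
    chunk_size: int,
) -> Iterator[ReadAssignment]:
    """Stable external merge sort over pickled spill chunks."""
    chunks: list[str] = []
    buf: list[tuple[tuple, int, ReadAssignment]] = []
    serial = 0  # global input index keeps equal-key rows in input order
    try:
        for ra in rows:
            buf.append((key(ra), serial, ra))
            serial += 1
            if len(buf) >= chunk_size:
                buf.sort(key=lambda t: (t[0], t[1]))
                fd, path = tempfile.mkstemp(suffix=".chunk")
                with os.fdopen(fd, "wb") as fh:
                    pickle.dump(buf, fh)
                chunks.append(path)
                buf = []
        buf.sort(key=lambda t: (t[0], t[1]))
        if not chunks:
            for _, _, ra in buf:
                yield ra
            return

        def _load(path: str) -> Iterator[tuple[tuple, int, ReadAssignment]]:
            with open(path, "rb") as fh:
                yield from pickle.load(fh)

        streams = [_load(p) for p in chunks] + [iter(buf)]
        for _, _, ra in heapq.merge(*streams, key=lambda t: (t[0], t[1])):
            yield ra
    finally:
        for path in chunks:
            if os.path.exists(path):
                os.unlink(path)


def sort_by_molecule(
    rows: Iterable[ReadAssignment], chunk_size: int = 200_000
) -> Iterator[ReadAssignment]:
    """Sort by (barcode, umi, read_name) so molecule blocks are contiguous."""
    return _external_sort(
        rows, key=lambda r: (r.block_key(), r.read_name), chunk_size=chunk_size
    )


def sort_by_location(
    rows: Iterable[ReadAssignment], chunk_size: int = 200_000
) -> Iterator[ReadAssignment]:
    """Sort by genomic location for the final output table."""
    return _external_sort(
        rows,
        key=lambda r: (r.chrom, r.aligned_span.start, r.aligned_span.end, r.read_name),
        chunk_size=chunk_size,
    )


# ---------------------------------------------------------------------------
# molecule blocks


def group_blocks(
    rows_sorted: Iterable[ReadAssignment],
) -> Iterator[MoleculeBlock]:
    """Group molecule-sorted rows into blocks of one (barcode, UMI)."""
    current: Optional[MoleculeBlock] = None
    for ra in rows_sorted:
        key = ra.block_key()
        if current is None or key != current.key:
            if current is not None:
                yield current
            current = MoleculeBlock(key=key)
        current.assignments.append(ra)
    if current is not None:
        yield current


def _locus_key(ra: ReadAssignment) -> tuple:
    if ra.gene_id is not None:
        return ("gene", ra.gene_id)
    # locus bucket for gene-less assignments: chromosome + rounded start
    return ("locus", ra.chrom, ra.aligned_span.start // 10_000)


def resolve_block(block: MoleculeBlock, short_frac: float = 0.5) -> MoleculeBlock:
    """Filter uninformative assignments and annotate correction factors.

    Within one molecule, an assignment is dropped when (i) it hits no gene
    while another assignment in the block does, or (ii) its aligned length
    is below ``short_frac`` of the block's longest gene-bearing alignment.
    umicount / ambiguity / gambiguity are recomputed on the survivors;
    ambiguity and gambiguity are per read (the transcripts and genes/loci
    that read supports), umicount is the number of reads retaining at least
    one assignment.
    """
    if not block.assignments:
        raise ValueError("cannot resolve an empty block")
    survivors = list(block.assignments)
    if len(survivors) > 1:
        any_gene = any(a.gene_id is not None for a in survivors)
        if any_gene:
            survivors = [a for a in survivors if a.gene_id is not None]
            longest = max(a.aligned_length for a in survivors)
            survivors = [
                a for a in survivors
                if a.aligned_length >= short_frac * longest
            ] or survivors

    reads: dict[str, list[ReadAssignment]] = {}
    for a in survivors:
        reads.setdefault(a.read_name, []).append(a)
    umicount = len(reads)
    for per_read in reads.values():
        tx = {a.transcript_id for a in per_read if a.transcript_id is not None}
        loci = {_locus_key(a) for a in per_read}
        ambiguity = max(1, len(tx))
        gambiguity = max(1, len(loci))
        for a in per_read:
            a.umicount = umicount
            a.ambiguity = ambiguity
            a.gambiguity = gambiguity

    block_tx = {a.transcript_id for a in survivors if a.transcript_id is not None}
    block_loci = {_locus_key(a) for a in survivors}
    return MoleculeBlock(
        key=block.key,
        assignments=survivors,
        umicount=umicount,
        ambiguity=max(1, len(block_tx)),
        gambiguity=max(1, len(block_loci)),
    )


# ---------------------------------------------------------------------------
# end-to-end adaptation


def process_assignments(
    known: Iterable[ReadAssignment],
    novel: Iterable[ReadAssignment] = (),
    novel_models: Iterable[TranscriptModel] = (),
    short_frac: float = 0.5,
    chunk_size: int = 200_000,
) -> tuple[list[ReadAssignment], list[MoleculeBlock]]:
    """Merge, rename, block-resolve and position-sort assignment tables.

    Returns the final location-sorted rows plus the resolved molecule
    blocks that feed the counting step.
    """
    novel = list(novel)
    models = list(novel_models)
    if models:
        novel, _, _ = rename_novel(novel, models)
    merged = merge_known_novel(known, novel)
    blocks = [
        resolve_block(b, short_frac=short_frac)
        for b in group_blocks(sort_by_molecule(merged, chunk_size=chunk_size))
    ]
    rows = [a for b in blocks for a in b.assignments]
    return list(sort_by_location(rows, chunk_size=chunk_size)), blocks
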