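"""Droplet barcode detection, error correction, and FASTQ tagging.

The detector is a greedy pass over observed barcodes sorted by read count:
the most frequent free barcode is promoted to a droplet barcode, every free
barcode within Levenshtein distance 1 is absorbed onto it and removed, and
the procedure repeats with the next free barcode until its read count drops
below ``min_reads`` or ``max_droplets`` droplets exist.  With a whitelist,
only listed barcodes can be promoted; unlisted ones remain absorbable as
sequencing errors of a listed droplet.

Droplet barcodes are therefore pairwise at distance >= 2 by construction:
anything closer to an earlier droplet was absorbed before it could be
promoted.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import edlib

from scicounter.fastq import FastqRecord, read_fastq, write_fastq

_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def levenshtein_within_1(a: str, b: str) -> bool:
    """True iff the full Levenshtein distance between a and b is <= 1.

    Banded (cost cut-off 1) alignment; agrees with unbanded dynamic
    programming by construction of the band.
    """
    if a == b:
        return True
    if abs(len(a) - len(b)) > 1:
        return False
    return edlib.align(a, b, task="distance", k=1)["editDistance"] != -1


def _distance1_neighborhood(seq: str, alphabet: str = "ACGT") -> set[str]:
    """Every string within Levenshtein distance 1 of ``seq`` (incl. itself)."""
    out = {seq}
    for i in range(len(seq)):
        out.add(seq[:i] + seq[i + 1 :])
        for b in alphabet:
            out.add(seq[:i] + b + seq[i + 1 :])
    for i in range(len(seq) + 1):
        for b in alphabet:
            out.add(seq[:i] + b + seq[i:])
    return out


@dataclass
class BarcodeCountTable:
    """Observed barcode sequences with read counts.

    Sorted descending by count on construction, ties broken
    lexicographically, sequences unique.
    """

    entries: list[tuple[str, int]]

    def __post_init__(self) -> None:
        seqs = [s for s, _ in self.entries]
        if len(seqs) != len(set(seqs)):
            raise ValueError("duplicate barcode sequences in count table")
        if any(c < 1 for _, c in self.entries):
            raise ValueError("read counts must be positive")
        self.entries = sorted(self.entries, key=lambda e: (-e[1], e[0]))

    @classmethod
    def from_barcodes(cls, barcodes: Iterable[str]) -> "BarcodeCountTable":
        return cls(entries=list(Counter(barcodes).items()))

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class DemuxParams:
    min_reads: int = 20
    max_droplets: int = 100_000
    whitelist: Optional[frozenset[str]] = None
    n_batches: int = 50

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.max_droplets < 1:
            raise ValueError("max_droplets must be >= 1")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")


@dataclass
class DropletAssignment:
    """Result of droplet detection.

    ``member_map`` sends every observed barcode that was promoted or
    absorbed to its droplet barcode; ``unassigned`` holds the rest.
    """

    droplet_barcodes: list[str] = field(default_factory=list)
    member_map: dict[str, str] = field(default_factory=dict)
    unassigned: set[str] = field(default_factory=set)
    n_absorbed: dict[str, int] = field(default_factory=dict)

    def correct(self, observed: str) -> Optional[str]:
        return self.member_map.get(observed)

    def validate(self) -> None:
        """Check the structural invariants (cheap, neighborhood-based)."""
        droplets = set(self.droplet_barcodes)
        if not droplets.issubset(self.member_map.keys()):
            raise AssertionError("droplet barcode missing from member_map")
        for d in self.droplet_barcodes:
            if self.member_map[d] != d:
                raise AssertionError(f"droplet {d} does not map to itself")
        if not set(self.member_map.values()).issubset(droplets):
            raise AssertionError("member_map value is not a droplet barcode")
        if self.unassigned & self.member_map.keys():
            raise AssertionError("barcode both assigned and unassigned")
        # pairwise distance >= 2: no droplet inside another's distance-1 ball
        seen: set[str] = set()
        for d in self.droplet_barcodes:
            if d in seen:
                raise AssertionError(f"droplet {d} within distance 1 of another")
            seen |= _distance1_neighborhood(d)


def detect_droplets(
    counts: BarcodeCountTable, params: DemuxParams = DemuxParams()
) -> DropletAssignment:
    """Greedy droplet detection over a sorted barcode count table.

    The distance-1 search is an exact neighborhood-enumeration lookup
    (substitutions, insertions, deletions of the candidate), partitioned
    into ``params.n_batches`` batches; results are independent of the batch
    count.
    """
    assignment = DropletAssignment()
    free: dict[str, int] = {s: c for s, c in counts.entries}
    order = [s for s, _ in counts.entries]
    for seq in order:
        if seq not in free:
            continue  # absorbed earlier
        count = free[seq]
        if count < params.min_reads:
            break  # sorted order: nothing later can pass the floor
        if len(assignment.droplet_barcodes) >= params.max_droplets:
            break
        if params.whitelist is not None and seq not in params.whitelist:
            continue  # not promotable; stays available for absorption
        # promote and absorb the distance-1 neighborhood, in batches
        assignment.droplet_barcodes.append(seq)
        assignment.member_map[seq] = seq
        del free[seq]
        neighbors = sorted(_distance1_neighborhood(seq) - {seq})
        absorbed = 0
        batch_size = max(1, -(-len(neighbors) // params.n_batches))
        for start in range(0, len(neighbors), batch_size):
            for cand in neighbors[start : start + batch_size]:
                if cand in free:
                    assignment.member_map[cand] = seq
                    del free[cand]
                    absorbed += 1
        assignment.n_absorbed[seq] = absorbed
    assignment.unassigned = set(free)
    return assignment


# ---------------------------------------------------------------------------
# barcode/UMI extraction


def extract_barcode(
    read: FastqRecord,
    adapter: str,
    bc_len: int = 16,
    umi_len: int = 12,
    max_adapter_dist: int = 2,
    search_window: int = 200,
) -> Optional[tuple[str, str]]:
    """Locate the adapter and return the (barcode, UMI) preceding it.

    Read layout: ``[barcode][UMI][adapter][cDNA]``.  The adapter is searched
    within the first ``search_window`` nt of both strands allowing up to
    ``max_adapter_dist`` edits; returns None when it is absent or when too
    few bases precede it to hold barcode + UMI.
    """
    if bc_len < 1 or umi_len < 1:
        raise ValueError("bc_len and umi_len must be >= 1")
    for seq in (read.sequence, reverse_complement(read.sequence)):
        window = seq[:search_window]
        hit = edlib.align(
            adapter, window, mode="HW", task="locations", k=max_adapter_dist
        )
        if hit["editDistance"] == -1:
            continue
        start = hit["locations"][0][0]
        if start < bc_len + umi_len:
            continue
        barcode = seq[start - bc_len - umi_len : start - umi_len]
        umi = seq[start - umi_len : start]
        return barcode, umi
    return None


def extract_all(
    reads: Iterable[FastqRecord],
    adapter: str,
    bc_len: int = 16,
    umi_len: int = 12,
    max_adapter_dist: int = 2,
) -> dict[str, tuple[str, str]]:
    """Barcode/UMI per read name for every read where extraction succeeds."""
    out: dict[str, tuple[str, str]] = {}
    for read in reads:
        hit = extract_barcode(read, adapter, bc_len, umi_len, max_adapter_dist)
        if hit is not None:
            out[read.name] = hit
    return out


# ---------------------------------------------------------------------------
# FASTQ tagging


def tag_reads(
    reads: Iterable[FastqRecord],
    per_read_barcodes: dict[str, tuple[str, str]],
    assignment: DropletAssignment,
) -> Iterator[tuple[FastqRecord, bool]]:
    """Yield (record, matched) pairs with corrected barcodes in read names.

    A matched read is renamed ``<dropletBC>_<UMI>_<original name>`` and
    carries the same two values as a FASTQ comment; reads without an
    extractable or assignable barcode are yielded unmodified with
    ``matched=False``.
    """
    for rec in reads:
        hit = per_read_barcodes.get(rec.name)
        droplet = None
        if hit is not None:
            droplet = assignment.correct(hit[0])
        if droplet is None:
            yield rec, False
            continue
        umi = hit[1]
        yield (
            FastqRecord(
                name=f"{droplet}_{umi}_{rec.name}",
                sequence=rec.sequence,
                quality=rec.quality,
                comment=f"CB:Z:{droplet}\tUB:Z:{umi}",
            ),
            True,
        )


def tag_fastq(
    in_paths: Iterable[str | os.PathLike],
    per_read_barcodes: dict[str, tuple[str, str]],
    assignment: DropletAssignment,
    out_tagged: str | os.PathLike,
    out_unmatched: str | os.PathLike,
) -> tuple[int, int]:
    """Stream FASTQ files into tagged and unmatched outputs; returns counts."""

    def _stream() -> Iterator[FastqRecord]:
        for path in in_paths:
            yield from read_fastq(path)

    n_tagged = n_unmatched = 0
    tagged_recs: list[FastqRecord] = []
    unmatched_recs: list[FastqRecord] = []
    for rec, matched in tag_reads(_stream(), per_read_barcodes, assignment):
        if matched:
            tagged_recs.append(rec)
            n_tagged += 1
        else:
            unmatched_recs.append(rec)
            n_unmatched += 1
    write_fastq(tagged_recs, out_tagged)
    write_fastq(unmatched_recs, out_unmatched)
    return n_tagged, n_unmatched


def barcode_summary(
    counts: BarcodeCountTable, assignment: DropletAssignment
) -> list[tuple[str, int, int, str]]:
    """Rows (barcode, reads, n_absorbed, status) for the demux summary TSV."""
    rows = []
    droplets = set(assignment.droplet_barcodes)
    for seq, n in counts.entries:
        if seq in droplets:
            status = "droplet"
        elif seq in assignment.member_map:
            status = f"absorbed:{assignment.member_map[seq]}"
        else:
            status = "unassigned"
        rows.append((seq, n, assignment.n_absorbed.get(seq, 0), status))
    return rows
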