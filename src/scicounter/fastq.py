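"""Minimal FASTQ record handling (gzip-transparent via pysam)."""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import pysam


@dataclass
class FastqRecord:
    name: str
    sequence: str
    quality: str
    comment: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"record {self.name}: sequence/quality length mismatch")


def read_fastq(path: str | os.PathLike) -> Iterator[FastqRecord]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield FastqRecord(
                name=entry.name,
                sequence=entry.sequence,
                quality=entry.quality or "I" * len(entry.sequence),
                comment=entry.comment,
            )


def write_fastq(records: Iterable[FastqRecord], path: str | os.PathLike) -> int:
    """Write 4-line FASTQ records; gzip if the path ends in .gz. Returns count."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    n = 0
    with opener(path, "wt") as fh:
        for rec in records:
            header = f"@{rec.name}"
            if rec.comment:
                header += f" {rec.comment}"
            fh.write(f"{header}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n
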