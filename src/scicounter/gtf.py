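"""GTF reading/writing and BED output.

GTF uses 1-based inclusive coordinates; everything in memory is 0-based
half-open, so the conversion (start-1, end) happens here and nowhere else.
Parsing goes through :mod:`gffutils`.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils

from scicounter.models import GeneModel, GenomicInterval, TranscriptModel

RRNA_BIOTYPES = {"rRNA", "rRNA_pseudogene", "Mt_rRNA"}


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Load gene/transcript/exon features from a GTF file.

    Genes carrying a ``gene_biotype``/``gene_type`` attribute naming an rRNA
    biotype are flagged ``is_rRNA`` (used by the organelle counter).
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="transcript", order_by="start"):
            exons = tuple(
                GenomicInterval(e.seqid, e.start - 1, e.end)
                for e in db.children(t, featuretype="exon", order_by="start")
            )
            if not exons:
                continue
            transcripts.append(
                TranscriptModel(
                    transcript_id=t.id,
                    gene_id=g.id,
                    chrom=t.seqid,
                    strand=t.strand,
                    exons=exons,
                )
            )
        biotype = (
            g.attributes.get("gene_biotype", g.attributes.get("gene_type", [""]))
        )[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                interval=GenomicInterval(g.seqid, g.start - 1, g.end),
                strand=g.strand,
                is_rRNA=biotype in RRNA_BIOTYPES,
                transcripts=tuple(transcripts),
            )
        )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | os.PathLike) -> None:
    """Write gene/transcript/exon features in GTF (1-based inclusive)."""

    def attr(**kv: str) -> str:
        return " ".join(f'{k} "{v}";' for k, v in kv.items())

    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            biotype = "rRNA" if g.is_rRNA else "protein_coding"
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        "scicounter",
                        "gene",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        g.strand,
                        ".",
                        attr(gene_id=g.gene_id, gene_biotype=biotype),
                    ]
                )
                + "\n"
            )
            for t in g.transcripts:
                s = t.span
                fh.write(
                    "\t".join(
                        [
                            s.chrom,
                            "scicounter",
                            "transcript",
                            str(s.start + 1),
                            str(s.end),
                            ".",
                            t.strand,
                            ".",
                            attr(gene_id=g.gene_id, transcript_id=t.transcript_id),
                        ]
                    )
                    + "\n"
                )
                for e in t.exons:
                    fh.write(
                        "\t".join(
                            [
                                e.chrom,
                                "scicounter",
                                "exon",
                                str(e.start + 1),
                                str(e.end),
                                ".",
                                t.strand,
                                ".",
                                attr(
                                    gene_id=g.gene_id,
                                    transcript_id=t.transcript_id,
                                ),
                            ]
                        )
                        + "\n"
                    )


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as 3-column BED (0-based half-open, as in memory)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
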