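"""Synthetic inputs with ground truth for every pipeline stage.

The generator emulates a droplet-based long-read single-cell experiment at
desk scale: a skewed per-cell read depth (log-normal), an ambient-droplet
tail (geometric), 16 nt cell barcodes + 12 nt UMIs corrupted by
substitution/indel errors, truncated reads covering a variable fraction of
their isoform, polyA detection flags, and controlled multi-isoform /
multi-gene ambiguity in the read-assignment tables.  Every output is
deterministic per seed and comes with an exact truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from scicounter.fastq import FastqRecord
from scicounter.models import (
    GeneModel,
    GenomicInterval,
    ReadAssignment,
    TranscriptModel,
)

BASES = "ACGT"
#: fixed linker between the UMI and the cDNA body in simulated reads
LINKER = "TCAGACGATG"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    ``reads_per_cell_shape`` is the log-normal sigma of per-cell depth;
    ``error_rate`` is per-base with an 8:1:1 substitution:insertion:deletion
    split; the covered-fraction (truncation) model is Beta(alpha, beta)
    over (0, 1].
    """

    n_cells: int = 100
    n_ambient: int = 500
    barcode_length: int = 16
    umi_length: int = 12
    mean_reads_per_cell: float = 50.0
    reads_per_cell_shape: float = 0.6
    ambient_mean_reads: float = 3.0
    error_rate: float = 0.02
    truncation_alpha: float = 5.0
    truncation_beta: float = 1.0
    polya_rate: float = 0.8
    multi_isoform_frac: float = 0.10
    multi_gene_frac: float = 0.05
    umi_dup_rate: float = 0.20
    junk_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_ambient < 0:
            raise ValueError("need n_cells >= 1 and n_ambient >= 0")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be in [0, 1]")
        if not (0.0 <= self.polya_rate <= 1.0):
            raise ValueError("polya_rate must be in [0, 1]")
        if self.barcode_length < 1 or self.umi_length < 1:
            raise ValueError("barcode/UMI lengths must be positive")


def noiseless(config: SimConfig) -> SimConfig:
    """A copy of ``config`` with every noise source switched off."""
    return replace(
        config,
        error_rate=0.0,
        multi_isoform_frac=0.0,
        multi_gene_frac=0.0,
        junk_frac=0.0,
        truncation_alpha=math.inf,  # degenerate at covered fraction 1.0
        polya_rate=1.0,
    )


# ---------------------------------------------------------------------------
# barcode universe


def _neighborhood(seq: str) -> set[str]:
    """All sequences within Levenshtein distance 1 of ``seq`` (incl. itself)."""
    out = {seq}
    for i in range(len(seq)):
        out.add(seq[:i] + seq[i + 1 :])  # deletion
        for b in BASES:
            out.add(seq[:i] + b + seq[i + 1 :])  # substitution
    for i in range(len(seq) + 1):
        for b in BASES:
            out.add(seq[:i] + b + seq[i:])  # insertion
    return out


def make_barcode_universe(
    n: int, length: int, min_dist: int, seed: int
) -> list[str]:
    """``n`` distinct barcodes, pairwise Levenshtein distance >= ``min_dist``.

    Rejection sampling; for min_dist <= 3 candidate screening uses
    distance-1 neighborhood sets (two sequences are within distance 2 iff
    their distance-1 neighborhoods intersect), otherwise pairwise banded
    alignment.  Raises ``ValueError`` when the attempt budget is exhausted,
    which includes impossible requests (n > 4**length).
    """
    if min_dist < 1:
        raise ValueError("min_dist must be >= 1")
    if length < 1 or n < 0:
        raise ValueError("need positive length and non-negative n")
    if 4**length < n:
        raise ValueError(f"cannot draw {n} distinct {length}-mers")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    taken: set[str] = set()  # distance-(min_dist-1) exclusion zone
    budget = 200 * n + 1000
    use_neighborhoods = min_dist <= 3
    while len(accepted) < n:
        if budget <= 0:
            raise ValueError(
                f"attempt budget exhausted at {len(accepted)}/{n} barcodes "
                f"(length={length}, min_dist={min_dist})"
            )
        budget -= 1
        cand = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        if use_neighborhoods:
            if min_dist == 1:
                ok = cand not in taken
                zone = {cand}
            elif min_dist == 2:
                ok = cand not in taken
                zone = _neighborhood(cand)
            else:  # min_dist == 3
                zone = _neighborhood(cand)
                ok = taken.isdisjoint(zone)
            if not ok:
                continue
            taken |= zone
        else:
            k = min_dist - 1
            if any(
                edlib.align(cand, b, task="distance", k=k)["editDistance"] != -1
                for b in accepted
            ):
                continue
        accepted.append(cand)
    return accepted


# ---------------------------------------------------------------------------
# sequence-level corruption


_ERROR_KINDS = np.array([0, 1, 2])  # substitution, insertion, deletion
_ERROR_PROBS = np.array([0.8, 0.1, 0.1])


def corrupt(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    """Apply per-base errors (8:1:1 substitution:insertion:deletion)."""
    if error_rate <= 0.0:
        return seq
    out: list[str] = []
    for base in seq:
        if rng.random() >= error_rate:
            out.append(base)
            continue
        kind = rng.choice(_ERROR_KINDS, p=_ERROR_PROBS)
        if kind == 0:  # substitute with a different base
            choices = [b for b in BASES if b != base]
            out.append(choices[rng.integers(0, 3)])
        elif kind == 1:  # insert before
            out.append(BASES[rng.integers(0, 4)])
            out.append(base)
        # kind == 2: deletion — emit nothing
    return "".join(out)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _draw_covered_fraction(config: SimConfig, rng: np.random.Generator) -> float:
    if math.isinf(config.truncation_alpha):
        return 1.0
    frac = float(rng.beta(config.truncation_alpha, config.truncation_beta))
    return min(1.0, max(frac, 1e-3))


def _cell_depths(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    mu = math.log(config.mean_reads_per_cell) - config.reads_per_cell_shape**2 / 2
    raw = rng.lognormal(mean=mu, sigma=config.reads_per_cell_shape, size=config.n_cells)
    return np.maximum(1, np.rint(raw)).astype(int)


def _ambient_depths(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.n_ambient == 0:
        return np.zeros(0, dtype=int)
    p = 1.0 / max(1.0, config.ambient_mean_reads)
    return rng.geometric(p, size=config.n_ambient)


# ---------------------------------------------------------------------------
# tagged-read simulation


def simulate_tagged_reads(
    config: SimConfig,
    truth_expression: dict[str, float],
) -> tuple[list[FastqRecord], pd.DataFrame]:
    """Simulate raw droplet reads plus their exact ground truth.

    Each read is ``[barcode][UMI][linker][cDNA body]`` with per-base errors
    over the barcode/UMI/linker prefix; polyA-flagged reads end in a 25 nt
    A-tail.  The truth table links every read name to its true cell,
    UMI, feature, covered fraction, polyA flag and ambient status.
    """
    if not truth_expression:
        raise ValueError("truth_expression must be non-empty")
    rng = np.random.default_rng(config.seed)
    features = sorted(truth_expression)
    rates = np.array([truth_expression[f] for f in features], dtype=float)
    if (rates <= 0).any():
        raise ValueError("expression rates must be positive")
    probs = rates / rates.sum()

    universe = make_barcode_universe(
        config.n_cells + config.n_ambient, config.barcode_length, 3, config.seed
    )
    cells = universe[: config.n_cells]
    ambient = universe[config.n_cells :]
    depths = np.concatenate([_cell_depths(config, rng), _ambient_depths(config, rng)])
    is_ambient = [False] * config.n_cells + [True] * config.n_ambient

    records: list[FastqRecord] = []
    truth_rows: list[dict] = []
    serial = 0
    body_len_full = 400
    for barcode, depth, amb in zip(cells + ambient, depths, is_ambient):
        for _ in range(int(depth)):
            feature = features[rng.choice(len(features), p=probs)]
            umi = _random_seq(config.umi_length, rng)
            frac = _draw_covered_fraction(config, rng)
            polya = bool(rng.random() < config.polya_rate)
            name = f"r{serial:07d}"
            serial += 1
            prefix = corrupt(barcode + umi + LINKER, config.error_rate, rng)
            body = _random_seq(max(30, int(body_len_full * frac)), rng)
            if polya:
                body += "A" * 25
            seq = prefix + body
            records.append(FastqRecord(name=name, sequence=seq, quality="I" * len(seq)))
            truth_rows.append(
                {
                    "read_name": name,
                    "cell": barcode,
                    "umi": umi,
                    "feature": feature,
                    "covered_fraction": frac,
                    "polya": polya,
                    "is_ambient": amb,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_name", "cell", "umi", "feature",
            "covered_fraction", "polya", "is_ambient",
        ],
    )
    return records, truth


# ---------------------------------------------------------------------------
# annotation fixture


def make_annotation(
    n_genes: int,
    chrom: str = "chr1",
    chrom_length: int = 1_000_000,
    transcripts_per_gene: int = 2,
    seed: int = 0,
    rrna_genes: int = 0,
) -> list[GeneModel]:
    """Evenly spaced multi-exon genes with ``transcripts_per_gene`` isoforms.

    Isoforms of a gene share the first exon and differ in their intron
    chains, so multi-isoform ambiguity is constructible.  The last
    ``rrna_genes`` genes are flagged as rRNA (organelle tests).
    """
    rng = np.random.default_rng(seed)
    slot = chrom_length // max(1, n_genes)
    genes: list[GeneModel] = []
    for gi in range(n_genes):
        g_start = gi * slot + 1000
        gene_id = f"gene{gi:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        transcripts = []
        n_tx = max(1, transcripts_per_gene)
        gene_end = g_start
        for ti in range(n_tx):
            exons = []
            pos = g_start
            n_exons = 2 + ti  # distinct intron chains per isoform
            for _ in range(n_exons):
                exon_len = int(rng.integers(150, 400))
                exons.append(GenomicInterval(chrom, pos, pos + exon_len))
                pos += exon_len + int(rng.integers(100, 300))
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{gene_id}.t{ti}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            gene_end = max(gene_end, exons[-1].end)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(chrom, g_start, gene_end),
                strand=strand,
                is_rRNA=gi >= n_genes - rrna_genes,
                transcripts=tuple(transcripts),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# read-assignment table simulation


def simulate_assignment_table(
    config: SimConfig,
    annotation: Sequence[GeneModel],
) -> tuple[list[ReadAssignment], pd.DataFrame]:
    """Per-molecule read assignments in the post-demux dialect, plus truth.

    Emits controlled fractions of multi-isoform (ambiguity > 1) and
    multi-gene (gambiguity > 1) reads, UMI duplicates, sub-90 %% coverage
    reads from the truncation model, and short intergenic junk rows that the
    block-resolution filter must discard.  The truth table holds the exact
    per-cell molecule count per transcript and gene.
    """
    genes = [g for g in annotation if g.transcripts]
    if not genes:
        raise ValueError("annotation must contain at least one gene with transcripts")
    rng = np.random.default_rng(config.seed)
    cells = make_barcode_universe(
        config.n_cells, config.barcode_length, 3, config.seed
    )
    all_tx = [(g, t) for g in genes for t in g.transcripts]

    rows: list[ReadAssignment] = []
    truth_rows: list[dict] = []
    depths = _cell_depths(config, rng)
    mol_serial = 0
    for barcode, depth in zip(cells, depths):
        used_umis: set[str] = set()
        for _ in range(int(depth)):
            gene, tx = all_tx[rng.integers(0, len(all_tx))]
            umi = _random_seq(config.umi_length, rng)
            while umi in used_umis:
                umi = _random_seq(config.umi_length, rng)
            used_umis.add(umi)

            # the transcripts this molecule's reads will support
            support: list[tuple[GeneModel, TranscriptModel]] = [(gene, tx)]
            if (
                len(gene.transcripts) > 1
                and rng.random() < config.multi_isoform_frac
            ):
                others = [t for t in gene.transcripts if t is not tx]
                support.append((gene, others[rng.integers(0, len(others))]))
            if len(genes) > 1 and rng.random() < config.multi_gene_frac:
                other_genes = [g for g in genes if g is not gene]
                og = other_genes[rng.integers(0, len(other_genes))]
                support.append((og, og.transcripts[rng.integers(0, len(og.transcripts))]))

            n_reads = 1
            if rng.random() < config.umi_dup_rate:
                n_reads += int(rng.geometric(0.5))
            frac = _draw_covered_fraction(config, rng)
            polya = bool(rng.random() < config.polya_rate)
            for j in range(n_reads):
                read_name = f"{barcode}_{umi}_m{mol_serial:06d}r{j}"
                span_len = max(50, int(len(tx.span) * frac))
                span = GenomicInterval(
                    tx.chrom, tx.span.start, tx.span.start + span_len
                )
                for sg, st in support:
                    rows.append(
                        ReadAssignment(
                            read_name=read_name,
                            chrom=st.chrom,
                            strand=st.strand,
                            aligned_span=span,
                            barcode=barcode,
                            umi=umi,
                            transcript_id=st.transcript_id,
                            gene_id=sg.gene_id,
                            assignment_events="." ,
                            covered_pct=frac,
                            polya_detected=polya,
                        )
                    )
                if j == 0 and rng.random() < config.junk_frac:
                    # short intergenic fragment sharing the molecule's UMI
                    junk_len = max(30, span_len // 5)
                    junk_start = tx.span.end + 10_000
                    rows.append(
                        ReadAssignment(
                            read_name=f"{barcode}_{umi}_m{mol_serial:06d}j",
                            chrom=tx.chrom,
                            strand=tx.strand,
                            aligned_span=GenomicInterval(
                                tx.chrom, junk_start, junk_start + junk_len
                            ),
                            barcode=barcode,
                            umi=umi,
                            assignment_events="intergenic",
                        )
                    )
            truth_rows.append(
                {
                    "cell": barcode,
                    "transcript_id": tx.transcript_id,
                    "gene_id": gene.gene_id,
                    "umi": umi,
                    "n_reads": n_reads,
                    "covered_pct": frac,
                    "polya": polya,
                    "n_support": len(support),
                }
            )
            mol_serial += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "cell", "transcript_id", "gene_id", "umi",
            "n_reads", "covered_pct", "polya", "n_support",
        ],
    )
    return rows, truth


def truth_molecule_counts(truth: pd.DataFrame, by: str = "transcript_id") -> pd.DataFrame:
    """Exact molecules per (cell, feature) from a simulator truth table."""
    out = (
        truth.groupby(["cell", by], as_index=False)
        .size()
        .rename(columns={"size": "molecules", by: "feature_id"})
    )
    return out.sort_values(["cell", "feature_id"], ignore_index=True)


# ---------------------------------------------------------------------------
# organelle alignment fixture


def simulate_organelle_alignments(
    n_reads: int,
    chrom: str = "chrM",
    chrom_length: int = 16_000,
    seed: int = 0,
    barcodes: Optional[Sequence[str]] = None,
) -> list["AlignmentRecord"]:
    """Random spliced/clipped alignments on a small circular-genome-sized chrom.

    CIGARs mix soft clips, matches, insertions, deletions and occasional
    N gaps so the region parser and the overlap classifier see every
    reference-consuming and non-consuming operation.
    """
    from scicounter.organelle import AlignmentRecord

    rng = np.random.default_rng(seed)
    out: list[AlignmentRecord] = []
    for i in range(n_reads):
        pos = int(rng.integers(0, chrom_length - 200))
        parts: list[str] = []
        if rng.random() < 0.3:
            parts.append(f"{int(rng.integers(5, 30))}S")
        ref_left = chrom_length - pos
        n_segments = int(rng.integers(1, 3))
        for s in range(n_segments):
            m = int(rng.integers(40, min(400, max(41, ref_left))))
            parts.append(f"{m}M")
            ref_left -= m
            if rng.random() < 0.3:
                parts.append(f"{int(rng.integers(1, 10))}I")
            if rng.random() < 0.3 and ref_left > 20:
                d = int(rng.integers(1, 15))
                parts.append(f"{d}D")
                ref_left -= d
            if s < n_segments - 1:
                if ref_left > 300:
                    n = int(rng.integers(50, 250))
                    parts.append(f"{n}N")
                    ref_left -= n
                else:
                    break
        if rng.random() < 0.3:
            parts.append(f"{int(rng.integers(5, 30))}S")
        bc = barcodes[int(rng.integers(0, len(barcodes)))] if barcodes else None
        out.append(
            AlignmentRecord(
                read_name=f"org{i:06d}",
                chrom=chrom,
                pos=pos,
                cigar="".join(parts),
                barcode=bc,
                umi=_random_seq(12, rng) if bc else None,
            )
        )
    return out


def write_truth_tsv(truth: pd.DataFrame, path: str) -> None:
    truth.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cell-calling fixture


def simulate_cell_calling(
    n_ambient: int = 5000,
    n_cells: int = 100,
    n_genes: int = 50,
    ambient_mean_depth: float = 50.0,
    cell_depth_factor: float = 20.0,
    seed: int = 0,
):
    """Droplet gene profiles for cell-calling benchmarks.

    Ambient barcodes draw geometric depths and multinomial profiles from a
    shared ambient gene distribution (first half of the genes); planted
    cells express a disjoint program (second half) at
    ``cell_depth_factor`` times the ambient mean depth.  ``n_cells=0``
    gives a pure ambient-only null.

    Returns (genes x barcodes sparse matrix, barcode names, is_cell array).
    """
    import scipy.sparse

    rng = np.random.default_rng(seed)
    half = n_genes // 2
    ambient_props = np.zeros(n_genes)
    ambient_props[:half] = rng.dirichlet(np.ones(half) * 5.0)
    cell_props = np.zeros(n_genes)
    cell_props[half:] = 1.0 / (n_genes - half)

    ambient_depths = rng.geometric(1.0 / ambient_mean_depth, size=n_ambient)
    profiles = [rng.multinomial(t, ambient_props) for t in ambient_depths]
    cell_depth = int(round(ambient_mean_depth * cell_depth_factor))
    profiles += [rng.multinomial(cell_depth, cell_props) for _ in range(n_cells)]

    mat = scipy.sparse.csr_matrix(np.vstack(profiles).T)
    names = [f"ambient{i:05d}" for i in range(n_ambient)] + [
        f"cell{i:04d}" for i in range(n_cells)
    ]
    is_cell = np.array([False] * n_ambient + [True] * n_cells)
    return mat, names, is_cell
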