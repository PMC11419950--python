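"""Per-cell feature counting from resolved molecule blocks.

Isoform counts come in six flavors.  ``weighted`` adds 1/(ambiguity ×
umicount) for every read-to-transcript assignment, so each molecule
distributes exactly unit mass over the transcripts it supports.  ``unique``
counts molecules whose retained assignments support a single transcript;
``strict`` additionally requires a supporting read covering at least 90 %
of that transcript.  ``aweighted`` / ``aunique`` / ``astrict`` are the same
three restricted to reads with a detected polyA tail (evidence of an intact
3' end).

Gene counts: ``count`` adds 1/(gambiguity × umicount) per read and gene,
intronic reads included; ``nicount`` accrues the same weight only from
reads matching an isoform of the gene.
"""

from __future__ import annotations

import os
from collections import defaultdict
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from scicounter.models import MoleculeBlock

STRICT_COVERAGE = 0.90

ISOFORM_FLAVORS = ["weighted", "unique", "strict", "aweighted", "aunique", "astrict"]
GENE_FLAVORS = ["count", "nicount"]


def _block_cell(block: MoleculeBlock) -> str:
    bc = block.barcode
    return bc if bc is not None else "."


def count_isoforms(blocks: Iterable[MoleculeBlock]) -> pd.DataFrame:
    """Six-flavor per-cell transcript counts.

    Returns a tidy frame with columns feature_id, cell, weighted, unique,
    strict, aweighted, aunique, astrict (one row per observed pair).
    """
    acc: dict[tuple[str, str], np.ndarray] = defaultdict(lambda: np.zeros(6))
    for block in blocks:
        cell = _block_cell(block)
        per_read: dict[str, dict[str, tuple]] = {}
        for a in block.assignments:
            if a.transcript_id is None:
                continue
            acc[(a.transcript_id, cell)][0] += 1.0 / (a.ambiguity * a.umicount)
            if a.polya_detected:
                acc[(a.transcript_id, cell)][3] += 1.0 / (a.ambiguity * a.umicount)
            per_read.setdefault(a.read_name, {})[a.transcript_id] = (
                a.covered_pct,
                a.polya_detected,
            )
        # molecule-level unique/strict: all reads must agree on one transcript
        block_tx = {tx for txs in per_read.values() for tx in txs}
        if len(block_tx) != 1:
            continue
        (tx,) = block_tx
        covered = [info[tx][0] for info in per_read.values() if tx in info]
        polya_covered = [
            info[tx][0] for info in per_read.values() if tx in info and info[tx][1]
        ]
        key = (tx, cell)
        acc[key][1] += 1  # unique
        if max(covered) >= STRICT_COVERAGE:
            acc[key][2] += 1  # strict
        if polya_covered:
            acc[key][4] += 1  # aunique
            if max(polya_covered) >= STRICT_COVERAGE:
                acc[key][5] += 1  # astrict
    rows = [
        {"feature_id": f, "cell": c, **dict(zip(ISOFORM_FLAVORS, v))}
        for (f, c), v in acc.items()
    ]
    df = pd.DataFrame(rows, columns=["feature_id", "cell", *ISOFORM_FLAVORS])
    for col in ("unique", "strict", "aunique", "astrict"):
        if len(df):
            df[col] = df[col].astype(int)
    return df.sort_values(["feature_id", "cell"], ignore_index=True)


def count_genes(blocks: Iterable[MoleculeBlock]) -> pd.DataFrame:
    """Per-cell gene counts (``count`` and isoform-matching ``nicount``)."""
    acc: dict[tuple[str, str], np.ndarray] = defaultdict(lambda: np.zeros(2))
    for block in blocks:
        cell = _block_cell(block)
        # deduplicate per (read, gene): a read supports each gene once
        per_read_gene: dict[tuple[str, str], dict] = {}
        for a in block.assignments:
            if a.gene_id is None:
                continue
            slot = per_read_gene.setdefault(
                (a.read_name, a.gene_id),
                {"w": 1.0 / (a.gambiguity * a.umicount), "isoform": False},
            )
            if a.transcript_id is not None and not a.intronic:
                slot["isoform"] = True
        for (_, gene), slot in per_read_gene.items():
            acc[(gene, cell)][0] += slot["w"]
            if slot["isoform"]:
                acc[(gene, cell)][1] += slot["w"]
    rows = [
        {"gene_id": g, "cell": c, "count": v[0], "nicount": v[1]}
        for (g, c), v in acc.items()
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "cell", *GENE_FLAVORS])
    return df.sort_values(["gene_id", "cell"], ignore_index=True)


# ---------------------------------------------------------------------------
# output


def counts_to_matrix(
    df: pd.DataFrame,
    value_col: str,
    feature_col: Optional[str] = None,
) -> tuple[scipy.sparse.csr_matrix, list[str], list[str]]:
    """Tidy counts → (features × cells sparse matrix, features, cells)."""
    if feature_col is None:
        feature_col = "feature_id" if "feature_id" in df.columns else "gene_id"
    features = sorted(df[feature_col].unique())
    cells = sorted(df["cell"].unique())
    fi = {f: i for i, f in enumerate(features)}
    ci = {c: i for i, c in enumerate(cells)}
    mat = scipy.sparse.coo_matrix(
        (
            df[value_col].to_numpy(),
            (
                df[feature_col].map(fi).to_numpy(dtype=int),
                df["cell"].map(ci).to_numpy(dtype=int),
            ),
        ),
        shape=(len(features), len(cells)),
    ).tocsr()
    return mat, features, cells


def write_counts(
    df: pd.DataFrame,
    out_dir: str | os.PathLike,
    prefix: str,
    flavors: Optional[list[str]] = None,
) -> None:
    """Write the tidy TSV plus one MatrixMarket triplet per flavor."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    df.to_csv(os.path.join(out_dir, f"{prefix}_counts.tsv"), sep="\t", index=False)
    if not len(df):
        return
    if flavors is None:
        flavors = [c for c in (ISOFORM_FLAVORS + GENE_FLAVORS) if c in df.columns]
    feature_col = "feature_id" if "feature_id" in df.columns else "gene_id"
    mat0, features, cells = counts_to_matrix(df, flavors[0], feature_col)
    with open(os.path.join(out_dir, f"{prefix}_features.tsv"), "w") as fh:
        fh.write("\n".join(features) + "\n")
    with open(os.path.join(out_dir, f"{prefix}_barcodes.tsv"), "w") as fh:
        fh.write("\n".join(cells) + "\n")
    for flavor in flavors:
        mat, _, _ = counts_to_matrix(df, flavor, feature_col)
        scipy.io.mmwrite(os.path.join(out_dir, f"{prefix}_{flavor}.mtx"), mat)
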