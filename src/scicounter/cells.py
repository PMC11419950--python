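"""Cell calling, cell-type pseudobulk, and multi-sample merging.

Cell calling is a simplified ambient-profile test in the spirit of
EmptyDrops: barcodes at or below a depth threshold define the ambient RNA
profile; every deeper barcode receives a Monte Carlo p-value for the
deviation of its gene profile from multinomial draws of the ambient
profile at its own depth, followed by Benjamini-Hochberg control.
Barcodes above a pronounced knee in the ranked-depth curve are always
retained.  Exact parity with the published EmptyDrops implementation is
not claimed.

Pseudobulk sums a chosen count flavor over the cells of each cell type;
multi-sample tables merge novel isoforms across samples by intron chain.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from scicounter.models import TranscriptModel

UNASSIGNED_GROUP = "unassigned"


# ---------------------------------------------------------------------------
# cell calling


@dataclass(frozen=True)
class CellCallParams:
    lower: int = 100          # ambient depth threshold (total counts)
    n_iter: int = 1000        # Monte Carlo draws per tested depth
    fdr: float = 0.01         # Benjamini-Hochberg target
    seed: int = 0
    knee_prominence: float = 0.3  # required cliff height, log10 units
    knee_min_above: int = 5       # barcodes required above a knee

    def __post_init__(self) -> None:
        if self.lower < 1 or self.n_iter < 1:
            raise ValueError("lower and n_iter must be positive")
        if not (0.0 < self.fdr < 1.0):
            raise ValueError("fdr must be in (0, 1)")


@dataclass
class CellCallResult:
    cells: set[str]
    table: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    knee_total: Optional[float] = None


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg rejection mask."""
    if len(pvals) == 0:
        return np.zeros(0, dtype=bool)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject


def find_knee(
    totals: np.ndarray, prominence: float = 0.3, min_above: int = 5
) -> Optional[float]:
    """Knee of the ranked barcode depth curve, or None.

    The knee is the largest log10 jump between consecutive ranked totals
    with at least ``min_above`` barcodes above it.  A knee is only reported
    when that jump exceeds ``prominence`` log10 units: adjacent order
    statistics of a smooth ambient depth distribution sit close together,
    so an ambient-only curve has no knee, while a population of cells
    stacked well above the ambient tail produces a pronounced cliff.
    Returns the smallest total above the jump (retain totals >= knee).
    """
    totals = np.sort(np.asarray(totals, dtype=float))[::-1]
    totals = totals[totals > 0]
    if len(totals) <= min_above:
        return None
    y = np.log10(totals)
    gaps = y[min_above - 1 : -1] - y[min_above:]
    i = int(np.argmax(gaps))
    if gaps[i] < prominence:
        return None
    return float(totals[min_above - 1 + i])


def call_cells(
    profiles: scipy.sparse.spmatrix,
    barcodes: Sequence[str],
    params: CellCallParams = CellCallParams(),
) -> CellCallResult:
    """Distinguish cell-containing droplets from ambient-only ones.

    ``profiles`` is a genes x barcodes count matrix.  Barcodes with total
    count <= ``params.lower`` define the ambient profile and are never
    called; at least 10 such barcodes are required.
    """
    profiles = scipy.sparse.csc_matrix(profiles)
    if profiles.shape[1] != len(barcodes):
        raise ValueError("profiles/barcodes dimension mismatch")
    if len(barcodes) == 0:
        return CellCallResult(cells=set())
    totals = np.asarray(profiles.sum(axis=0)).ravel()
    ambient_mask = totals <= params.lower
    if int(ambient_mask.sum()) < 10:
        raise ValueError(
            f"only {int(ambient_mask.sum())} barcodes at or below "
            f"lower={params.lower}; ambient profile unestimable"
        )
    ambient = np.asarray(profiles[:, ambient_mask].sum(axis=1)).ravel()
    props = ambient + 1e-10
    props = props / props.sum()
    log_props = np.log(props)

    cand_idx = np.nonzero(~ambient_mask)[0]
    rng = np.random.default_rng(params.seed)
    pvals = np.ones(len(cand_idx))
    # group candidates by depth: one set of Monte Carlo draws per depth
    depth_groups: dict[int, list[int]] = {}
    for j, idx in enumerate(cand_idx):
        depth_groups.setdefault(int(totals[idx]), []).append(j)
    for depth in sorted(depth_groups):
        sims = rng.multinomial(depth, props, size=params.n_iter)
        sim_ll = (
            gammaln(depth + 1)
            - gammaln(sims + 1).sum(axis=1)
            + sims @ log_props
        )
        for j in depth_groups[depth]:
            obs = np.asarray(profiles[:, cand_idx[j]].todense()).ravel()
            obs_ll = (
                gammaln(depth + 1) - gammaln(obs + 1).sum() + obs @ log_props
            )
            pvals[j] = (1 + int((sim_ll <= obs_ll).sum())) / (params.n_iter + 1)

    reject = _bh_reject(pvals, params.fdr)
    # knee search runs above the ambient threshold only: the low tail of a
    # discrete depth distribution always ends in a 2 -> 1 jump
    knee_total = find_knee(
        totals[~ambient_mask], params.knee_prominence, params.knee_min_above
    )
    called = set()
    for j, idx in enumerate(cand_idx):
        if reject[j] or (knee_total is not None and totals[idx] >= knee_total):
            called.add(barcodes[idx])
    table = pd.DataFrame(
        {
            "barcode": [barcodes[i] for i in cand_idx],
            "total": totals[cand_idx],
            "pvalue": pvals,
            "significant": reject,
            "is_cell": [barcodes[i] in called for i in cand_idx],
        }
    )
    return CellCallResult(cells=called, table=table, knee_total=knee_total)


def counts_to_profiles(
    counts: pd.DataFrame,
    value_col: str = "count",
    exclude_novel: bool = True,
) -> tuple[scipy.sparse.csr_matrix, list[str], list[str]]:
    """Tidy gene counts -> (genes x barcodes matrix, genes, barcodes).

    Novel genes are excluded by default so ambient testing and typing run
    on the reference annotation only.
    """
    from scicounter.counting import counts_to_matrix

    feature_col = "gene_id" if "gene_id" in counts.columns else "feature_id"
    if exclude_novel:
        counts = counts[~counts[feature_col].str.startswith("novel")]
    mat, features, cells = counts_to_matrix(counts, value_col, feature_col)
    return mat, features, cells


# ---------------------------------------------------------------------------
# group files and pseudobulk


def read_group_file(path: str) -> dict[str, str]:
    """2-column TSV (cell, group), no header; duplicate cells are an error."""
    groups: dict[str, str] = {}
    dups = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cell, group = line.rstrip("\n").split("\t")[:2]
            if not group:
                raise ValueError(f"empty group for cell {cell}")
            if cell in groups:
                dups.append(cell)
            groups[cell] = group
    if dups:
        raise ValueError(f"duplicate cells in group file: {sorted(set(dups))[:10]}")
    return groups


def pseudobulk(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    flavor: str,
) -> pd.DataFrame:
    """Sum one count flavor over the cells of each group.

    Returns a wide table (feature index x group columns).  Cells missing
    from the group map aggregate under ``unassigned``.
    """
    if flavor not in counts.columns:
        raise ValueError(f"flavor {flavor!r} not among {list(counts.columns)}")
    feature_col = "feature_id" if "feature_id" in counts.columns else "gene_id"
    df = counts[[feature_col, "cell", flavor]].copy()
    df["group"] = df["cell"].map(lambda c: groups.get(c, UNASSIGNED_GROUP))
    wide = (
        df.pivot_table(
            index=feature_col, columns="group", values=flavor, aggfunc="sum", fill_value=0
        )
        .rename_axis(index="feature", columns=None)
        .sort_index()
    )
    return wide[sorted(wide.columns)]


# ---------------------------------------------------------------------------
# multi-sample merging


def _feature_sidecar_rows(models: Sequence[TranscriptModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        s = m.span
        rows.append(
            {
                "feature": m.transcript_id,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "strand": m.strand,
                "intron_chain": ";".join(f"{d}-{a}" for d, a in m.intron_chain),
                "novel": True,
            }
        )
    return pd.DataFrame(rows)


def _merged_novel_id(
    chrom: str, start: int, end: int, strand: str, chain: tuple
) -> str:
    payload = ";".join(f"{d}-{a}" for d, a in chain)
    h = hashlib.md5(payload.encode()).hexdigest()[:8]
    return f"novelt_{chrom}_{start}_{end}_{strand}_{h}"


def merge_samples(
    tables: Sequence[tuple[str, pd.DataFrame]],
    novel_models: Mapping[str, Sequence[TranscriptModel]] | None = None,
    end_tolerance: int = 50,
) -> pd.DataFrame:
    """Combine per-sample pseudobulk tables into one multi-sample table.

    Known features match by ID.  Novel spliced transcripts match across
    samples by (chrom, strand, exact intron chain); single-exon novel
    transcripts match when both ends agree within ``end_tolerance``.
    A merged row takes the union span across samples; its columns are
    ``<sample>__<group>`` with absent combinations set to 0.
    """
    if not tables:
        raise ValueError("need at least one sample")
    novel_models = novel_models or {}

    # collect all novel models, validate strand consistency per chain
    chain_strand: dict[tuple, str] = {}
    spliced: dict[tuple, list[TranscriptModel]] = {}
    mono: list[tuple[str, str, int, int, TranscriptModel]] = []
    for sample, models in novel_models.items():
        for m in models:
            chain = m.intron_chain
            if chain:
                key = (m.chrom, chain)
                if key in chain_strand and chain_strand[key] != m.strand:
                    raise ValueError(
                        f"conflicting strand for intron chain at {m.chrom}: "
                        f"{chain[:2]}..."
                    )
                chain_strand[key] = m.strand
                spliced.setdefault((m.chrom, m.strand, chain), []).append(m)
            else:
                s = m.span
                mono.append((m.chrom, m.strand, s.start, s.end, m))

    id_map: dict[str, str] = {}  # per-sample transcript_id -> merged id
    for (chrom, strand, chain), members in spliced.items():
        start = min(m.span.start for m in members)
        end = max(m.span.end for m in members)
        merged = _merged_novel_id(chrom, start, end, strand, chain)
        for m in members:
            id_map[m.transcript_id] = merged
    # single-exon: greedy clustering over the sorted union (order-invariant)
    mono.sort(key=lambda t: (t[0], t[1], t[2], t[3], t[4].transcript_id))
    cluster: list[tuple[str, str, int, int, TranscriptModel]] = []
    clusters: list[list] = []
    for item in mono:
        if (
            cluster
            and item[0] == cluster[0][0]
            and item[1] == cluster[0][1]
            and abs(item[2] - cluster[0][2]) <= end_tolerance
            and abs(item[3] - cluster[0][3]) <= end_tolerance
        ):
            cluster.append(item)
        else:
            if cluster:
                clusters.append(cluster)
            cluster = [item]
    if cluster:
        clusters.append(cluster)
    for members in clusters:
        chrom, strand = members[0][0], members[0][1]
        start = min(m[2] for m in members)
        end = max(m[3] for m in members)
        merged = _merged_novel_id(chrom, start, end, strand, ())
        for m in members:
            id_map[m[4].transcript_id] = merged

    pieces = []
    for sample, table in sorted(tables, key=lambda t: t[0]):
        t = table.copy()
        t.index = [id_map.get(f, f) for f in t.index]
        t = t.groupby(level=0).sum()
        t.columns = [f"{sample}__{c}" for c in t.columns]
        pieces.append(t)
    out = pd.concat(pieces, axis=1).fillna(0).sort_index()
    out.index.name = "feature"
    return out[sorted(out.columns)]


def write_pseudobulk(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index_label="feature")
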