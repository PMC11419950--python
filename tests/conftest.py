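"""Shared fixtures and independent reference oracles."""

from __future__ import annotations

import numpy as np
import pytest

from scicounter import fixtures
from scicounter.demux import BarcodeCountTable, DemuxParams


def levenshtein_dp(a: str, b: str) -> int:
    """Unbanded full dynamic-programming Levenshtein distance (oracle)."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def reference_detect_droplets(counts: BarcodeCountTable, params: DemuxParams):
    """O(n^2) greedy droplet detection using full-DP distances (oracle).

    Mirrors the documented procedure directly: promote the highest-count
    free barcode, absorb everything at distance <= 1, repeat.
    """
    free = dict(counts.entries)
    order = [s for s, _ in counts.entries]
    droplets: list[str] = []
    member: dict[str, str] = {}
    for seq in order:
        if seq not in free:
            continue
        if free[seq] < params.min_reads:
            break
        if len(droplets) >= params.max_droplets:
            break
        if params.whitelist is not None and seq not in params.whitelist:
            continue
        droplets.append(seq)
        member[seq] = seq
        del free[seq]
        for other in list(free):
            if levenshtein_dp(seq, other) <= 1:
                member[other] = seq
                del free[other]
    return droplets, member, set(free)


def random_barcode_table(
    rng: np.random.Generator, max_barcodes: int = 200, length: int = 8
) -> BarcodeCountTable:
    """A random observed-barcode table with clustered error barcodes."""
    n_true = int(rng.integers(3, max(4, max_barcodes // 4)))
    entries: dict[str, int] = {}
    bases = "ACGT"
    for _ in range(n_true):
        seq = "".join(bases[i] for i in rng.integers(0, 4, size=length))
        entries[seq] = entries.get(seq, 0) + int(rng.integers(1, 200))
    # sprinkle distance-1 corruptions of existing barcodes
    seqs = list(entries)
    while len(entries) < max_barcodes and len(entries) < 4 * n_true:
        src = seqs[int(rng.integers(0, len(seqs)))]
        i = int(rng.integers(0, len(src)))
        mutated = src[:i] + bases[int(rng.integers(0, 4))] + src[i + 1 :]
        if mutated not in entries:
            entries[mutated] = int(rng.integers(1, 30))
    return BarcodeCountTable(entries=list(entries.items()))


@pytest.fixture(scope="session")
def annotation():
    return fixtures.make_annotation(n_genes=6, chrom_length=600_000, seed=11)


@pytest.fixture(scope="session")
def sim_config():
    return fixtures.SimConfig(n_cells=25, mean_reads_per_cell=30, seed=7)


@pytest.fixture(scope="session")
def noisy_table(sim_config, annotation):
    return fixtures.simulate_assignment_table(sim_config, annotation)


@pytest.fixture(scope="session")
def noiseless_table(annotation):
    cfg = fixtures.noiseless(
        fixtures.SimConfig(n_cells=15, mean_reads_per_cell=25, seed=13)
    )
    return fixtures.simulate_assignment_table(cfg, annotation)
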