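"""Cell calling calibration, pseudobulk aggregation, cross-sample merging."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse

from scicounter import cells
from scicounter.cells import (
    CellCallParams,
    call_cells,
    find_knee,
    merge_samples,
    pseudobulk,
    read_group_file,
)
from scicounter.models import GenomicInterval, TranscriptModel


def ambient_matrix(rng, n_barcodes, n_genes=40, mean_depth=50.0):
    props = rng.dirichlet(np.ones(n_genes) * 5)
    totals = rng.geometric(1.0 / mean_depth, size=n_barcodes)
    mat = np.vstack([rng.multinomial(t, props) for t in totals]).T
    return scipy.sparse.csr_matrix(mat), props


class TestFindKnee:
    def test_smooth_ambient_curve_has_no_knee(self):
        rng = np.random.default_rng(1)
        totals = rng.geometric(1 / 50.0, size=3000)
        assert find_knee(totals[totals > 100]) is None

    def test_pronounced_cliff_detected(self):
        totals = np.concatenate([np.full(50, 5000.0), np.linspace(400, 101, 500)])
        knee = find_knee(totals)
        assert knee == 5000.0

    def test_tiny_input_has_no_knee(self):
        assert find_knee(np.array([10.0, 5.0])) is None


class TestCallCells:
    def test_empty_input(self):
        res = call_cells(scipy.sparse.csr_matrix((0, 0)), [])
        assert res.cells == set()

    def test_too_few_ambient_refused(self):
        mat = scipy.sparse.csr_matrix(np.full((5, 5), 100))
        with pytest.raises(ValueError, match="ambient"):
            call_cells(mat, [f"b{i}" for i in range(5)], CellCallParams(lower=10))

    def test_ambient_only_calls_at_most_fdr(self):
        rng = np.random.default_rng(7)
        mat, _ = ambient_matrix(rng, 2500)
        names = [f"b{i}" for i in range(2500)]
        res = call_cells(
            mat, names, CellCallParams(lower=100, n_iter=400, fdr=0.05, seed=1)
        )
        n_candidates = int((np.asarray(mat.sum(axis=0)).ravel() > 100).sum())
        assert len(res.cells) / max(1, n_candidates) <= 0.05 + 0.02

    def test_planted_cells_recovered(self):
        rng = np.random.default_rng(8)
        n_genes = 40
        amb_props = np.zeros(n_genes)
        amb_props[: n_genes // 2] = rng.dirichlet(np.ones(n_genes // 2) * 5)
        cell_props = np.zeros(n_genes)
        cell_props[n_genes // 2 :] = 1.0 / (n_genes // 2)
        amb = np.vstack(
            [rng.multinomial(t, amb_props) for t in rng.geometric(1 / 50.0, 2000)]
        )
        planted = np.vstack([rng.multinomial(1000, cell_props) for _ in range(50)])
        mat = scipy.sparse.csr_matrix(np.vstack([amb, planted]).T)
        names = [f"a{i}" for i in range(2000)] + [f"c{i}" for i in range(50)]
        res = call_cells(
            mat, names, CellCallParams(lower=100, n_iter=400, fdr=0.05, seed=2)
        )
        recall = sum(1 for n in res.cells if n.startswith("c")) / 50
        assert recall >= 0.95

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(9)
        mat, _ = ambient_matrix(rng, 800)
        names = [f"b{i}" for i in range(800)]
        p = CellCallParams(lower=100, n_iter=200, fdr=0.1, seed=5)
        assert call_cells(mat, names, p).cells == call_cells(mat, names, p).cells


class TestPseudobulk:
    COUNTS = pd.DataFrame(
        {
            "feature_id": ["T1"] * 3 + ["T2"] * 2,
            "cell": ["c1", "c2", "c3", "c1", "c4"],
            "weighted": [1.0, 2.0, 5.0, 1.0, 7.0],
        }
    )

    def test_direct_sum(self):
        groups = {"c1": "A", "c2": "A", "c3": "B", "c4": "B"}
        out = pseudobulk(self.COUNTS, groups, "weighted")
        assert out.loc["T1", "A"] == 3.0 and out.loc["T1", "B"] == 5.0
        assert out.loc["T2", "B"] == 7.0

    def test_missing_cell_goes_unassigned(self):
        out = pseudobulk(self.COUNTS, {"c1": "A", "c2": "A", "c3": "B"}, "weighted")
        assert out.loc["T2", "unassigned"] == 7.0

    def test_conservation(self):
        groups = {"c1": "A", "c2": "B", "c3": "B"}
        out = pseudobulk(self.COUNTS, groups, "weighted")
        assert out.to_numpy().sum() == self.COUNTS["weighted"].sum()

    def test_editing_groups_changes_only_affected_columns(self):
        g1 = {"c1": "A", "c2": "A", "c3": "B", "c4": "C"}
        g2 = {"c1": "A", "c2": "A", "c3": "B2", "c4": "C"}  # only c3 moved
        out1 = pseudobulk(self.COUNTS, g1, "weighted")
        out2 = pseudobulk(self.COUNTS, g2, "weighted")
        assert out1["A"].equals(out2["A"])
        assert out1["C"].equals(out2["C"])
        assert out1.loc["T1", "B"] == out2.loc["T1", "B2"]

    def test_unknown_flavor_rejected(self):
        with pytest.raises(ValueError, match="flavor"):
            pseudobulk(self.COUNTS, {}, "bogus")

    def test_duplicate_cell_in_group_file_rejected(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("c1\tA\nc1\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_group_file(str(path))

    def test_group_file_round_trip(self, tmp_path):
        path = tmp_path / "groups.tsv"
        path.write_text("c1\tneuron\nc2\tglia\n")
        assert read_group_file(str(path)) == {"c1": "neuron", "c2": "glia"}


def novel_model(tid, start, end, introns=((1200, 1400),), chrom="chr1", strand="+"):
    exon_bounds = []
    pos = start
    for d, a in introns:
        exon_bounds.append((pos, d))
        pos = a
    exon_bounds.append((pos, end))
    return TranscriptModel(
        transcript_id=tid,
        gene_id=tid.replace("t", "g"),
        chrom=chrom,
        strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exon_bounds),
    )


class TestMergeSamples:
    def _tables(self):
        t1 = pd.DataFrame({"A": [3.0, 1.0]}, index=["ENST1", "nov_s1"])
        t2 = pd.DataFrame({"A": [2.0, 4.0]}, index=["ENST1", "nov_s2"])
        models = {
            "s1": [novel_model("nov_s1", 1000, 2000)],
            "s2": [novel_model("nov_s2", 980, 2050)],
        }
        return [("s1", t1), ("s2", t2)], models

    def test_same_intron_chain_merges_with_union_span(self):
        tables, models = self._tables()
        out = merge_samples(tables, models)
        novel_rows = [f for f in out.index if f.startswith("novelt_")]
        assert len(novel_rows) == 1
        assert "chr1_980_2050" in novel_rows[0]
        assert out.loc[novel_rows[0], "s1__A"] == 1.0
        assert out.loc[novel_rows[0], "s2__A"] == 4.0

    def test_different_chains_stay_separate(self):
        tables, models = self._tables()
        models["s2"] = [novel_model("nov_s2", 980, 2050, introns=((1300, 1500),))]
        out = merge_samples(tables, models)
        assert len([f for f in out.index if f.startswith("novelt_")]) == 2

    def test_single_sample_prefixes_columns(self):
        t = pd.DataFrame({"A": [3.0]}, index=["ENST1"])
        out = merge_samples([("s1", t)])
        assert list(out.columns) == ["s1__A"]
        assert out.loc["ENST1", "s1__A"] == 3.0

    def test_sample_order_invariance(self):
        tables, models = self._tables()
        out1 = merge_samples(tables, models)
        out2 = merge_samples(list(reversed(tables)), models)
        pd.testing.assert_frame_equal(out1, out2)

    def test_conflicting_strand_rejected(self):
        tables, models = self._tables()
        models["s2"] = [novel_model("nov_s2", 980, 2050, strand="-")]
        with pytest.raises(ValueError, match="strand"):
            merge_samples(tables, models)

    def test_single_exon_end_tolerance(self):
        t1 = pd.DataFrame({"A": [1.0]}, index=["m1"])
        t2 = pd.DataFrame({"A": [2.0]}, index=["m2"])
        models = {
            "s1": [novel_model("m1", 1000, 2000, introns=())],
            "s2": [novel_model("m2", 1030, 2040, introns=())],
        }
        out = merge_samples([("s1", t1), ("s2", t2)], models, end_tolerance=50)
        assert len(out) == 1
        out_far = merge_samples(
            [("s1", t1), ("s2", t2)], models, end_tolerance=10
        )
        assert len(out_far) == 2

    def test_absent_combinations_are_zero(self):
        t1 = pd.DataFrame({"A": [3.0]}, index=["ENST1"])
        t2 = pd.DataFrame({"B": [2.0]}, index=["ENST2"])
        out = merge_samples([("s1", t1), ("s2", t2)])
        assert out.loc["ENST2", "s1__A"] == 0.0
        assert out.loc["ENST1", "s2__B"] == 0.0

    def test_conservation_through_merge(self):
        tables, models = self._tables()
        out = merge_samples(tables, models)
        assert out.to_numpy().sum() == sum(
            t.to_numpy().sum() for _, t in tables
        )

    def test_no_samples_rejected(self):
        with pytest.raises(ValueError):
            merge_samples([])
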