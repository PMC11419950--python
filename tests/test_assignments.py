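"""Assignment adaptation: renaming, merging, block resolution, sorting."""

import random

import pytest

from scicounter import assignments as asg
from scicounter import fixtures
from scicounter.models import GenomicInterval, MoleculeBlock, ReadAssignment, TranscriptModel
from scicounter.regions import split_regions


def ra(name, tx=None, gene=None, start=0, end=1000, bc="AAAA", umi="CCCC",
       chrom="chr1", covered=1.0, polya=False, intronic=False):
    return ReadAssignment(
        read_name=name, chrom=chrom, strand="+",
        aligned_span=GenomicInterval(chrom, start, end),
        barcode=bc, umi=umi, transcript_id=tx, gene_id=gene,
        covered_pct=covered, polya_detected=polya, intronic=intronic,
    )


def model(tid, gid, chrom="chr1", strand="+", exons=((1000, 1400), (1600, 2000))):
    return TranscriptModel(
        transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand,
        exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
    )


class TestRenameNovel:
    def test_same_model_from_two_regions_gets_one_id(self):
        m1 = model("transcript_7.region1", "gene_3.region1")
        m2 = model("transcript_12.region2", "gene_9.region2")
        _, models1, map1 = asg.rename_novel([], [m1])
        _, models2, map2 = asg.rename_novel([], [m2])
        assert models1[0].transcript_id == models2[0].transcript_id
        assert models1[0].gene_id == models2[0].gene_id

    def test_same_span_different_chains_distinct(self):
        m1 = model("t1", "g1", exons=((1000, 1400), (1600, 2000)))
        m2 = model("t2", "g2", exons=((1000, 1300), (1500, 2000)))
        _, out, _ = asg.rename_novel([], [m1, m2])
        assert out[0].transcript_id != out[1].transcript_id
        assert out[0].transcript_id.startswith("novelt_chr1_1000_2000_+_")

    def test_known_ids_pass_through(self):
        rows = [ra("r1", tx="ENST1", gene="ENSG1")]
        out, _, _ = asg.rename_novel(rows, [model("novel_x", "novelg_x")])
        assert out[0].transcript_id == "ENST1" and out[0].gene_id == "ENSG1"

    def test_assignments_follow_the_map(self):
        m = model("tx_novel", "g_novel")
        rows = [ra("r1", tx="tx_novel", gene="g_novel")]
        out, models, _ = asg.rename_novel(rows, [m])
        assert out[0].transcript_id == models[0].transcript_id
        assert out[0].is_novel


class TestMergeKnownNovel:
    def test_known_only_read_unchanged(self):
        out = asg.merge_known_novel([ra("r1", tx="T1", gene="G1")], [])
        assert [r.transcript_id for r in out] == ["T1"]

    def test_novel_assignment_wins(self):
        known = [ra("r1", tx="T1", gene="G1")]
        novel = [ra("r1", tx="novelt_x", gene="novelg_x")]
        out = asg.merge_known_novel(known, novel)
        assert [r.transcript_id for r in out] == ["novelt_x"]

    def test_conflicting_duplicates_rejected(self):
        rows = [ra("r1", tx="T1", gene="G1"), ra("r1", tx="T1", gene="G1")]
        with pytest.raises(ValueError, match="r1"):
            asg.merge_known_novel(rows, [])

    def test_multi_assignment_is_not_a_conflict(self):
        rows = [ra("r1", tx="T1", gene="G1"), ra("r1", tx="T2", gene="G1")]
        assert len(asg.merge_known_novel(rows, [])) == 2


class TestResolveBlock:
    def _block(self, rows):
        return MoleculeBlock(key=rows[0].block_key(), assignments=list(rows))

    def test_intergenic_dropped_when_gene_present(self):
        rows = [
            ra("r1", tx="T1", gene="G1", start=0, end=900),
            ra("r2", start=5000, end=5150),  # intergenic, short
        ]
        out = asg.resolve_block(self._block(rows))
        assert [a.read_name for a in out.assignments] == ["r1"]
        assert out.umicount == 1 and out.ambiguity == 1

    def test_significantly_shorter_dropped(self):
        rows = [
            ra("r1", tx="T1", gene="G1", start=0, end=900),
            ra("r2", tx="T2", gene="G2", start=0, end=300),  # < 50% of 900
        ]
        out = asg.resolve_block(self._block(rows))
        assert [a.transcript_id for a in out.assignments] == ["T1"]

    def test_singleton_block_untouched(self):
        out = asg.resolve_block(self._block([ra("r1", tx="T1", gene="G1")]))
        assert out.umicount == 1 and out.ambiguity == 1 and out.gambiguity == 1

    def test_three_reads_same_umi_unique_transcript(self):
        rows = [ra(f"r{i}", tx="T1", gene="G1") for i in range(3)]
        out = asg.resolve_block(self._block(rows))
        assert out.umicount == 3 and out.ambiguity == 1
        assert all(a.umicount == 3 and a.ambiguity == 1 for a in out.assignments)

    def test_per_read_ambiguity(self):
        rows = [
            ra("r1", tx="T1", gene="G1"),
            ra("r1", tx="T2", gene="G1"),
        ]
        out = asg.resolve_block(self._block(rows))
        assert all(a.ambiguity == 2 and a.gambiguity == 1 for a in out.assignments)

    def test_never_increases_ambiguity(self, noisy_table):
        rows, _ = noisy_table
        for block in asg.group_blocks(asg.sort_by_molecule(rows)):
            before_tx = len({a.transcript_id for a in block.assignments
                             if a.transcript_id})
            out = asg.resolve_block(block)
            assert out.ambiguity <= max(1, before_tx)

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            asg.resolve_block(MoleculeBlock(key=("A", "C")))


class TestSorting:
    def _rows(self, n=500, seed=4):
        rng = random.Random(seed)
        rows = []
        for i in range(n):
            rows.append(
                ra(f"r{i}", tx="T1", gene="G1",
                   bc="".join(rng.choice("ACGT") for _ in range(4)),
                   umi="".join(rng.choice("ACGT") for _ in range(4)),
                   start=rng.randrange(0, 100_000), end=rng.randrange(100_001, 200_000))
            )
        return rows

    def test_idempotent_on_sorted_input(self):
        rows = self._rows()
        once = list(asg.sort_by_molecule(rows, chunk_size=64))
        twice = list(asg.sort_by_molecule(once, chunk_size=64))
        assert [r.read_name for r in once] == [r.read_name for r in twice]

    def test_matches_in_memory_sort(self):
        rows = self._rows()
        external = list(asg.sort_by_location(rows, chunk_size=50))
        oracle = sorted(
            rows, key=lambda r: (r.chrom, r.aligned_span.start,
                                 r.aligned_span.end, r.read_name)
        )
        assert [r.read_name for r in external] == [r.read_name for r in oracle]

    def test_stability_on_equal_keys(self):
        rows = []
        for i in range(10):
            r = ra("same", tx="T1", gene="G1", bc="AAAA", umi="CCCC",
                   start=10, end=20)
            r.inconsistency = i  # payload marker; not part of any sort key
            rows.append(r)
        out = list(asg.sort_by_location(rows, chunk_size=3))
        assert [r.inconsistency for r in out] == list(range(10))


class TestEndToEnd:
    def test_every_read_in_exactly_one_block(self, noisy_table):
        rows, _ = noisy_table
        blocks = list(asg.group_blocks(asg.sort_by_molecule(rows)))
        seen = {}
        for b in blocks:
            for name in b.read_names():
                assert seen.setdefault(name, b.key) == b.key
        assert len(seen) == len({r.read_name for r in rows})

    def test_region_split_equivalence(self, annotation):
        from scicounter.pipeline import process_by_region

        cfg = fixtures.SimConfig(n_cells=20, mean_reads_per_cell=25, seed=31)
        rows, _ = fixtures.simulate_assignment_table(cfg, annotation)
        chrom_lengths = {"chr1": 700_000}
        regions = split_regions(chrom_lengths, annotation, target=200_000,
                                free_window=20_000)
        assert len(regions) >= 3
        unsplit, _ = asg.process_assignments(
            [r for r in fixtures.simulate_assignment_table(cfg, annotation)[0]]
        )
        split = process_by_region(rows, regions)
        assert len(split) == len(unsplit)
        for a, b in zip(split, unsplit):
            assert (a.read_name, a.transcript_id, a.umicount, a.ambiguity,
                    a.gambiguity) == (b.read_name, b.transcript_id, b.umicount,
                                      b.ambiguity, b.gambiguity)

    def test_table_round_trip(self, tmp_path, noisy_table):
        rows, _ = noisy_table
        processed, _ = asg.process_assignments(list(rows))
        path = tmp_path / "adapted.tsv"
        asg.write_assignment_table(processed, path)
        back = list(asg.read_assignment_table(path))
        assert len(back) == len(processed)
        for a, b in zip(back, processed):
            assert a.read_name == b.read_name
            assert a.transcript_id == b.transcript_id
            assert a.umicount == b.umicount
            assert a.ambiguity == b.ambiguity
            assert a.polya_detected == b.polya_detected
            assert abs(a.covered_pct - b.covered_pct) < 1e-4

    def test_gzip_round_trip(self, tmp_path):
        rows = [ra("r1", tx="T1", gene="G1")]
        path = tmp_path / "t.tsv.gz"
        asg.write_assignment_table(rows, path)
        assert [r.read_name for r in asg.read_assignment_table(path)] == ["r1"]
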