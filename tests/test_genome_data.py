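"""Gene/insertion data model, per-gene summaries, and file formats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connis.genome import (
    GeneAnnotation,
    GeneSet,
    InsertionSiteSet,
    filter_min_reads,
    genome_density,
    summarize_gene,
    summarize_genes,
    truncate_gene,
)
from connis import io


class TestInsertionSiteSet:
    def test_duplicate_positions_merge_reads(self):
        iss = InsertionSiteSet(1000, [100, 100, 200], [5, 3, 1])
        assert iss.sites == {100: 8, 200: 1}
        assert iss.h == 2

    def test_position_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside genome"):
            InsertionSiteSet(10, [0], [5])
        with pytest.raises(ValueError, match="outside genome"):
            InsertionSiteSet(10, [11])

    def test_density(self):
        assert genome_density(InsertionSiteSet(4_000_000, np.arange(1, 200_001))) == 0.05
        assert InsertionSiteSet(10, np.arange(1, 11)).theta == 1.0
        with pytest.warns(RuntimeWarning):
            assert genome_density(InsertionSiteSet(10, [])) == 0.0


class TestFilterMinReads:
    def test_filters_and_recomputes_h(self):
        iss = filter_min_reads(InsertionSiteSet(20, [5, 9], [1, 3]), 2)
        assert iss.sites == {9: 3} and iss.h == 1

    def test_min_reads_one_is_identity(self):
        iss = InsertionSiteSet(20, [5, 9], [1, 3])
        assert filter_min_reads(iss, 1).sites == iss.sites

    def test_empty_result_warns(self):
        with pytest.warns(RuntimeWarning):
            out = filter_min_reads(InsertionSiteSet(20, [5, 9], [1, 1]), 2)
        assert out.h == 0


class TestTruncation:
    def test_five_percent_of_100bp(self):
        assert truncate_gene(1, 100, 0.05) == (6, 95)

    def test_zero_fraction_identity(self):
        assert truncate_gene(7, 31, 0.0) == (7, 31)

    def test_small_gene_rounding_keeps_interval(self):
        assert truncate_gene(11, 17, 0.05) == (11, 17)  # floor(0.35) == 0

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            truncate_gene(1, 10, 0.5)


class TestSummaries:
    def test_hand_enumerated_runs(self):
        iss = InsertionSiteSet(30, [13, 17])
        s = summarize_gene(GeneAnnotation("g", 11, 20), iss)
        assert (s.k, s.l) == (2, 3)  # runs 11-12, 14-16, 18-20

    def test_no_insertions_run_spans_gene(self):
        s = summarize_gene(GeneAnnotation("g", 11, 20), InsertionSiteSet(30, []))
        assert (s.k, s.l) == (0, 10)

    def test_saturated_gene_has_zero_run(self):
        s = summarize_gene(GeneAnnotation("g", 11, 12), InsertionSiteSet(30, [11, 12]))
        assert (s.k, s.l) == (2, 0)

    @settings(max_examples=150, deadline=None)
    @given(st.data())
    def test_matches_naive_scan_and_run_partition(self, data):
        b = data.draw(st.integers(20, 120))
        positions = data.draw(st.sets(st.integers(1, b), max_size=b))
        start = data.draw(st.integers(1, b - 5))
        end = data.draw(st.integers(start, b))
        iss = InsertionSiteSet(b, sorted(positions))
        s = summarize_gene(GeneAnnotation("g", start, end), iss)
        # naive position-by-position scan
        runs, current, k = [], 0, 0
        for pos in range(start, end + 1):
            if pos in positions:
                k += 1
                if current:
                    runs.append(current)
                current = 0
            else:
                current += 1
        if current:
            runs.append(current)
        assert s.k == k
        assert s.l == (max(runs) if runs else 0)
        assert sum(runs) + k == end - start + 1  # runs partition non-IS positions

    def test_vectorized_agrees_with_single_gene_path(self, rng):
        b = 5000
        iss = InsertionSiteSet(b, np.unique(rng.integers(1, b + 1, 400)))
        starts = np.sort(rng.choice(b - 60, 40, replace=False) + 1)
        genes = GeneSet([f"g{i}" for i in range(40)], starts, starts + rng.integers(10, 50, 40))
        table = summarize_genes(genes, iss, trunc_frac=0.1)
        for j, gene in enumerate(genes):
            single = summarize_gene(gene, iss, trunc_frac=0.1)
            row = table.iloc[j]
            assert (row.k, row.l, row.effective_start, row.effective_end) == (
                single.k, single.l, single.effective_start, single.effective_end
            )


class TestGeneSet:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            GeneSet(["a", "a"], [1, 5], [3, 9])

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GeneSet(["a"], [5], [3])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no gene features"):
            GeneSet([], [], [])


class TestIO:
    def test_gff3_coordinates_pass_through(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr\tsrc\tgene\t190\t255\t.\t+\t.\tID=thrA;locus_tag=b0001\n"
            "chr\tsrc\tCDS\t190\t255\t.\t+\t.\tID=cds1\n"
        )
        genes = io.load_annotation(path)
        assert len(genes) == 1
        g = genes[0]
        assert (g.gene_id, g.start, g.end, g.length) == ("b0001", 190, 255, 66)

    def test_bed_is_zero_based_half_open(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr\t189\t255\tgeneA\t0\t+\n")
        g = io.load_annotation(path)[0]
        assert (g.start, g.end) == (190, 255)

    def test_empty_annotation_errors(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text("##gff-version 3\n")
        with pytest.raises(ValueError, match="no gene features"):
            io.load_annotation(path)

    def test_malformed_record_names_line(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text("chr\tsrc\tgene\tnotanint\t255\t.\t+\t.\tID=x\n")
        with pytest.raises(ValueError, match="line 1"):
            io.load_annotation(path)

    def test_bed_round_trip(self, tmp_path):
        genes = GeneSet(["a", "b"], [190, 401], [255, 460], ["+", "-"])
        io.write_annotation(genes, tmp_path / "x.bed")
        back = io.load_annotation(tmp_path / "x.bed")
        assert np.array_equal(back.starts, genes.starts)
        assert np.array_equal(back.ends, genes.ends)
        assert list(back.ids) == ["a", "b"]

    def test_gff3_round_trip_cross_checked_with_gffutils(self, tmp_path):
        gffutils = pytest.importorskip("gffutils")
        genes = GeneSet(["a", "b"], [10, 300], [120, 950], ["+", "-"])
        path = tmp_path / "x.gff3"
        io.write_annotation(genes, path)
        db = gffutils.create_db(str(path), ":memory:")
        records = {f.attributes["ID"][0]: (f.start, f.end) for f in db.features_of_type("gene")}
        assert records == {"a": (10, 120), "b": (300, 950)}
        back = io.load_annotation(path)
        assert np.array_equal(back.starts, genes.starts)

    def test_tsv_insertions_merge_duplicates(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("position\tread_count\n100\t5\n100\t3\n200\t1\n")
        iss = io.load_insertions(path, genome_length=1000)
        assert iss.sites == {100: 8, 200: 1} and iss.h == 2

    def test_wig_round_trip_carries_genome_length(self, tmp_path):
        iss = InsertionSiteSet(50, [7, 9], [2, 4])
        io.write_insertions(iss, tmp_path / "x.wig")
        back = io.load_insertions(tmp_path / "x.wig")
        assert back.genome_length == 50 and back.sites == {7: 2, 9: 4}

    def test_out_of_range_position_names_line(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("position\tread_count\n0\t5\n")
        with pytest.raises(ValueError, match="line 2"):
            io.load_insertions(path, genome_length=10)

    def test_truth_round_trip(self, tmp_path):
        import pandas as pd

        truth = pd.Series(["essential", "non-essential"], index=["a", "b"], name="label")
        io.write_truth(truth, tmp_path / "t.tsv")
        back = io.read_truth(tmp_path / "t.tsv")
        assert back.to_dict() == truth.to_dict()
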