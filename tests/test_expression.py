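"""Coverage tracks, WIG round trips, exome QC and RPKM quantification."""

import numpy as np
import pytest

from conftest import write_sam
from seqmine.annotation import AnnotationIndex, TranscriptModel
from seqmine.expression import (ExpressionRecord, coverage_track, exon_qc,
                                phenotype_matrix, read_matrix, read_wig,
                                rpkm_quantify, quantify_sample, write_matrix,
                                write_wig)
from seqmine.pileup import pileup_from_sam


def ref_fixture(length=2000, seed=2024):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join(np.array(list("ACGT"))[
        rng.integers(0, 4, size=length)])}


class TestCoverageTrack:
    def test_single_read_span(self, tmp_path):
        ref = ref_fixture()
        sam = write_sam(tmp_path / "a.sam",
                        [("r1", 100, [(0, 5)], ref["chr1"][100:105],
                          "?" * 5, 0, 60)], length=2000)
        track = coverage_track(sam)
        assert track["chr1"][100:105].tolist() == [1] * 5
        assert track["chr1"].sum() == 5

    def test_overlap_depth_two(self, tmp_path):
        ref = ref_fixture()
        sam = write_sam(tmp_path / "a.sam", [
            ("r1", 100, [(0, 20)], ref["chr1"][100:120], "?" * 20, 0, 60),
            ("r2", 110, [(0, 20)], ref["chr1"][110:130], "?" * 20, 0, 60),
        ], length=2000)
        track = coverage_track(sam)
        assert (track["chr1"][110:120] == 2).all()
        assert (track["chr1"][100:110] == 1).all()

    def test_deletions_covered_splice_gaps_not(self, tmp_path):
        ref = ref_fixture()
        seq_d = ref["chr1"][100:102] + ref["chr1"][105:107]
        sam = write_sam(tmp_path / "a.sam", [
            ("r1", 100, [(0, 2), (2, 3), (0, 2)], seq_d, "?" * 4, 0, 60),
            ("r2", 200, [(0, 2), (3, 50), (0, 2)],
             ref["chr1"][200:202] + ref["chr1"][255:257], "?" * 4, 0, 60),
        ], length=2000)
        track = coverage_track(sam)
        assert (track["chr1"][100:107] == 1).all()  # D spans covered
        assert (track["chr1"][202:252] == 0).all()  # N gap not covered
        assert (track["chr1"][252:254] == 1).all()  # block after the gap

    def test_track_matches_pileup_depths(self, tmp_path):
        """Random match-only reads: track equals pileup depth everywhere."""
        rng = np.random.default_rng(21)
        ref = ref_fixture()
        reads = []
        for i, s in enumerate(np.sort(rng.integers(0, 1950, size=150))):
            s = int(s)
            ln = int(rng.integers(20, 50))
            ln = min(ln, 2000 - s)
            reads.append((f"r{i}", s, [(0, ln)], ref["chr1"][s:s + ln],
                          "?" * ln, 0, 60))
        sam = write_sam(tmp_path / "a.sam", reads, length=2000)
        track = coverage_track(sam)
        depths = np.zeros(2000, dtype=int)
        for col in pileup_from_sam(sam, ref):
            depths[col.pos] = col.depth
        assert np.array_equal(track["chr1"], depths)

    def test_total_coverage_conservation(self, tmp_path):
        """Summed depth equals summed reference-consuming aligned bases."""
        ref = ref_fixture()
        reads = [("r1", 10, [(0, 30)], ref["chr1"][10:40], "?" * 30, 0, 60),
                 ("r2", 50, [(0, 10), (2, 5), (0, 10)],
                  ref["chr1"][50:60] + ref["chr1"][65:75], "?" * 20, 0, 60)]
        sam = write_sam(tmp_path / "a.sam", reads, length=2000)
        track = coverage_track(sam)
        assert track["chr1"].sum() == 30 + 25


def test_wig_round_trip(tmp_path):
    rng = np.random.default_rng(33)
    track = {"chr1": rng.integers(0, 5, size=500).astype(np.int64),
             "chr2": np.zeros(300, dtype=np.int64)}
    track["chr2"][100:150] = 7
    path = tmp_path / "c.wig"
    write_wig(track, str(path))
    rt = read_wig(str(path), {"chr1": 500, "chr2": 300})
    for chrom in track:
        assert np.array_equal(rt[chrom], track[chrom])


class TestExonQC:
    def make_index(self):
        index = AnnotationIndex()
        index.add(TranscriptModel("t1", "g1", "chr1", "+",
                                  [(0, 100), (200, 300)]))
        return index

    def test_report_arithmetic(self):
        """Exons averaging 4x and 12x give ec5=50%, ec10=50%, mde=8."""
        track = {"chr1": np.zeros(400, dtype=np.int64)}
        track["chr1"][0:100] = 4
        track["chr1"][200:300] = 12
        rep = exon_qc(track, self.make_index(), total_mapped_reads=100,
                      on_target_reads=100)
        assert rep.mean_depth_exons == pytest.approx(8.0)
        assert rep.pct_exons_cov_ge5 == pytest.approx(50.0)
        assert rep.pct_exons_cov_ge10 == pytest.approx(50.0)
        assert rep.coverage_specificity == pytest.approx(100.0)
        assert rep.coverage_quantiles[0.0] == pytest.approx(4.0)
        assert rep.coverage_quantiles[1.0] == pytest.approx(12.0)

    def test_defective_regions_listed(self):
        track = {"chr1": np.zeros(400, dtype=np.int64)}
        track["chr1"][200:300] = 30
        rep = exon_qc(track, self.make_index(), 10, 10, defective_floor=1.0)
        assert rep.defective_regions == [("chr1", 0, 100, 0.0)]

    def test_uniform_coverage_simulation(self, tmp_path):
        """A uniformly tiled exome shows ~30x mde and ec10 = 100%."""
        rng = np.random.default_rng(14)
        ref = ref_fixture()
        reads = []
        n = 30 * 2000 // 40
        for i, s in enumerate(np.sort(rng.integers(0, 1960, size=n))):
            s = int(s)
            reads.append((f"r{i}", s, [(0, 40)], ref["chr1"][s:s + 40],
                          "?" * 40, 0, 60))
        sam = write_sam(tmp_path / "a.sam", reads, length=2000)
        index = AnnotationIndex()
        index.add(TranscriptModel("t1", "g1", "chr1", "+",
                                  [(200, 700), (1200, 1700)]))
        track = coverage_track(sam)
        rep = exon_qc(track, index, n, n)
        assert abs(rep.mean_depth_exons - 30) / 30 < 0.1
        assert rep.pct_exons_cov_ge10 == 100.0

    def test_empty_exon_set_rejected(self):
        with pytest.raises(ValueError):
            exon_qc({"chr1": np.zeros(10, dtype=np.int64)},
                    AnnotationIndex(), 10, 10)


class TestRPKM:
    def test_closed_form_example(self):
        """100 reads on a 2 kb model with 10M mapped reads is RPKM 5.0."""
        (rec,) = rpkm_quantify({"t1": 100}, {"t1": 2000}, 10_000_000)
        assert rec.rpkm == pytest.approx(5.0, abs=1e-12)

    def test_zero_count_zero_rpkm(self):
        (rec,) = rpkm_quantify({"t1": 0}, {"t1": 500}, 1000)
        assert rec.rpkm == 0.0

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        counts = {f"t{i}": int(rng.integers(0, 5000)) for i in range(200)}
        lengths = {f"t{i}": int(rng.integers(100, 10000)) for i in range(200)}
        total = 3_456_789
        for rec in rpkm_quantify(counts, lengths, total):
            expected = (counts[rec.feature_id] * 1e9
                        / lengths[rec.feature_id] / total)
            assert rec.rpkm == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_duplication(self):
        """Doubling every count and the library size leaves RPKM unchanged."""
        counts = {"a": 10, "b": 250}
        lengths = {"a": 1000, "b": 3000}
        base = {r.feature_id: r.rpkm
                for r in rpkm_quantify(counts, lengths, 1_000_000)}
        doubled = {r.feature_id: r.rpkm
                   for r in rpkm_quantify({k: 2 * v for k, v in counts.items()},
                                          lengths, 2_000_000)}
        assert base == doubled

    def test_zero_length_model_rejected(self):
        with pytest.raises(ValueError):
            rpkm_quantify({"t": 1}, {"t": 0}, 100)

    def test_quantify_sample_counts_overlapping_reads(self, tmp_path):
        ref = ref_fixture()
        index = AnnotationIndex()
        index.add(TranscriptModel("t1", "g1", "chr1", "+", [(100, 200)]))
        index.add(TranscriptModel("t2", "g2", "chr1", "+", [(500, 700)]))
        reads = [
            ("r1", 120, [(0, 30)], ref["chr1"][120:150], "?" * 30, 0, 60),
            ("r2", 190, [(0, 30)], ref["chr1"][190:220], "?" * 30, 0, 60),
            ("r3", 300, [(0, 30)], ref["chr1"][300:330], "?" * 30, 0, 60),
        ]
        sam = write_sam(tmp_path / "a.sam", reads, length=2000)
        tx, ex, total = quantify_sample(sam, index)
        assert total == 3
        by_id = {r.feature_id: r for r in tx}
        assert by_id["t1"].read_count == 2  # r1 fully + r2 partially overlap
        assert by_id["t2"].read_count == 0
        assert by_id["t1"].mean_coverage == pytest.approx(40 / 100)


class TestPhenotypeMatrix:
    def rec(self, fid, rpkm=1.0, count=5):
        return ExpressionRecord(feature_id=fid, read_count=count,
                                mean_coverage=0.0, rpkm=rpkm)

    def test_disjoint_features_fill_zero(self):
        m = phenotype_matrix({"s1": [self.rec("a", 2.0)],
                              "s2": [self.rec("b", 3.0)]})
        assert m.rpkm.shape == (2, 2)
        assert m.rpkm.at["a", "s2"] == 0.0
        assert m.counts.at["b", "s1"] == 0

    def test_single_sample_identity(self):
        m = phenotype_matrix({"s1": [self.rec("a", 2.0, 7)]})
        assert m.rpkm.at["a", "s1"] == 2.0
        assert m.counts.at["a", "s1"] == 7

    def test_order_invariance(self):
        recs = {"s1": [self.rec("a", 1.0), self.rec("b", 2.0)],
                "s2": [self.rec("b", 3.0), self.rec("c", 4.0)]}
        m1 = phenotype_matrix([("s1", recs["s1"]), ("s2", recs["s2"])])
        m2 = phenotype_matrix([("s2", recs["s2"]), ("s1", recs["s1"])])
        assert (m1.rpkm[["s1", "s2"]] == m2.rpkm[["s1", "s2"]]).all().all()

    def test_duplicate_sample_rejected(self):
        with pytest.raises(ValueError):
            phenotype_matrix([("s1", []), ("s1", [])])


def test_expression_matrix_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    import pandas as pd
    df = pd.DataFrame(rng.random((10, 4)),
                      index=[f"g{i}" for i in range(10)],
                      columns=[f"s{j}" for j in range(4)])
    path = tmp_path / "m.tsv"
    write_matrix(df, str(path))
    rt = read_matrix(str(path))
    pd.testing.assert_frame_equal(rt, df)
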