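"""I/O contracts: genotype-aware VCF filtering, ENCODE peak dialects,
CGmap ingestion, GTF strand conventions and text round trips."""

import numpy as np
import pytest

from karyoscope import formats_io as fio
from karyoscope.formats_io import DepthTrack, GenomeLayout, Peak, PeakSet


class TestVcf:
    def test_het_depth_filter_counts(self, vcf_100_sites):
        records = fio.read_vcf_allele_depths(vcf_100_sites, min_site_depth=10)
        assert sorted(records) == ["chr1"]
        assert len(records["chr1"]) == 70
        assert all(r.ratio_alt == 0.5 for r in records["chr1"])

    def test_positions_sorted_and_zero_based(self, vcf_100_sites):
        recs = fio.read_vcf_allele_depths(vcf_100_sites, min_site_depth=10)["chr1"]
        pos = [r.position for r in recs]
        assert pos == sorted(pos)
        assert pos[0] == 99  # first site at POS=100, 1-based

    def test_min_depth_zero_keeps_low_coverage_hets(self, vcf_100_sites):
        records = fio.read_vcf_allele_depths(vcf_100_sites, min_site_depth=0)
        assert len(records["chr1"]) == 80

    def test_missing_ad_field_is_explicit_error(self, tmp_path):
        from tests.conftest import VCF_HEADER

        path = tmp_path / "noad.vcf"
        path.write_text(VCF_HEADER + "chr1\t500\t.\tA\tC\t50\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="chr1:500"):
            fio.read_vcf_allele_depths(path)

    def test_unknown_sample_is_error(self, vcf_100_sites):
        with pytest.raises(ValueError, match="nosuch"):
            fio.read_vcf_allele_depths(vcf_100_sites, sample="nosuch")

    def test_write_read_round_trip(self, tmp_path):
        layout = GenomeLayout({"chr1": 10_000})
        recs = {
            "chr1": [
                fio.AlleleBalanceRecord("chr1", 100, 10, 20),
                fio.AlleleBalanceRecord("chr1", 500, 7, 8),
            ]
        }
        path = tmp_path / "rt.vcf"
        fio.write_vcf(recs, layout, path)
        back = fio.read_vcf_allele_depths(path, min_site_depth=0)
        assert back == recs


class TestPeaks:
    def test_narrowpeak_signal_passthrough(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t600\tpk1\t850\t.\t12.3\t5.2\t3.1\t250\n")
        ps = fio.read_peaks(path, "narrowPeak")
        assert len(ps) == 1
        assert ps[0].signal_value == 12.3
        assert ps[0].summit_offset == 250

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.narrowPeak"
        path.write_text("")
        assert len(fio.read_peaks(path, "narrowPeak")) == 0

    def test_unsorted_input_is_sorted(self, tmp_path):
        path = tmp_path / "u.bed"
        path.write_text("chr2\t10\t20\nchr1\t50\t60\nchr1\t5\t9\n")
        ps = fio.read_peaks(path, "bed3")
        assert [(p.chromosome, p.start) for p in ps] == [("chr1", 5), ("chr1", 50), ("chr2", 10)]

    def test_column_mismatch_names_line(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t100\t600\tpk1\t850\t.\t12.3\t5.2\t3.1\t250\nchr1\t1\t2\n")
        with pytest.raises(ValueError, match=":2"):
            fio.read_peaks(path, "narrowPeak")

    @pytest.mark.parametrize("dialect", ["narrowPeak", "broadPeak", "bed3"])
    def test_round_trip(self, tmp_path, dialect):
        peaks = [
            Peak("chr1", 100, 600, "pk1", 850.0, ".", 12.3, 5.25, 3.125, 250),
            Peak("chr2", 10, 90, "pk2", 100.0, ".", 1.5, -1.0, -1.0, None),
        ]
        ps = PeakSet(peaks)
        path = tmp_path / f"rt.{dialect}"
        fio.write_peaks(ps, path, dialect)
        back = fio.read_peaks(path, dialect)
        assert [(p.chromosome, p.start, p.end) for p in back] == [
            (p.chromosome, p.start, p.end) for p in ps
        ]
        if dialect != "bed3":
            assert [p.signal_value for p in back] == [p.signal_value for p in ps]


class TestMethylation:
    def test_zero_total_rows_excluded(self, cgmap_50_rows):
        sites = fio.read_methylation_table(cgmap_50_rows)
        assert len(sites) == 45

    def test_level_recomputed_from_counts(self, tmp_path):
        path = tmp_path / "m.cgmap"
        path.write_text("chr1\tC\t1000\tCG\tCG\t0.700000\t7\t10\n")
        (site,) = fio.read_methylation_table(path)
        assert site.level == pytest.approx(0.7)
        assert site.context == "CpG"
        assert site.position == 999

    def test_negative_counts_error(self, tmp_path):
        path = tmp_path / "m.cgmap"
        path.write_text("chr1\tC\t1000\tCG\tCG\t0.5\t-1\t10\n")
        with pytest.raises(ValueError, match="negative"):
            fio.read_methylation_table(path)

    def test_round_trip(self, tmp_path, cgmap_50_rows):
        sites = fio.read_methylation_table(cgmap_50_rows)
        out = tmp_path / "rt.cgmap"
        fio.write_methylation_table(sites, out)
        assert fio.read_methylation_table(out) == sites


class TestGtf:
    def _write(self, tmp_path, body):
        path = tmp_path / "genes.gtf"
        path.write_text(body)
        return path

    def test_strand_tss_convention(self, tmp_path):
        path = self._write(
            tmp_path,
            'chr1\tx\tgene\t100\t500\t.\t+\t.\tgene_id "gplus";\n'
            'chr1\tx\tgene\t100\t500\t.\t-\t.\tgene_id "gminus";\n',
        )
        genes = {g.gene_id: g for g in fio.read_gtf_genes(path)}
        # 1-based inclusive [100, 500] -> 0-based points 99 and 499
        assert (genes["gplus"].tss, genes["gplus"].tes) == (99, 499)
        assert (genes["gminus"].tss, genes["gminus"].tes) == (499, 99)

    def test_duplicate_gene_id_is_error(self, tmp_path):
        path = self._write(
            tmp_path,
            'chr1\tx\tgene\t100\t500\t.\t+\t.\tgene_id "dup";\n'
            'chr1\tx\tgene\t800\t900\t.\t+\t.\tgene_id "dup";\n',
        )
        with pytest.raises(ValueError, match="dup"):
            fio.read_gtf_genes(path)


class TestDepthTrack:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DepthTrack("chr1", [0, 5], [10, 15], [1.0, 1.0])  # overlap
        with pytest.raises(ValueError):
            DepthTrack("chr1", [0], [0], [1.0])  # empty interval

    def test_mean_depth_weighted(self):
        t = DepthTrack.from_intervals("chr1", [(0, 10, 20.0), (10, 30, 50.0)])
        assert t.mean_depth(0, 30) == pytest.approx((10 * 20 + 20 * 50) / 30)
        assert t.mean_depth(40, 50) is None

    def test_bedgraph_round_trip(self, tmp_path):
        tracks = {"chr1": DepthTrack.from_intervals("chr1", [(0, 100, 12.5), (100, 250, 30.0)])}
        path = tmp_path / "d.bedGraph"
        fio.write_bedgraph(tracks, path)
        back = fio.read_bedgraph(path)
        np.testing.assert_array_equal(back["chr1"].starts, tracks["chr1"].starts)
        np.testing.assert_allclose(back["chr1"].depths, tracks["chr1"].depths)


class TestExpression:
    def test_round_trip_and_attach(self, tmp_path):
        genes = [
            fio.GeneRecord("g1", "chr1", "+", 100, 500, 12.0),
            fio.GeneRecord("g2", "chr1", "-", 900, 600, 0.5),
        ]
        path = tmp_path / "tpm.tsv"
        fio.write_expression_table(genes, path)
        table = fio.read_expression_table(path)
        assert table == {"g1": 12.0, "g2": 0.5}
        bare = [fio.GeneRecord(g.gene_id, g.chromosome, g.strand, g.tss, g.tes) for g in genes]
        attached = fio.attach_expression(bare, table)
        assert [g.tpm for g in attached] == [12.0, 0.5]

    def test_header_is_checked(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tvalue\ng1\t2\n")
        with pytest.raises(ValueError, match="gene_id"):
            fio.read_expression_table(path)
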