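"""Pileup TSV / BED / VCF round trips and the bundled fixtures."""

import pytest
from hypothesis import given, settings, strategies as st

from fasmosaic.datasets import (
    DEFAULT_REGIONS,
    fixture_pileup,
    fixture_report,
    load_fixtures,
)
from fasmosaic.pileup_io import (
    GenomicRegion,
    PileupFormatError,
    StrandedAlleleCount,
    VariantCall,
    read_bed,
    read_pileup_tsv,
    read_vcf,
    write_bed,
    write_pileup_tsv,
    write_vcf,
)


class TestTypes:
    def test_region_invariants(self):
        with pytest.raises(ValueError):
            GenomicRegion("chr10", 20, 10)
        with pytest.raises(ValueError):
            GenomicRegion("", 1, 2)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(depth=5, alt_fwd=4, alt_rev=3),  # alt exceeds depth
            dict(depth=10, alt_fwd=-1, alt_rev=0),
            dict(depth=10, alt_fwd=2, alt_rev=2, depth_fwd=5, depth_rev=6),
            dict(depth=10, alt_fwd=6, alt_rev=0, depth_fwd=5, depth_rev=5),
            dict(depth=10, alt_fwd=1, alt_rev=1, depth_fwd=5),
        ],
    )
    def test_count_invariants_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StrandedAlleleCount(chrom="chr10", pos=1, ref="A", alt="G", **kwargs)

    def test_rejected_classification_consistency(self):
        counts = StrandedAlleleCount("chr10", 1, "A", "G", 100, 2, 2)
        with pytest.raises(ValueError):
            VariantCall(counts, 0.04, 0.5, 1.0, True, "rejected")


class TestPileupTsv:
    def test_full_transcription_roundtrip(self, table2_tsv, table2_pileup):
        records = read_pileup_tsv(table2_tsv)
        assert len(records) == 12
        assert records == table2_pileup

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("chrom\tpos\tref\talt\tdepth\talt_fwd\talt_rev\n")
        assert read_pileup_tsv(path) == []

    def test_region_filter_keeps_seven_inner_records(self, table2_tsv):
        region = [GenomicRegion("chr10", 90773000, 90774000)]
        records = read_pileup_tsv(table2_tsv, regions=region)
        assert [r.pos for r in records] == [
            90773878, 90773947, 90773876, 90773125, 90773100, 90773099, 90773123
        ]

    def test_region_filter_idempotent_order_preserving(self, table2_tsv):
        region = [GenomicRegion("chr10", 90773000, 90774000)]
        once = read_pileup_tsv(table2_tsv, regions=region)
        path = table2_tsv.parent / "again.tsv"
        write_pileup_tsv(once, path)
        assert read_pileup_tsv(path, regions=region) == once

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tdepth\talt_fwd\talt_rev\n"
            "chr10\t100\tA\tG\t50\t1\t1\n"
            "chr10\tnotanint\tA\tG\t50\t1\t1\n"
        )
        with pytest.raises(PileupFormatError, match=":3"):
            read_pileup_tsv(path)

    def test_alt_exceeding_depth_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tdepth\talt_fwd\talt_rev\n"
            "chr10\t100\tA\tG\t5\t4\t3\n"
        )
        with pytest.raises(PileupFormatError, match="exceeds"):
            read_pileup_tsv(path)


class TestBed:
    def test_coordinate_conversion(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr10\t90770000\t90775000\tFAS_target\n")
        (region,) = read_bed(path)
        assert (region.chrom, region.start, region.end) == ("chr10", 90770001, 90775000)
        assert region.label == "FAS_target"

    def test_empty_file(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("")
        assert read_bed(path) == []

    def test_overlapping_lines_not_merged(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr10\t100\t200\na\nchr10\t150\t250\n".replace("\na\n", "\n"))
        regions = read_bed(path)
        assert len(regions) == 2

    def test_degenerate_interval_rejected(self, tmp_path):
        path = tmp_path / "r.bed"
        path.write_text("chr10\t200\t200\n")
        with pytest.raises(ValueError):
            read_bed(path)

    def test_write_read_roundtrip(self, tmp_path):
        path = tmp_path / "r.bed"
        write_bed(DEFAULT_REGIONS, path)
        assert tuple(read_bed(path)) == DEFAULT_REGIONS


class TestVcf:
    def _call(self, counts, **kw):
        from fasmosaic.caller import (
            compute_vaf,
            strand_bias_pvalue,
            strand_bias_score,
        )
        return VariantCall(
            counts=counts,
            vaf=compute_vaf(counts),
            strand_bias=strand_bias_score(counts),
            sb_pvalue=strand_bias_pvalue(counts),
            filters_passed=True,
            classification="somatic",
            **kw,
        )

    def test_snv_pass_record(self, tmp_path, table2_pileup):
        call = self._call(table2_pileup[0], sample_id="P1")  # chr10:90771840 T>C
        path = tmp_path / "p1.vcf"
        write_vcf([call], path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1
        fields = lines[0].split("\t")
        assert fields[:5] == ["chr10", "90771840", ".", "T", "C"]
        assert fields[6] == "PASS"

    def test_empty_call_list_header_only(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_vcf([], path)
        assert all(l.startswith("#") for l in path.read_text().splitlines())

    def test_deletion_anchored_and_roundtrips(self, tmp_path, table2_pileup):
        deletion = table2_pileup[1]  # chr10:90773878 G -> '-'
        call = self._call(deletion, sample_id="P2")
        path = tmp_path / "p2.vcf"
        write_vcf([call], path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        chrom, pos, _, ref, alt = body.split("\t")[:5]
        assert int(pos) == deletion.pos - 1 and len(ref) == len(alt) + 1
        (back,) = read_vcf(path)
        assert back.counts.pos == deletion.pos
        assert back.counts.ref == "G" and back.counts.alt == "-"
        assert (back.counts.alt_fwd, back.counts.alt_rev) == (10, 20)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        depth=st.integers(10, 500),
        alt_fwd=st.integers(0, 5),
        alt_rev=st.integers(1, 5),
        pos=st.integers(90770501, 90774499),
    )
    def test_write_read_roundtrip_property(self, tmp_path_factory, depth, alt_fwd, alt_rev, pos):
        counts = StrandedAlleleCount("chr10", pos, "A", "G", depth, alt_fwd, alt_rev)
        call = self._call(counts, sample_id="S")
        path = tmp_path_factory.mktemp("vcf") / "x.vcf"
        write_vcf([call], path)
        (back,) = read_vcf(path)
        assert back.counts == StrandedAlleleCount("chr10", pos, "A", "G", depth, alt_fwd, alt_rev)
        assert back.vaf == pytest.approx(call.vaf, abs=1e-9)
        assert back.classification == "somatic"


class TestFixtures:
    def test_cohort_shape(self):
        samples, calls = load_fixtures()
        assert len(samples) == 52
        assert sum(s.group == "patient" for s in samples) == 8
        assert len(calls) == 12

    def test_seven_patients_have_matchable_known_variants(self):
        samples, _ = load_fixtures()
        with_variant = [s for s in samples if s.known_variant is not None]
        assert len(with_variant) == 7
        p8 = next(s for s in samples if s.sample_id == "P8")
        assert p8.known_variant is None and p8.known_undetectable

    def test_p8_dnt_percent(self):
        samples, _ = load_fixtures()
        p8 = next(s for s in samples if s.sample_id == "P8")
        assert p8.dnt_percent == 4

    def test_strand_counts_sum_to_allele_coverage(self, table2_report):
        for row in table2_report:
            assert row["alt_fwd"] + row["alt_rev"] == row["allele_cov"]

    def test_all_report_sites_inside_default_regions(self, table2_pileup):
        for rec in table2_pileup:
            assert any(r.contains(rec.chrom, rec.pos) for r in DEFAULT_REGIONS)
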