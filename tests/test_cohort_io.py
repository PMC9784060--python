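"""Cohort I/O: ID normalisation, region trimming, call-rate filtering,
annotation and VCF round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stratpgx import cohort_io
from stratpgx.cohort_io import (
    AnnotationRecord,
    AnnotationTable,
    GeneRegion,
    MISSING,
    ValidationError,
    annotate,
    filter_call_rate,
    normalize_variant_id,
    region_size,
    trim_to_regions,
)

from conftest import make_matrix

CYP2A6 = GeneRegion("CYP2A6", "chr19", 41_349_343, 41_356_460)
CYP2B6 = GeneRegion("CYP2B6", "chr19", 41_497_104, 41_524_408)


class TestNormalizeVariantId:
    @pytest.mark.parametrize(
        "args, expected",
        [
            (("chr19", 40849872, "C", "T"), "chr19:40849872C-T"),
            (("chr4", 1, "A", "AT"), "chr4:1A-AT"),
            (("chr2", 100, "ATG", "A"), "chr2:100ATG-A"),
        ],
    )
    def test_format(self, args, expected):
        assert normalize_variant_id(*args) == expected

    @pytest.mark.parametrize(
        "args",
        [
            ("chr19", 40849872, "C", ""),
            ("chr19", 40849872, "", "T"),
            ("chr19", 0, "C", "T"),
            ("", 5, "C", "T"),
        ],
    )
    def test_invalid_inputs_rejected(self, args):
        with pytest.raises(ValidationError):
            normalize_variant_id(*args)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr4", "chr19", "chrX"]),
                st.integers(min_value=1, max_value=10**9),
                st.text(alphabet="ACGT", min_size=1, max_size=4),
                st.text(alphabet="ACGT", min_size=1, max_size=4),
            ),
            min_size=2,
            max_size=30,
            unique=True,
        )
    )
    def test_injective_on_distinct_tuples(self, tuples):
        ids = [normalize_variant_id(*t) for t in tuples]
        assert len(set(ids)) == len(set(tuples))


class TestRegions:
    @pytest.mark.parametrize(
        "region, expected",
        [
            (CYP2A6, 7117),
            (CYP2B6, 27_304),
            (GeneRegion("G", "chr1", 500, 500), 0),
        ],
    )
    def test_region_size_is_subtraction(self, region, expected):
        assert region_size(region) == expected

    def test_invalid_region_rejected(self):
        with pytest.raises(ValidationError):
            GeneRegion("G", "chr1", 10, 5)
        with pytest.raises(ValidationError):
            GeneRegion("G", "", 1, 5)


class TestTrimToRegions:
    def test_region_membership_and_gene_assignment(self):
        gm, _ = make_matrix([[1, 1, 1]], ["AFR"], start_pos=1)
        gm.variants[0].pos = CYP2A6.start_bp  # on the start boundary
        gm.variants[1].pos = CYP2A6.start_bp - 1  # just outside
        gm.variants[2].pos = CYP2B6.stop_bp  # stop boundary, other gene
        out = trim_to_regions(gm, [CYP2A6, CYP2B6])
        assert [v.pos for v in out.variants] == [CYP2A6.start_bp, CYP2B6.stop_bp]
        assert [v.gene_name for v in out.variants] == ["CYP2A6", "CYP2B6"]
        assert out.samples == gm.samples

    def test_empty_matrix_passes_through(self):
        gm, _ = make_matrix(np.zeros((2, 0)), ["AFR", "AFR"])
        out = trim_to_regions(gm, [CYP2A6])
        assert out.n_variants == 0 and out.n_samples == 2

    def test_idempotent(self, demo_cohort):
        _, gm, _, _, _ = demo_cohort
        regions = list(demo_cohort[0].regions)
        once = trim_to_regions(gm, regions)
        twice = trim_to_regions(once, regions)
        assert [v.canonical_id for v in once.variants] == [
            v.canonical_id for v in twice.variants
        ]
        assert np.array_equal(once.calls, twice.calls)

    def test_overlapping_regions_rejected(self):
        gm, _ = make_matrix([[0]], ["AFR"])
        overlapping = [
            GeneRegion("A", "chr19", 100, 200),
            GeneRegion("B", "chr19", 150, 300),
        ]
        with pytest.raises(ValidationError, match="overlap"):
            trim_to_regions(gm, overlapping)

    def test_empty_region_list_rejected(self):
        gm, _ = make_matrix([[0]], ["AFR"])
        with pytest.raises(ValidationError):
            trim_to_regions(gm, [])


class TestFilterCallRate:
    def test_one_missing_call_fails_full_rate(self):
        calls = np.ones((3, 100), dtype=np.int16)
        calls[1, 42] = MISSING
        gm, _ = make_matrix(calls, ["AFR"] * 3)
        out, removed = filter_call_rate(gm, min_rate=1.0)
        assert removed == ["S0001"]
        assert out.n_samples == 2
        assert (out.calls != MISSING).all()

    def test_fully_called_matrix_unchanged(self):
        gm, _ = make_matrix([[0, 1], [2, 1]], ["AFR", "EUR"])
        out, removed = filter_call_rate(gm)
        assert removed == []
        assert np.array_equal(out.calls, gm.calls)

    def test_threshold_arithmetic(self):
        # call rate 96/100 = 0.96 >= 0.95 -> retained
        calls = np.ones((1, 100), dtype=np.int16)
        calls[0, :4] = MISSING
        gm, _ = make_matrix(calls, ["AFR"])
        out, removed = filter_call_rate(gm, min_rate=0.95)
        assert removed == [] and out.n_samples == 1

    def test_all_samples_removed_returns_empty_matrix(self):
        calls = np.full((2, 3), MISSING, dtype=np.int16)
        gm, _ = make_matrix(calls, ["AFR", "AFR"])
        out, removed = filter_call_rate(gm)
        assert out.n_samples == 0 and len(removed) == 2

    def test_invalid_min_rate_rejected(self):
        gm, _ = make_matrix([[0]], ["AFR"])
        with pytest.raises(ValidationError):
            filter_call_rate(gm, min_rate=0.0)


class TestAnnotate:
    def test_lookup_hit_and_miss(self):
        gm, _ = make_matrix([[1, 1]], ["AFR"])
        key = gm.variants[0].canonical_id
        ann = AnnotationTable.from_records(
            [(key, AnnotationRecord(rsid="rs42", sift_score=0.02))]
        )
        out = annotate(gm, ann)
        assert out.variants[0].rsid == "rs42"
        assert out.variants[0].sift_score == 0.02
        assert out.variants[1].rsid is None

    def test_duplicate_annotation_key_rejected(self):
        rec = AnnotationRecord(rsid="rs1")
        with pytest.raises(ValidationError, match="duplicate"):
            AnnotationTable.from_records([("k", rec), ("k", rec)])

    def test_score_range_enforced(self):
        with pytest.raises(ValidationError):
            AnnotationRecord(sift_score=1.5)


class TestVcfRoundTrip:
    def test_dosages_ids_and_order_preserved(self, tmp_path, demo_cohort):
        spec, gm, _, _, _ = demo_cohort
        path = tmp_path / "rt.vcf"
        cohort_io.write_vcf(gm, path)
        back = cohort_io.read_vcf(path)
        assert [v.canonical_id for v in back.variants] == [
            v.canonical_id for v in gm.variants
        ]
        assert back.samples == gm.samples
        assert np.array_equal(back.calls, gm.calls)
        assert [v.consequence_class for v in back.variants] == [
            v.consequence_class for v in gm.variants
        ]

    def test_missing_genotypes_survive_round_trip(self, tmp_path):
        calls = np.array([[0, 1], [MISSING, 2]], dtype=np.int16)
        gm, _ = make_matrix(calls, ["AFR", "EUR"])
        cohort_io.write_vcf(gm, tmp_path / "m.vcf")
        back = cohort_io.read_vcf(tmp_path / "m.vcf")
        assert np.array_equal(back.calls, calls)

    def test_multiallelic_rows_are_split(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chr19>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
            "chr19\t100\trs7\tA\tT,G\t.\t.\t.\tGT\t0/1\t1/2\n"
        )
        gm = cohort_io.read_vcf(vcf)
        assert [v.alt for v in gm.variants] == ["T", "G"]
        assert [v.rsid for v in gm.variants] == ["rs7", "rs7"]
        # S1 = A/T -> dosage (1, 0); S2 = T/G -> dosage (1, 1)
        assert gm.calls.tolist() == [[1, 0], [1, 1]]


class TestManifest:
    def test_round_trip(self, tmp_path, demo_cohort):
        _, _, manifest, _, _ = demo_cohort
        cohort_io.write_manifest(manifest, tmp_path / "m.tsv")
        back = cohort_io.read_manifest(tmp_path / "m.tsv")
        assert back.entries == dict(manifest.entries)

    def test_unknown_population_label_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample_id\tpopulation\nS1\tMARS\n")
        with pytest.raises(ValidationError, match="MARS"):
            cohort_io.read_manifest(p)

    def test_duplicate_sample_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("sample_id\tpopulation\nS1\tAFR\nS1\tEUR\n")
        with pytest.raises(ValidationError, match="duplicate"):
            cohort_io.read_manifest(p)
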