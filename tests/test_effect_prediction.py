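"""Effect prediction: consensus scoring, degree of support, novelty and
clinical-subset selection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stratpgx import frequency_profiling as fp
from stratpgx import association_testing as at
from stratpgx.cohort_io import (
    AnnotationRecord,
    AnnotationTable,
    GenotypeMatrix,
    ValidationError,
    VariantRecord,
    annotate,
)
from stratpgx.effect_prediction import (
    classify_support,
    condel_score,
    flag_novel,
    predict_effects,
    select_clinical_subset,
)
from stratpgx.synthetic_data import simulate_annotations, simulate_cohort

from test_synthetic_data import small_spec

unit = st.floats(0.0, 1.0, allow_nan=False)


class TestCondelScore:
    @pytest.mark.parametrize(
        "sift, polyphen, expected",
        [
            (0.0, 1.0, 1.0),  # maximally deleterious on both scales
            (1.0, 0.0, 0.0),  # maximally neutral on both scales
            (0.2, 0.9, 0.85),
            (0.5, 0.5, 0.5),
        ],
    )
    def test_equal_weight_average(self, sift, polyphen, expected):
        assert condel_score(sift, polyphen) == pytest.approx(expected)

    def test_absent_score_yields_no_consensus(self):
        assert condel_score(None, 0.9) is None
        assert condel_score(0.1, None) is None

    def test_weighting(self):
        # full weight on polyphen reduces to the polyphen score
        assert condel_score(0.9, 0.7, w_sift=1e-9, w_polyphen=1.0) == pytest.approx(
            0.7, abs=1e-6
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            condel_score(1.2, 0.5)
        with pytest.raises(ValidationError):
            condel_score(0.5, 0.5, w_sift=0.0)

    @given(unit, unit, unit)
    def test_monotone_in_each_argument(self, s, p, delta):
        base = condel_score(s, p)
        s_hi = min(1.0, s + delta)
        p_hi = min(1.0, p + delta)
        assert condel_score(s_hi, p) <= base + 1e-12  # non-increasing in sift
        assert condel_score(s, p_hi) >= base - 1e-12  # non-decreasing in polyphen

    @given(unit, unit)
    def test_scale_duality(self, s, p):
        # swapping (sift, polyphen) -> (1 - polyphen, 1 - sift) is a no-op
        assert condel_score(1 - p, 1 - s) == pytest.approx(condel_score(s, p))


class TestClassifySupport:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            ((True, True, True), "consensus"),
            ((True, True, False), "doubleton"),
            ((True, False, False), "singleton"),
            ((False, False, False), "none"),
        ],
    )
    def test_full_information(self, flags, expected):
        label, n = classify_support(*flags)
        assert label == expected and n == 3

    def test_absent_flags_reduce_denominator(self):
        label, n = classify_support(True, True, None)
        assert label == "doubleton" and n == 2
        label, n = classify_support(None, None, None)
        assert label == "none" and n == 0


class TestFlagNovel:
    def test_novel_count_matches_simulator_truth(self):
        spec = small_spec([0.5] * 100)
        gm, _, truth = simulate_cohort(spec)
        ann = simulate_annotations(truth, known_fraction=0.8, seed=5)
        gm = annotate(gm, ann)
        report = flag_novel(gm)
        assert len(report) == 20
        assert set(report["canonical_id"]) == {
            v.canonical_id for v in gm.variants
        } - truth.known_ids

    def test_fully_known_cohort_has_empty_report(self):
        spec = small_spec([0.5] * 30)
        gm, _, truth = simulate_cohort(spec)
        ann = simulate_annotations(truth, known_fraction=1.0, seed=5)
        gm = annotate(gm, ann)
        assert len(flag_novel(gm)) == 0

    def test_known_variant_without_consequence_is_not_novel(self):
        v = VariantRecord("chr19", 41_350_000, "C", "T", rsid="rs1")
        gm = GenotypeMatrix(
            variants=[v], samples=["S"], calls=np.array([[1]], dtype=np.int16)
        )
        report = flag_novel(gm)
        assert len(report) == 0
        preds = predict_effects(gm)
        assert not preds[0].novel

    def test_unmapped_novel_variant_labelled_mapping_failure(self):
        v = VariantRecord("chr4", 69_920_000, "G", "GT", gene_name="UGT2B7")
        gm = GenotypeMatrix(
            variants=[v], samples=["S"], calls=np.array([[1]], dtype=np.int16)
        )
        report = flag_novel(gm)
        assert report.iloc[0]["consequence"] == "mapping_failure"

    def test_known_and_novel_partition_the_universe(self, demo_cohort):
        _, gm, _, truth, _ = demo_cohort
        preds = predict_effects(gm)
        novel = {p.canonical_id for p in preds if p.novel}
        known = {p.canonical_id for p in preds if not p.novel}
        universe = {v.canonical_id for v in gm.variants}
        assert novel | known == universe
        assert novel & known == set()


def brute_force_subset(ft, status, assoc, effects, mode="or"):
    """Independent three-predicate filter over the variant universe."""
    eff = {e.canonical_id: e for e in effects}
    sig = {r.canonical_id for r in assoc if r.significant}
    selected = set()
    for j, v in enumerate(ft.variants):
        e = eff[v.canonical_id]
        has_pheno = bool(e.phenotype_terms)
        has_condel = e.condel is not None
        evid = (has_pheno or has_condel) if mode == "or" else (has_pheno and has_condel)
        if evid and bool(status.overall[j]) and v.canonical_id in sig:
            selected.add(v.canonical_id)
    return selected


class TestClinicalSubset:
    def _stages(self, gm, manifest):
        ft = fp.compute_frequencies(gm, manifest)
        status = fp.allelic_status(ft)
        assoc = at.run_association(ft, status, ref_pop="AFR")
        effects = predict_effects(gm)
        return ft, status, assoc, effects

    @pytest.mark.parametrize("mode", ["or", "and"])
    def test_equals_brute_force_filter(self, demo_cohort, mode):
        _, gm, manifest, _, _ = demo_cohort
        ft, status, assoc, effects = self._stages(gm, manifest)
        subset = select_clinical_subset(ft, status, assoc, effects, "AFR", mode=mode)
        got = {e.canonical_id for entries in subset.by_gene.values() for e in entries}
        assert got == brute_force_subset(ft, status, assoc, effects, mode)

    def test_engineered_cohort_selects_exactly_twelve(self):
        # 12 qualifying variants (phenotype-tagged, AFR-private at 50%,
        # necessarily significant) among decoys failing one predicate each
        n_qual, n_decoy = 12, 8
        freqs = [[0.5, 0.0]] * n_qual + [[0.5, 0.0]] * n_decoy
        spec = small_spec(freqs, populations={"AFR": 200, "EUR": 200}, seed=21)
        gm, manifest, _ = simulate_cohort(spec)
        items = []
        for i, v in enumerate(gm.variants):
            terms = ("Efavirenz poor metabolism",) if i < n_qual else ()
            items.append((v.canonical_id, AnnotationRecord(rsid=f"rs{i}", phenotype_terms=terms)))
        gm = annotate(gm, AnnotationTable.from_records(items))
        ft, status, assoc, effects = self._stages(gm, manifest)
        subset = select_clinical_subset(ft, status, assoc, effects, "AFR")
        assert subset.total == 12
        assert set(subset.by_gene) == {"CYP2A6"}

    def test_markers_follow_frequency_comparison(self, demo_cohort):
        _, gm, manifest, _, _ = demo_cohort
        ft, status, assoc, effects = self._stages(gm, manifest)
        subset = select_clinical_subset(ft, status, assoc, effects, "AFR")
        by_id = {v.canonical_id: j for j, v in enumerate(ft.variants)}
        ri = ft.pop_index("AFR")
        for entries in subset.by_gene.values():
            for e in entries:
                j = by_id[e.canonical_id]
                for pop, marker in e.markers.items():
                    if marker is None:
                        continue
                    ci = ft.pop_index(pop)
                    if marker == "higher":
                        assert ft.frequency[j, ci] > ft.frequency[j, ri]
                    else:
                        assert ft.frequency[j, ci] < ft.frequency[j, ri]

    def test_significant_without_phenotype_or_consensus_excluded(self):
        spec = small_spec([[0.5, 0.0]], populations={"AFR": 200, "EUR": 200}, seed=3)
        gm, manifest, _ = simulate_cohort(spec)
        # annotated (known) but no phenotype terms and no scores
        gm = annotate(
            gm,
            AnnotationTable.from_records(
                [(gm.variants[0].canonical_id, AnnotationRecord(rsid="rs9"))]
            ),
        )
        ft, status, assoc, effects = self._stages(gm, manifest)
        assert any(r.significant for r in assoc)
        subset = select_clinical_subset(ft, status, assoc, effects, "AFR")
        assert subset.total == 0
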