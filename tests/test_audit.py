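"""PPV truncation, review sheets, reviewer labels and out-of-hierarchy calls."""

import numpy as np
import pytest

from conftest import make_defn
from helpers import key, make_ranking
from icdsem.audit import (
    PhenotypeSets,
    build_review_sheet,
    classify_new_codes,
    derive_sets,
    ppv_curve,
    read_annotations,
)
from icdsem.catalog import IcdCatalog, IcdCode
from icdsem.exceptions import DataError

A, B, C, D, E = (key(n) for n in "ABCDE")


@pytest.fixture
def letter_catalog():
    return IcdCatalog(
        [IcdCode("ICD10CM", n, f"description {n}") for n in "ABCDEFGH"]
    )


class TestPpvCurve:
    def test_hand_example(self):
        curve = ppv_curve([A, C, B, D], {A, B}, k=4)
        np.testing.assert_allclose(curve.ppv, [1.0, 0.5, 2 / 3, 0.5])
        assert curve.cutoff_rank == 4

    def test_reference_prefix_all_ones(self):
        curve = ppv_curve([A, B, C, D], {A, B}, k=4)
        np.testing.assert_allclose(curve.ppv[:2], [1.0, 1.0])

    def test_no_reference_hits_cutoff_zero(self):
        curve = ppv_curve([C, D], {A, B}, k=2)
        assert np.all(curve.ppv == 0.0)
        assert curve.cutoff_rank == 0

    def test_hit_count_increments_bounded(self):
        rng = np.random.default_rng(3)
        items = [key(f"I{i}") for i in range(30)]
        reference = set(rng.choice(30, 10, replace=False).tolist())
        reference = {items[i] for i in reference}
        curve = ppv_curve(items, reference, k=30)
        hits = curve.ppv * np.arange(1, 31)
        increments = np.diff(np.concatenate([[0.0], hits]))
        assert set(np.rint(increments).astype(int)) <= {0, 1}

    def test_threshold_monotone(self):
        items = [A, C, B, D]
        strict = ppv_curve(items, {A, B}, k=4, threshold=0.9)
        loose = ppv_curve(items, {A, B}, k=4, threshold=0.4)
        assert strict.cutoff_rank <= loose.cutoff_rank

    def test_empty_reference_rejected(self):
        with pytest.raises(DataError):
            ppv_curve([A], set(), 1)


class TestReviewSheet:
    def test_union_by_hand(self, letter_catalog):
        producer = make_ranking([A, C, B, D], model_id="m1")
        sheet = build_review_sheet(
            [producer], reference={A, B, E}, catalog=letter_catalog, k=4, shuffle_seed=0
        )
        assert set(sheet.keys) == {A, B, C, D, E}

    def test_same_seed_same_order(self, letter_catalog):
        producer = make_ranking([A, C, B, D], model_id="m1")
        s1 = build_review_sheet([producer], {A, B}, letter_catalog, k=4, shuffle_seed=5)
        s2 = build_review_sheet([producer], {A, B}, letter_catalog, k=4, shuffle_seed=5)
        assert s1.rows == s2.rows

    def test_different_seed_same_set(self, letter_catalog):
        producer = make_ranking([A, C, B, D], model_id="m1")
        s1 = build_review_sheet([producer], {A, B}, letter_catalog, k=4, shuffle_seed=1)
        s2 = build_review_sheet([producer], {A, B}, letter_catalog, k=4, shuffle_seed=2)
        assert set(s1.keys) == set(s2.keys)

    def test_producer_order_invariance(self, letter_catalog):
        p1 = make_ranking([A, C, B, D], model_id="m1")
        p2 = make_ranking([B, D, A, C], model_id="m2")
        s12 = build_review_sheet([p1, p2], {A, B}, letter_catalog, k=4, shuffle_seed=3)
        s21 = build_review_sheet([p2, p1], {A, B}, letter_catalog, k=4, shuffle_seed=3)
        assert set(s12.keys) == set(s21.keys)
        assert s12.rows == s21.rows

    def test_reference_always_present(self, letter_catalog):
        # producer never retrieves E, but E is in the reference
        producer = make_ranking([C, D, A, B], model_id="m1")
        sheet = build_review_sheet([producer], {A, E}, letter_catalog, k=4, shuffle_seed=0)
        assert E in set(sheet.keys)

    def test_blinded_frame_has_no_provenance(self, letter_catalog):
        producer = make_ranking([A, C, B, D], model_id="m1")
        sheet = build_review_sheet([producer], {A, B}, letter_catalog, k=4, shuffle_seed=0)
        blinded = sheet.to_frame(blinded=True)
        assert list(blinded.columns) == ["vocabulary", "code", "description"]
        keyed = sheet.to_frame(blinded=False)
        assert "provenance" in keyed.columns


class TestDeriveSets:
    def _sheet(self, letter_catalog, items, reference=None):
        # reference defaults to the whole list so PPV never truncates
        producer = make_ranking(items, model_id="m1")
        return build_review_sheet(
            [producer], reference or set(items), letter_catalog, k=len(items), shuffle_seed=0
        )

    def test_label_semantics(self, letter_catalog):
        sheet = self._sheet(letter_catalog, [A, B, C])
        sets = derive_sets(sheet, {A: 2, B: 1, C: 0}, reference={A})
        assert sets.strict == {A}
        assert sets.extended == {A, B}

    def test_all_zero_labels_empty_sets(self, letter_catalog):
        sheet = self._sheet(letter_catalog, [A, B])
        sets = derive_sets(sheet, {A: 0, B: 0}, reference={A})
        assert sets.strict == sets.extended == frozenset()

    def test_counts_on_larger_sheet(self, letter_catalog):
        items = [key(n) for n in "ABCDEFGH"] + [key("I"), key("J")]
        catalog = IcdCatalog([IcdCode("ICD10CM", n, f"d {n}") for n in "ABCDEFGHIJ"])
        producer = make_ranking(items, model_id="m1")
        sheet = build_review_sheet([producer], set(items), catalog, k=10, shuffle_seed=0)
        labels = {k: 2 for k in items[:4]}
        labels.update({k: 1 for k in items[4:7]})
        labels.update({k: 0 for k in items[7:]})
        sets = derive_sets(sheet, labels, reference={items[0]})
        assert len(sets.strict) == 4
        assert len(sets.extended) == 7

    def test_missing_annotation_rejected(self, letter_catalog):
        sheet = self._sheet(letter_catalog, [A, B])
        with pytest.raises(DataError, match="unannotated"):
            derive_sets(sheet, {A: 2}, reference={A})

    def test_out_of_range_label_rejected(self, letter_catalog):
        sheet = self._sheet(letter_catalog, [A, B])
        with pytest.raises(DataError, match="labels outside"):
            derive_sets(sheet, {A: 2, B: 3}, reference={A})

    def test_unknown_annotation_code_rejected(self, letter_catalog):
        sheet = self._sheet(letter_catalog, [A, B])
        with pytest.raises(DataError, match="not on the sheet"):
            derive_sets(sheet, {A: 2, B: 1, E: 0}, reference={A})

    def test_strict_subset_extended_enforced(self):
        with pytest.raises(DataError):
            PhenotypeSets(reference=frozenset(), strict=frozenset({A}), extended=frozenset())

    def test_read_annotations_roundtrip(self, tmp_path):
        path = tmp_path / "ann.csv"
        path.write_text("vocabulary,code,label\nICD10CM,A,2\nICD10CM,B,1\n")
        assert read_annotations(path) == {A: 2, B: 1}


class TestClassifyNewCodes:
    def test_strict_equals_reference_no_additions(self):
        defn = make_defn("P", [A, B])
        sets = PhenotypeSets(
            reference=frozenset({A, B}), strict=frozenset({A, B}), extended=frozenset({A, B})
        )
        report = classify_new_codes(sets, defn, [defn])
        assert report.counts() == {
            "additional_strict": 0,
            "additional_extended": 0,
            "out_of_hierarchy_strict": 0,
            "out_of_hierarchy_extended": 0,
        }

    def test_seventeen_additional_all_out_of_hierarchy(self):
        """Reviewer confirms 17 codes beyond the reference, none in any ancestor."""
        reference = frozenset({A, B})
        parent = make_defn("PARENT", [C])
        defn = make_defn("P", reference, parent="PARENT")
        extra = frozenset(key(f"N{i:02d}") for i in range(17))
        sets = PhenotypeSets(
            reference=reference, strict=reference | extra, extended=reference | extra
        )
        report = classify_new_codes(sets, defn, [parent, defn])
        assert len(report.additional_strict) == 17
        assert report.out_of_hierarchy_strict == extra

    def test_code_in_parent_set_is_in_hierarchy(self):
        parent = make_defn("PARENT", [C])
        defn = make_defn("P", [A], parent="PARENT")
        sets = PhenotypeSets(
            reference=frozenset({A}), strict=frozenset({A, C, D}), extended=frozenset({A, C, D})
        )
        report = classify_new_codes(sets, defn, [parent, defn])
        assert C in report.additional_strict
        assert C not in report.out_of_hierarchy_strict
        assert D in report.out_of_hierarchy_strict

    def test_cumulative_series(self):
        defn = make_defn("P", [A])
        sets = PhenotypeSets(
            reference=frozenset({A}), strict=frozenset({A, B}), extended=frozenset({A, B, C})
        )
        report = classify_new_codes(sets, defn, [defn], ranking_items=[A, B, C, D], k=4)
        cum = report.cumulative
        assert list(cum["cum_additional_strict"]) == [0, 1, 1, 1]
        assert list(cum["cum_additional_extended"]) == [0, 1, 2, 2]

    def test_reference_never_counted_as_additional(self):
        defn = make_defn("P", [A, B])
        sets = PhenotypeSets(
            reference=frozenset({A, B}), strict=frozenset({A}), extended=frozenset({A, B, C})
        )
        report = classify_new_codes(sets, defn, [defn])
        assert report.additional_strict == frozenset()
        assert report.additional_extended == {C}
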