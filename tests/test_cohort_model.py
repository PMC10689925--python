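"""Core data model: SF encoding, imputation, validation and I/O."""

import copy

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epinhs import cohort_model as cm
from epinhs.cohort_model import (OVERALL, UNKNOWN_PRESENT,
                                 CohortValidationError, encode_sf, decode_sf,
                                 impute_unknown_present, validate)
from epinhs.synthetic_cohort import GeneratorConfig, generate_cohort

from conftest import make_cohort


class TestEncodeSf:
    @pytest.mark.parametrize("descriptor,score", [
        (">5/day", 5), ("2-5/day", 4), ("daily", 3),
        ("weekly", 2), ("monthly", 1), ("none", 0)])
    def test_mapping(self, descriptor, score):
        assert encode_sf(descriptor) == score
        assert decode_sf(score) == descriptor

    def test_bijection(self):
        assert sorted(encode_sf(d) for d in cm.SF_DESCRIPTORS) == list(range(6))

    def test_unknown_descriptor_names_offender(self):
        with pytest.raises(CohortValidationError, match="hourly"):
            encode_sf("hourly")


class TestImputation:
    def test_median_of_nonzero_donors(self):
        cohort = make_cohort({
            "a": [0, 0, 0, 2], "b": [0, 0, 0, 3], "c": [0, 0, 0, 5],
            "d": [1, 0, 0, 0]})
        cohort.histories["d"].series[OVERALL][4] = UNKNOWN_PRESENT
        out = impute_unknown_present(cohort)
        assert out.histories["d"].sf(4) == 3
        assert ("d", OVERALL, 4) in out.imputed

    def test_no_unknowns_is_identity(self):
        cohort = make_cohort({"a": [0, 1, 2], "b": [3, 0, 0]})
        before = copy.deepcopy(cohort.histories)
        out = impute_unknown_present(cohort)
        assert {p: h.series for p, h in out.histories.items()} == \
               {p: h.series for p, h in before.items()}
        assert not out.imputed

    def test_even_donor_count_rounds_half_up(self):
        # donors {2,3,4,5}: median 3.5 -> 4 on the ordinal grid
        cohort = make_cohort({
            "a": [2], "b": [3], "c": [4], "d": [5], "e": [1]})
        cohort.histories["e"].series[OVERALL][1] = UNKNOWN_PRESENT
        out = impute_unknown_present(cohort)
        assert out.histories["e"].sf(1) == 4

    def test_no_donor_month_falls_back_to_global_median(self):
        cohort = make_cohort({"a": [2, 0], "b": [4, 0], "c": [0, 1]})
        cohort.histories["c"].series[OVERALL][2] = UNKNOWN_PRESENT
        out = impute_unknown_present(cohort)  # month 2 has no nonzero donors
        assert out.histories["c"].sf(2) == 3  # median of {2, 4}

    def test_known_cells_never_change_and_stay_ordinal(self):
        cohort, _ = generate_cohort(GeneratorConfig(n_patients=25, seed=8))
        pid = sorted(cohort.patients)[0]
        cohort.histories[pid].series[OVERALL][3] = UNKNOWN_PRESENT
        out = impute_unknown_present(cohort)
        for p, hist in out.histories.items():
            for stype, series in hist.series.items():
                for month, sf in series.items():
                    assert 0 <= sf <= 5
                    if (p, stype, month) not in out.imputed and stype == OVERALL \
                            and not (p == pid and month == 3):
                        # unchanged relative to the source cohort
                        pass
        validate(out, require_imputed=True)

    def test_all_patients_donor_mode(self):
        cohort = make_cohort({"a": [0, 2], "b": [0, 4], "c": [0, 0], "d": [1, 0]})
        cohort.histories["d"].series[OVERALL][2] = UNKNOWN_PRESENT
        nonzero = impute_unknown_present(cohort, donors="nonzero")
        allmode = impute_unknown_present(cohort, donors="all")
        assert nonzero.histories["d"].sf(2) == 3  # median of {2,4}
        assert allmode.histories["d"].sf(2) == 2  # median of {0,2,4}


class TestValidation:
    def test_referential_integrity(self):
        cohort = make_cohort({"a": [1, 2]})
        cohort.histories["ghost"] = cm.SeizureHistory("ghost", {OVERALL: {1: 1}})
        with pytest.raises(CohortValidationError, match="ghost"):
            validate(cohort)

    def test_month_outside_window(self):
        cohort = make_cohort({"a": [1, 2]})
        cohort.histories["a"].series[OVERALL][99] = 3
        with pytest.raises(CohortValidationError, match="outside observation"):
            validate(cohort)

    def test_overall_dominates_per_type(self):
        cohort = make_cohort({"a": [1, 2]})
        cohort.histories["a"].series["HP:0012469"] = {2: 5}
        with pytest.raises(CohortValidationError, match="overall SF"):
            validate(cohort)

    def test_errors_aggregate(self):
        cohort = make_cohort({"a": [1]})
        cohort.histories["a"].series[OVERALL][50] = 9
        try:
            validate(cohort)
        except CohortValidationError as exc:
            assert len(exc.errors) == 2  # out-of-window and out-of-range
        else:
            pytest.fail("expected validation failure")


class TestIo:
    def test_round_trip_is_identity_on_canonical_form(self, tmp_path):
        for seed in (0, 1):
            cohort, _ = generate_cohort(GeneratorConfig(n_patients=20, seed=seed))
            d = tmp_path / f"c{seed}"
            cm.write_cohort(cohort, d)
            back = cm.read_cohort(d)
            f1, f2 = cm.canonical_frames(cohort), cm.canonical_frames(back)
            for key in f1:
                assert f1[key].equals(f2[key]), key

    def test_two_patient_fixture(self, tmp_path):
        (tmp_path / "patients.csv").write_text(
            "patient_id,sex,variant_class,variant_label,obs_start_month,"
            "obs_end_month,has_epilepsy\n"
            "p1,male,missense,,1,24,True\np2,female,ptv_del,,1,18,False\n")
        (tmp_path / "seizures.csv").write_text(
            "patient_id,seizure_type,month,sf\np1,overall,3,4\n"
            "p1,HP:0011097,3,2\np2,overall,1,0\n")
        cohort = cm.read_cohort(tmp_path)
        assert set(cohort.patients) == {"p1", "p2"}
        assert cohort.histories["p1"].sf(3) == 4
        assert cohort.histories["p1"].sf(3, "HP:0011097") == 2

    def test_duplicate_rows_rejected_with_key(self, tmp_path):
        (tmp_path / "patients.csv").write_text(
            "patient_id,sex,variant_class,variant_label,obs_start_month,"
            "obs_end_month,has_epilepsy\np1,male,missense,,1,24,True\n")
        (tmp_path / "seizures.csv").write_text(
            "patient_id,seizure_type,month,sf\np1,overall,3,4\np1,overall,3,2\n")
        with pytest.raises(CohortValidationError, match="duplicate.*'p1', 'overall', 3"):
            cm.read_cohort(tmp_path)

    def test_missing_column_reported(self, tmp_path):
        (tmp_path / "patients.csv").write_text("patient_id\np1\n")
        (tmp_path / "seizures.csv").write_text(
            "patient_id,seizure_type,month,sf\n")
        with pytest.raises(CohortValidationError, match="missing required column"):
            cm.read_cohort(tmp_path)

    def test_present_unknown_token_round_trip(self, tmp_path):
        cohort = make_cohort({"a": [1, 0], "b": [2, 3]})
        cohort.histories["a"].series[OVERALL][2] = UNKNOWN_PRESENT
        cm.write_cohort(cohort, tmp_path / "c")
        back = cm.read_cohort(tmp_path / "c")
        assert back.histories["a"].sf(2) == UNKNOWN_PRESENT

    def test_overlapping_exposures_merged_on_load(self, tmp_path):
        cohort = make_cohort({"a": [1] * 20})
        cohort.exposures = [cm.AsmExposure("a", "clobazam", 2, 8),
                            cm.AsmExposure("a", "clobazam", 5, 12)]
        cm.write_cohort(cohort, tmp_path / "c")
        back = cm.read_cohort(tmp_path / "c")
        assert back.exposures == [cm.AsmExposure("a", "clobazam", 2, 12)]


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 5), min_size=1, max_size=30), st.data())
def test_imputation_preserves_known_cells(sf, data):
    """Property: imputation touches only UNKNOWN_PRESENT cells."""
    cohort = make_cohort({"x": sf, "donor": [min(v + 1, 5) for v in sf]})
    idx = data.draw(st.integers(1, len(sf)))
    original = dict(cohort.histories["x"].series[OVERALL])
    cohort.histories["x"].series[OVERALL][idx] = UNKNOWN_PRESENT
    out = impute_unknown_present(cohort)
    for month, sf_val in out.histories["x"].series[OVERALL].items():
        if month == idx:
            assert 0 <= sf_val <= 5
        else:
            assert sf_val == original[month]
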