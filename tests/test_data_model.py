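"""Tests for cohort domain types, validation, and CSV round trips."""

import numpy as np
import pandas as pd
import pytest

from ertmap import (
    BiomarkerMatrix,
    Cohort,
    CohortValidationError,
    Diagnosis,
    GroupSpec,
    Sex,
    SubjectRecord,
    load_cohort,
    make_fixture,
    select_group,
    write_cohort,
)


def subject(sid="s1", diagnosis=Diagnosis.HC, mmse=29.0, cdrsb=0.0, adas=5.0):
    return SubjectRecord(
        subject_id=sid, diagnosis=diagnosis, sex=Sex.F, age=72.0,
        mmse=mmse, cdrsb=cdrsb, adas=adas,
    )


class TestSubjectRecord:
    def test_valid(self):
        assert subject().mmse == 29.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mmse": 31.0},
            {"mmse": -0.5},
            {"cdrsb": 18.5},
            {"adas": 71.0},
        ],
    )
    def test_out_of_range_scores_rejected(self, kwargs):
        with pytest.raises(CohortValidationError, match="s1"):
            subject(**kwargs)


class TestBiomarkerMatrix:
    def test_canonical_count_enforced(self):
        with pytest.raises(CohortValidationError, match="ATH expects 68 regions"):
            BiomarkerMatrix(
                biomarker="ATH",
                region_names=[f"r{i}" for i in range(67)],
                subject_ids=["s1"],
                values=np.ones((1, 67)),
            )

    def test_synthetic_panel_free_count(self):
        mat = BiomarkerMatrix(
            biomarker="SYN_A",
            region_names=["a", "b"],
            subject_ids=["s1"],
            values=np.ones((1, 2)),
        )
        assert mat.n_regions == 2

    def test_missing_values_rejected(self):
        with pytest.raises(CohortValidationError, match="non-finite"):
            BiomarkerMatrix(
                biomarker="SYN_A",
                region_names=["a"],
                subject_ids=["s1"],
                values=np.array([[np.nan]]),
            )

    def test_duplicate_regions_rejected(self):
        with pytest.raises(CohortValidationError, match="duplicate region"):
            BiomarkerMatrix(
                biomarker="SYN_A",
                region_names=["a", "a"],
                subject_ids=["s1"],
                values=np.ones((1, 2)),
            )


class TestGroupSpec:
    def test_from_name(self):
        g = GroupSpec.from_name("hc_ad")
        assert g.members == frozenset({Diagnosis.HC, Diagnosis.AD})

    def test_inconsistent_members_rejected(self):
        with pytest.raises(CohortValidationError):
            GroupSpec(name="HC_AD", members=frozenset({Diagnosis.HC}))

    def test_unknown_name_rejected(self):
        with pytest.raises(CohortValidationError):
            GroupSpec.from_name("HC_ONLY")


class TestLoadCohort:
    def _write_minimal(self, tmp_path, mmse=29.0, n_regions=68):
        meta = pd.DataFrame(
            [
                {
                    "subject_id": "s1", "diagnosis": "HC", "sex": "F",
                    "age": 70.0, "mmse": mmse, "cdrsb": 0.0, "adas": 4.0,
                }
            ]
        )
        meta_path = tmp_path / "metadata.csv"
        meta.to_csv(meta_path, index=False)
        mat = pd.DataFrame(
            np.ones((1, n_regions)), columns=[f"r{i}" for i in range(n_regions)]
        )
        mat.insert(0, "subject_id", ["s1"])
        mat_path = tmp_path / "ath.csv"
        mat.to_csv(mat_path, index=False)
        return meta_path, mat_path

    def test_minimal_valid(self, tmp_path):
        meta_path, mat_path = self._write_minimal(tmp_path)
        cohort = load_cohort(meta_path, {"ATH": mat_path})
        assert cohort.n_subjects == 1 and cohort.matrices["ATH"].n_regions == 68

    def test_wrong_region_count(self, tmp_path):
        meta_path, mat_path = self._write_minimal(tmp_path, n_regions=67)
        with pytest.raises(CohortValidationError, match="ATH expects 68 regions"):
            load_cohort(meta_path, {"ATH": mat_path})

    def test_score_out_of_range_names_subject(self, tmp_path):
        meta_path, mat_path = self._write_minimal(tmp_path, mmse=31.0)
        with pytest.raises(CohortValidationError, match="s1"):
            load_cohort(meta_path, {"ATH": mat_path})

    def test_rows_with_missing_values_dropped(self, tmp_path):
        meta_path, mat_path = self._write_minimal(tmp_path)
        df = pd.read_csv(mat_path)
        extra = df.iloc[[0]].assign(subject_id="s2")
        extra.iloc[0, 3] = np.nan
        meta = pd.read_csv(meta_path)
        meta = pd.concat([meta, meta.assign(subject_id="s2")])
        meta.to_csv(meta_path, index=False)
        pd.concat([df, extra]).to_csv(mat_path, index=False)
        cohort = load_cohort(meta_path, {"ATH": mat_path})
        assert cohort.matrices["ATH"].subject_ids == ["s1"]
        assert cohort.n_subjects == 2


class TestRoundTrip:
    def test_write_then_load_bit_exact(self, tmp_path, tiny_cohort):
        paths = write_cohort(tiny_cohort, tmp_path)
        clone = load_cohort(
            paths["metadata"],
            {name: paths[name] for name in tiny_cohort.matrices},
        )
        for name, mat in tiny_cohort.matrices.items():
            np.testing.assert_array_equal(clone.matrices[name].values, mat.values)
            assert clone.matrices[name].region_names == mat.region_names
        for a, b in zip(clone.subjects, tiny_cohort.subjects):
            assert a == b


class TestSelectGroup:
    def _cohort(self, with_missing_ad_row=False):
        subjects = [
            subject("h1"), subject("h2"),
            subject("a1", Diagnosis.AD, mmse=22.0, cdrsb=5.0, adas=30.0),
            subject("a2", Diagnosis.AD, mmse=23.0, cdrsb=4.0, adas=31.0),
            subject("a3", Diagnosis.AD, mmse=21.0, cdrsb=6.0, adas=33.0),
        ]
        ids = ["h1", "h2", "a1", "a2", "a3"]
        mat_ids = ids[:-1] if with_missing_ad_row else ids
        matrices = {
            "SYN_A": BiomarkerMatrix(
                "SYN_A", ["r0", "r1"], list(ids), np.arange(10.0).reshape(5, 2)
            ),
            "MD": BiomarkerMatrix(
                "MD",
                [f"r{i}" for i in range(57)],
                list(mat_ids),
                np.ones((len(mat_ids), 57)),
            ),
        }
        return Cohort(subjects=subjects, matrices=matrices)

    def test_union_of_cohorts(self):
        X, y, ids = select_group(self._cohort(), "HC_AD", "SYN_A", "MMSE")
        assert X.shape == (5, 2)
        np.testing.assert_array_equal(y, [29.0, 29.0, 22.0, 23.0, 21.0])

    def test_absent_diagnosis_just_shrinks(self):
        X, _, _ = select_group(self._cohort(), "HC_MCI", "SYN_A", "MMSE")
        assert X.shape[0] == 2

    def test_per_biomarker_availability(self):
        X, _, ids = select_group(self._cohort(True), "HC_AD", "MD", "ADAS")
        assert X.shape[0] == 4 and "a3" not in ids

    def test_row_count_matches_per_diagnosis_sum(self, tiny_cohort):
        for group, expected in [("HC_MCI", 8), ("HC_AD", 8), ("HC_MCI_AD", 12)]:
            X, y, _ = select_group(tiny_cohort, group, "SYN_B", "CDRSB")
            assert X.shape[0] == expected == len(y)

    def test_empty_selection_raises(self):
        subjects = [subject("h1")]
        cohort = Cohort(
            subjects=subjects,
            matrices={
                "SYN_A": BiomarkerMatrix("SYN_A", ["r0"], [], np.empty((0, 1)))
            },
        )
        with pytest.raises(CohortValidationError, match="no subjects"):
            select_group(cohort, "HC_AD", "SYN_A", "MMSE")

    def test_missing_biomarker_raises(self, tiny_cohort):
        with pytest.raises(CohortValidationError, match="not present"):
            select_group(tiny_cohort, "HC_AD", "ATH", "MMSE")
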