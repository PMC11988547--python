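"""Clinical encoding, survival labels, genetic codes, balancing and splitting."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungmorph.assemble import (CLINICAL_COLUMNS, ValidationError, assemble,
                                balance_patient, build_patient_table,
                                cnv_code, decode_clinical, encode_clinical,
                                load_tables, snv_code, split_patients,
                                survival_label)
from lungmorph.nucfeat import FEATURE_COLUMNS
from lungmorph.synthetic import (CohortSpec, generate_cohort,
                                 sample_feature_rows, write_cohort)


def _raw(**over):
    base = {"sex": "Male", "race": "White", "age_at_diagnosis": 63.0,
            "T": "T2", "N": "N0", "M": "M0", "stage": "Stage II"}
    base.update(over)
    return base


class TestClinicalEncoding:
    @pytest.mark.parametrize("field,value,column,code", [
        ("sex", "Male", "Gender", 1),
        ("sex", "Female", "Gender", 2),
        ("race", "Asian", "Race", 2),
        ("race", "White", "Race", 4),
        ("T", "TX", "T", 5),
        ("T", "T1", "T", 1),
        ("N", "N3", "N", 4),
        ("M", "MX", "M", 5),
        ("M", "M1", "M", 2),
        ("stage", "Stage IV", "Stage", 4),
    ])
    def test_published_mapping(self, field, value, column, code):
        assert encode_clinical(_raw(**{field: value}))[column] == code

    def test_missing_race_is_unreported(self):
        assert encode_clinical(_raw(race=None))["Race"] == 0
        assert encode_clinical(_raw(race=float("nan")))["Race"] == 0

    def test_case_insensitive(self):
        assert encode_clinical(_raw(sex="FEMALE"))["Gender"] == 2

    def test_unmapped_value_names_field(self):
        with pytest.raises(ValidationError, match="T.*T9"):
            encode_clinical(_raw(T="T9"))

    def test_encoding_round_trip(self):
        for sex in ("Male", "Female"):
            for t in ("T1", "T2", "T3", "T4", "TX"):
                raw = _raw(sex=sex, T=t)
                enc = encode_clinical(raw)
                dec = decode_clinical(enc)
                assert dec["Gender"] == sex
                assert dec["T"] == t
        assert decode_clinical({"Race": 0})["Race"] == "Unreported"


class TestSurvivalLabel:
    @pytest.mark.parametrize("css,days,horizon,expected", [
        ("dead", 180, 365, 1),    # death before horizon
        ("alive", 800, 365, 2),   # followed past horizon
        ("dead", 800, 365, 2),    # died, but after the horizon
        ("alive", 100, 365, 0),   # unknown: censored before horizon
    ])
    def test_three_class_rule(self, css, days, horizon, expected):
        assert survival_label(css, days, horizon) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            survival_label("dead", -1, 365)


class TestGeneticCodes:
    @pytest.mark.parametrize("t,code", [
        (0.05, 0), (0.1, 0), (0.5, 1), (0.9, 1), (0.95, 2), (1.2, 2)])
    def test_cnv_classes_with_lower_boundary_ties(self, t, code):
        assert cnv_code(t) == code

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValidationError):
            cnv_code(-0.2)

    @pytest.mark.parametrize("vc,code", [
        ("Missense", 1), ("Nonsense", 1), ("Frame_Shift_Del", 1),
        ("Splice_Site", 1), ("Silent", 0), ("Intron", 0), ("3'UTR", 0),
        ("5′UTR", 0), ("RNA", 0), ("Splice region", 0)])
    def test_snv_vocabulary(self, vc, code):
        assert snv_code(vc) == code

    def test_unlisted_classification_rejected(self):
        with pytest.raises(ValidationError):
            snv_code("Nonsense_Mutation")


class TestBalancing:
    def _rows(self, n):
        return pd.DataFrame({"patient_id": "p", "Area": np.arange(n)})

    def test_undersampling_draws_distinct_originals(self):
        out = balance_patient(self._rows(350), target=200, seed=1)
        assert len(out) == 200
        assert out.Area.nunique() == 200

    def test_oversampling_keeps_every_original(self):
        out = balance_patient(self._rows(50), target=200, seed=1)
        assert len(out) == 200
        assert set(out.Area) == set(range(50))

    def test_exact_size_unchanged(self):
        out = balance_patient(self._rows(200), target=200, seed=1)
        assert out.Area.tolist() == list(range(200))

    def test_zero_rows_rejected(self):
        with pytest.raises(ValidationError):
            balance_patient(self._rows(0))

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(n=st.integers(1, 600), target=st.integers(1, 300),
           seed=st.integers(0, 2**31 - 1))
    def test_always_exactly_target_rows_from_originals(self, n, target, seed):
        out = balance_patient(self._rows(n), target=target, seed=seed)
        assert len(out) == target
        assert set(out.Area) <= set(range(n))
        if n < target:
            assert set(out.Area) == set(range(n))  # every original present


class TestSplitting:
    def test_published_cohort_arithmetic(self):
        ids = [f"p{i}" for i in range(1252)]
        subtypes = [1] * 525 + [2] * 727
        part = split_patients(ids, subtypes, seed=3)
        counts = Counter(part.values())
        assert counts == {"train": 752, "validation": 250, "test": 250}
        luad_train = sum(1 for i, s in zip(ids, subtypes)
                         if s == 1 and part[i] == "train")
        assert luad_train == 315
        lusc_train = sum(1 for i, s in zip(ids, subtypes)
                         if s == 2 and part[i] == "train")
        assert lusc_train == 437

    def test_small_single_stratum(self):
        part = split_patients([f"p{i}" for i in range(10)], seed=0)
        assert Counter(part.values()) == {"train": 6, "validation": 2, "test": 2}

    def test_no_patient_in_two_partitions(self):
        part = split_patients([f"p{i}" for i in range(57)],
                              [i % 2 for i in range(57)], seed=5)
        assert len(part) == 57  # each patient exactly one assignment

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError):
            split_patients(["a", "b", "c", "d"], [1, 1, 2, 2])

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(40)]
        assert split_patients(ids, seed=9) == split_patients(ids, seed=9)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortSpec(n_patients_class1=5,
                                      n_patients_class2=5, seed=13))


@pytest.fixture(scope="module")
def patients(cohort):
    return build_patient_table(p.to_raw() for p in cohort)


@pytest.fixture(scope="module")
def features(cohort):
    return sample_feature_rows(cohort, seed=13, rows_per_patient=30)


class TestAssemble:
    def test_subtype_design_has_46_factors(self, features, patients):
        ds = assemble(features, patients, task="subtype", target=30, seed=0)
        assert len(ds.feature_columns) == 46
        assert ds.label_column == "Type"

    def test_os_design_has_95_factors(self, features, patients):
        ds = assemble(features, patients, task="os2", target=30, seed=0)
        assert len(ds.feature_columns) == 95
        assert ds.label_column == "y2"
        assert len(FEATURE_COLUMNS) + len(CLINICAL_COLUMNS) + 15 + 27 + 26 == 95

    def test_row_count_is_target_times_patients(self, features, patients):
        ds = assemble(features, patients, task="subtype", target=30, seed=0)
        assert len(ds.rows) == 30 * 10

    def test_unknown_patients_dropped_with_count(self, features, patients,
                                                 caplog):
        extra = features.copy()
        extra.loc[:5, "patient_id"] = "GHOST"
        with caplog.at_level("WARNING"):
            ds = assemble(extra, patients, task="subtype", target=30, seed=0)
        assert "no record" in caplog.text
        assert "GHOST" not in set(ds.rows.patient_id)

    def test_partition_is_patient_level(self, features, patients):
        ds = assemble(features, patients, task="subtype", target=30, seed=0)
        for part in ("train", "validation", "test"):
            sub = ds.subset(part)
            other = {p for p, v in ds.partition.items() if v != part}
            assert not set(sub.patient_id) & other


class TestTableLoaders:
    def test_round_trip_through_tsv(self, tmp_path):
        cohort = generate_cohort(CohortSpec(n_patients_class1=3,
                                            n_patients_class2=3, seed=21))
        write_cohort(cohort, tmp_path, tiles_per_patient=1,
                     nuclei_per_tile=2, tile_size=64, seed=21)
        loaded = load_tables(tmp_path / "clinical.tsv", tmp_path / "cnv.tsv",
                             tmp_path / "snv.tsv", tmp_path / "mrna.tsv")
        direct = build_patient_table(p.to_raw() for p in cohort)
        assert loaded.shape == direct.shape
        pd.testing.assert_frame_equal(loaded.sort_index(), direct.sort_index(),
                                      check_like=True, atol=1e-9)
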