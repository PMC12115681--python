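"""Demographic preprocessing: QC rules, validation, binarisation, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from slicemap.phenotype import (CovariateScaler, PhenotypeRecord, ValidRanges,
                                binarize_label, derive_ld_or_odd, prepare_phenotype,
                                qc_filter, read_phenotype_csv, validate_record)


def rec(**kw):
    base = dict(subject_id="S1", qc_athena=1, qc_niak=1, dx_label=0, age=10.0,
                gender=1.0, handedness=1.0, full4_iq=100.0, secondary_dx="")
    base.update(kw)
    return PhenotypeRecord(**base)


class TestQCFilter:
    def test_both_zero_is_excluded(self):
        assert qc_filter([rec(qc_athena=0, qc_niak=0)]) == []

    @pytest.mark.parametrize("a,n", [(0, 1), (1, 0), (1, 1), (None, 1)])
    def test_one_passing_flag_retains_the_record(self, a, n):
        assert len(qc_filter([rec(qc_athena=a, qc_niak=n)])) == 1

    def test_missing_counts_as_questionable_only_with_the_other_flag_bad(self):
        assert qc_filter([rec(qc_athena=None, qc_niak=0)]) == []
        assert qc_filter([rec(qc_athena=None, qc_niak=None)]) == []

    def test_unparseable_qc_is_excluded_and_audited(self):
        bad = rec()
        bad.parse_errors.add("qc_athena")
        audit = []
        assert qc_filter([bad], audit=audit) == []
        assert audit[0][0] == "S1" and "unparseable" in audit[0][2]

    def test_counting_and_order_preservation(self):
        records = [rec(subject_id=f"S{i}", qc_athena=0 if i < 3 else 1,
                       qc_niak=0 if i < 3 else 1) for i in range(10)]
        kept = qc_filter(records)
        assert [r.subject_id for r in kept] == [f"S{i}" for i in range(3, 10)]


class TestValidation:
    def test_fully_valid_row_accepts(self):
        assert validate_record(rec()) == (True, None)

    @pytest.mark.parametrize("kw,reason", [
        (dict(dx_label=4), "dx_label"),
        (dict(dx_label=None), "dx_label"),
        (dict(full4_iq=None), "full4_iq"),
        (dict(full4_iq=300.0), "full4_iq"),
        (dict(age=45.0), "age"),
        (dict(gender=2.0), "gender"),
        (dict(handedness=None), "handedness"),
    ])
    def test_rejection_names_the_offending_field(self, kw, reason):
        ok, why = validate_record(rec(**kw))
        assert not ok and why == reason

    def test_filtering_is_idempotent(self):
        records = [rec(subject_id=f"S{i}", dx_label=i) for i in range(6)]
        once = [r for r in qc_filter(records) if validate_record(r)[0]]
        twice = [r for r in qc_filter(once) if validate_record(r)[0]]
        assert once == twice


class TestLdOrOdd:
    @pytest.mark.parametrize("text,expected", [
        ("ODD", 1),
        ("", 0),
        ("simple phobia; ODD", 1),
        ("Learning Disorder", 1),
        ("oppositional defiant disorder", 1),
        ("oddly specific phobia", 0),       # substring inside a word is not a match
        ("ld", 1),
    ])
    def test_token_matching(self, text, expected):
        assert derive_ld_or_odd(text) == expected

    @settings(deadline=None)
    @given(st.lists(st.sampled_from(["phobia", "anxiety", "ODD", "LD", "tic"]),
                    max_size=4))
    def test_matches_iff_a_vocab_token_is_present(self, tokens):
        text = "; ".join(tokens)
        assert derive_ld_or_odd(text) == int(bool({"ODD", "LD"} & set(tokens)))


class TestBinarisation:
    @pytest.mark.parametrize("dx,expected", [(0, 0), (1, 1), (2, 1), (3, 1)])
    def test_any_subtype_is_abnormal(self, dx, expected):
        assert binarize_label(dx) == expected

    def test_unvalidated_input_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            binarize_label(4)


class TestScaling:
    def attrs(self, ages):
        return pd.DataFrame(dict(age=ages, gender=[1.0] * len(ages),
                                 handedness=[0.0, 1.0, 2.0][:len(ages)],
                                 full4_iq=[90.0, 100.0, 110.0][:len(ages)],
                                 ld_or_odd=[0.0] * len(ages)))

    def test_minmax_maps_extremes_to_unit_interval(self):
        out = CovariateScaler().fit_transform(self.attrs([8.0, 12.0, 16.0]))
        assert list(out["age_norm"]) == [0.0, 0.5, 1.0]
        assert out.to_numpy().min() >= 0 and out.to_numpy().max() <= 1

    def test_heldout_value_above_training_max_clips_to_one(self):
        scaler = CovariateScaler().fit(self.attrs([8.0, 12.0, 16.0]))
        probe = self.attrs([25.0, 12.0, 8.0])
        assert scaler.transform(probe)["age_norm"].iloc[0] == 1.0

    def test_constant_attribute_maps_to_zero(self):
        df = self.attrs([10.0, 10.0, 10.0])
        out = CovariateScaler().fit_transform(df)
        assert (out["age_norm"] == 0.0).all()

    def test_binary_attributes_pass_through(self):
        df = self.attrs([8.0, 12.0, 16.0])
        df["gender"] = [0.0, 1.0, 0.0]
        out = CovariateScaler().fit_transform(df)
        assert list(out["gender"]) == [0.0, 1.0, 0.0]

    def test_exactly_five_components(self):
        out = CovariateScaler().fit_transform(self.attrs([8.0, 12.0, 16.0]))
        assert out.shape[1] == 5


class TestCsvRoundTrip:
    def test_missing_and_junk_values_are_flagged(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "Subject_ID,QC_Athena,QC_NIAK,DX,Age,Gender,Handedness,Full4_IQ,Secondary_DX\n"
            "S1,1,1,0,10,1,1,100,\n"
            "S2,x,1,0,10,1,1,100,ODD\n"
            "S3,1,1,2,,1,1,,\n")
        records = read_phenotype_csv(path)
        assert records[0].parse_errors == set()
        assert "qc_athena" in records[1].parse_errors
        assert records[2].age is None and records[2].full4_iq is None

    def test_pipeline_produces_labels_and_raw_attributes(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "Subject_ID,QC_Athena,QC_NIAK,DX,Age,Gender,Handedness,Full4_IQ,Secondary_DX\n"
            "S1,1,1,0,10,1,1,100,\n"
            "S2,0,0,1,11,0,1,105,\n"
            "S3,1,1,3,12,1,2,95,simple phobia; ODD\n")
        table, audit = prepare_phenotype(path)
        assert list(table["subject_id"]) == ["S1", "S3"]
        assert list(table["label"]) == [0, 1]
        assert list(table["ld_or_odd"]) == [0, 1]
        assert audit == [("S2", "qc_filter", "both QC flags questionable")]
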