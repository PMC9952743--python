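"""Preprocessing tests: IO round trips, cleaning, scaling and encoding."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import caselatent as cl
from caselatent.preprocess import (
    OTHER_LEVEL,
    SchemaError,
    ZeroVarianceError,
    drop_incomplete,
    fit_codec,
    load_static,
    split_train_test,
)


class TestLoadStatic:
    def test_round_trips_through_csv(self, small_cohort, tmp_path):
        path = tmp_path / "static.csv"
        small_cohort.static.to_csv(path, index=False)
        loaded, problems = load_static(path)
        assert problems == []
        assert loaded.to_csv(index=False) == small_cohort.static.to_csv(index=False)

    def test_missing_column_names_the_column(self, small_cohort, tmp_path):
        path = tmp_path / "bad.csv"
        small_cohort.static.drop(columns=["salary"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="salary"):
            load_static(path)

    def test_inverted_dates_are_flagged(self, small_cohort, tmp_path):
        static = small_cohort.static.copy()
        static.loc[2, "date_case_closed"] = "2000-01-01"
        path = tmp_path / "static.csv"
        static.to_csv(path, index=False)
        _, problems = load_static(path)
        assert any("row 2" in p and "precedes" in p for p in problems)


class TestDropIncomplete:
    def test_counts_missing_salary_rows(self, small_cohort):
        records = small_cohort.static.head(10).copy()
        records.loc[[1, 4], "salary"] = pd.NA
        survivors, n_dropped = drop_incomplete(records)
        assert len(survivors) == 8 and n_dropped == 2

    def test_complete_frame_is_identity(self, small_cohort):
        survivors, n_dropped = drop_incomplete(small_cohort.static)
        assert n_dropped == 0
        assert len(survivors) == len(small_cohort.static)

    def test_matches_independent_row_scan(self, small_cohort):
        damaged = cl.inject_missingness(small_cohort.static, 0.1, seed=8)
        survivors, n_dropped = drop_incomplete(damaged)
        # independent oracle: explicit per-row completeness check
        expected = 0
        for _, row in damaged.iterrows():
            fields = {c: row[c] for c in damaged.columns if c != "days_until_hlm"}
            complete = all(pd.notna(v) for v in fields.values())
            if row["blm_hlm_flag"] == cl.HLM and pd.isna(row["days_until_hlm"]):
                complete = False
            expected += complete
        assert len(survivors) == expected
        assert n_dropped == len(damaged) - expected

    def test_idempotent(self, small_cohort):
        damaged = cl.inject_missingness(small_cohort.static, 0.2, seed=1)
        once, _ = drop_incomplete(damaged)
        twice, dropped_again = drop_incomplete(once)
        assert dropped_again == 0
        pd.testing.assert_frame_equal(once, twice)


class TestScaler:
    def test_hand_computed_standard_scores(self):
        frame = pd.DataFrame({"age": [1.0, 2.0, 3.0]})
        scaler = cl.fit_scaler(frame, fields=["age"])
        assert scaler.means["age"] == 2.0
        assert scaler.sds["age"] == 1.0  # sample sd, n-1 denominator
        assert np.allclose(scaler.transform("age", np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_constant_field_raises_naming_it(self):
        frame = pd.DataFrame({"salary": [5.0, 5.0, 5.0]})
        with pytest.raises(ZeroVarianceError, match="salary"):
            cl.fit_scaler(frame, fields=["salary"])

    def test_params_frozen_after_transform(self, small_cohort):
        scaler = cl.fit_scaler(small_cohort.static)
        before = dict(scaler.means), dict(scaler.sds)
        scaler.transform("age", np.array([1.0, 99.0]))
        assert (dict(scaler.means), dict(scaler.sds)) == before


class TestVocabulary:
    def test_one_hot_definition(self):
        frame = pd.DataFrame({"industry": ["A", "B", "C"]})
        vocab = cl.CategoryVocabulary.fit(frame, fields=["industry"], strict=True)
        assert vocab.encode_column("industry", pd.Series(["B"])).tolist() == [[0.0, 1.0, 0.0]]

    def test_encode_decode_bijection(self, small_cohort):
        vocab = cl.CategoryVocabulary.fit(small_cohort.static)
        for field in vocab.fields:
            for i, level in enumerate(vocab.levels[field]):
                assert vocab.index_of(field, level) == i
                assert vocab.decode_index(field, i) == level

    def test_unknown_level_strict_vs_fallback(self):
        frame = pd.DataFrame({"cause": ["Fall", "Slip"]})
        strict = cl.CategoryVocabulary.fit(frame, fields=["cause"], strict=True)
        with pytest.raises(KeyError, match="Meteorite"):
            strict.index_of("cause", "Meteorite")
        lax = cl.CategoryVocabulary.fit(frame, fields=["cause"], strict=False)
        assert lax.decode_index("cause", lax.index_of("cause", "Meteorite")) == OTHER_LEVEL


class TestSplit:
    def test_five_percent_default(self, small_cohort):
        train, test = split_train_test(small_cohort.static, seed=0)
        assert len(test) == round(0.05 * len(small_cohort.static))
        assert len(train) + len(test) == len(small_cohort.static)

    def test_seeded_partition_is_stable(self, small_cohort):
        a = split_train_test(small_cohort.static, 0.2, seed=5)
        b = split_train_test(small_cohort.static, 0.2, seed=5)
        assert a[1]["case_id"].tolist() == b[1]["case_id"].tolist()

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(pd.DataFrame({"case_id": ["x"]}), 0.5, seed=0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(n=st.integers(10, 500), ratio=st.floats(0.05, 0.9))
    def test_split_is_a_partition(self, n, ratio):
        frame = pd.DataFrame({"case_id": [str(i) for i in range(n)]})
        train, test = split_train_test(frame, ratio, seed=1)
        assert len(train) + len(test) == n
        assert not set(train.case_id) & set(test.case_id)


class TestCodec:
    def test_feature_vector_groups_sum_to_one(self, small_cohort):
        codec = fit_codec(small_cohort.static)
        fv = codec.encode_record(small_cohort.static.iloc[0], day_passed=10.0)
        start = 0
        for f in codec.cat_fields:
            w = codec.vocab.width(f)
            assert fv.static_categorical[start : start + w].sum() == 1.0
            start += w

    def test_negative_day_rejected(self, small_cohort):
        codec = fit_codec(small_cohort.static)
        with pytest.raises(ValueError, match="day_passed"):
            codec.encode_record(small_cohort.static.iloc[0], day_passed=-1.0)

    def test_encode_decode_recovers_all_fields(self, small_cohort):
        """Feeding the encoded targets straight back through the decoder
        mapping recovers every modelled field (continuous up to the
        standardization round trip)."""
        records = small_cohort.static.head(50)
        codec = fit_codec(small_cohort.static)
        sl = pd.to_numeric(records["sl_total_days"]).to_numpy(dtype=float)
        hd = pd.to_numeric(records["days_until_hlm"], errors="coerce").to_numpy(dtype=float)
        batch = codec.encode_frame(records, sl, hd, with_targets=True)
        # perfect reconstruction: targets as continuous output, one-hot as probs
        probs = []
        for g, (_, width) in enumerate(codec.cat_output_groups):
            p = np.zeros((len(records), width))
            p[np.arange(len(records)), batch.y_cat_idx[:, g]] = 1.0
            probs.append(p)
        decoded = codec.decode_outputs(batch.y_cont, probs)
        for f in ("age", "salary", "alertness_score", "sl_total_days", "form7_pd"):
            assert np.allclose(decoded[f], pd.to_numeric(records[f]), atol=1e-9)
        for f in codec.cat_fields + ["blm_hlm_flag"]:
            assert (decoded[f].to_numpy() == records[f].to_numpy()).all()
        hlm_rows = ~np.isnan(hd)
        assert np.allclose(decoded.loc[hlm_rows, "hlm_day"], hd[hlm_rows], atol=1e-9)

    def test_alertness_flag_changes_width_by_one(self, small_cohort):
        with_a = fit_codec(small_cohort.static, use_alertness=True)
        without = fit_codec(small_cohort.static, use_alertness=False)
        assert with_a.n_cont_in - without.n_cont_in == 1
        assert "alertness_score" not in without.cont_input_fields

    def test_json_round_trip(self, small_cohort):
        codec = fit_codec(small_cohort.static)
        restored = cl.FeatureCodec.from_json(codec.to_json())
        records = small_cohort.static.head(5)
        a = codec.encode_frame(records, np.zeros(5))
        b = restored.encode_frame(records, np.zeros(5))
        assert np.array_equal(a.x_cont, b.x_cont)
        assert np.array_equal(a.x_cat, b.x_cat)
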