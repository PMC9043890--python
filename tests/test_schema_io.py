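"""Schema validation, cohort CSV round trips, and structural error handling."""

import numpy as np
import pandas as pd
import pytest

import proval as pv
from proval.exceptions import IntegrityError, RangeError, SchemaError

from conftest import make_cohort_frame


class TestSchema:
    def test_default_schema_structure(self, schema):
        assert len(schema.domains) == 7
        assert len(schema.item_ids) == 55
        assert sum(d.n_questions for d in schema.domains) == 22
        assert schema.domain("fears").n_questions == 1
        assert len(schema.anchor_labels) == 7

    def test_json_round_trip(self, schema, tmp_path):
        path = tmp_path / "schema.json"
        schema.to_json(path)
        back = pv.QuestionnaireSchema.from_json(path)
        assert back == schema

    @pytest.mark.parametrize("mutation,err", [
        (dict(minimum=4.0, maximum=4.0), "maximum"),   # degenerate range
        (dict(weight=0.0), "weight"),
    ])
    def test_item_invariants(self, mutation, err):
        kwargs = dict(item_id="x", question_id="q", minimum=1.0, maximum=4.0,
                      weight=1.0)
        kwargs.update(mutation)
        with pytest.raises(SchemaError, match=err):
            pv.ItemSpec(**kwargs)

    def test_duplicate_item_ids_rejected(self):
        dom = pv.DomainSpec(name="d1", items=(pv.ItemSpec("i1", "q1"),))
        dom2 = pv.DomainSpec(name="d2", items=(pv.ItemSpec("i1", "q2"),))
        with pytest.raises(SchemaError, match="duplicate"):
            pv.QuestionnaireSchema("inst", (dom, dom2))


class TestLoadCohort:
    def test_round_trip_preserves_cells(self, schema, tiny_frame, tmp_path):
        path = tmp_path / "cohort.csv"
        table = pv.CohortTable(tiny_frame, schema)
        table.write(path)
        back = pv.load_cohort(path, schema)
        assert len(back) == 4
        pd.testing.assert_frame_equal(
            back.data.astype(object).where(back.data.notna()),
            table.data.astype(object).where(table.data.notna()),
            check_dtype=False)

    def test_generated_cohort_round_trip(self, cohort, tmp_path):
        path = tmp_path / "big.csv"
        cohort.write(path)
        back = pv.load_cohort(path, cohort.schema)
        assert len(back) == len(cohort)
        a = pv.score_cohort(back)
        b = pv.score_cohort(cohort)
        pd.testing.assert_frame_equal(a, b, atol=1e-9)

    def test_out_of_range_sppb(self, schema, tiny_frame, tmp_path):
        tiny_frame.loc[0, "sppb"] = 13
        path = tmp_path / "bad.csv"
        tiny_frame.to_csv(path, index=False)
        with pytest.raises(RangeError, match="sppb"):
            pv.load_cohort(path, schema)

    def test_followup_without_baseline(self, schema, tiny_frame, tmp_path):
        frame = tiny_frame[~((tiny_frame.participant_id == "a")
                             & (tiny_frame.visit == "baseline"))]
        path = tmp_path / "orphan.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(IntegrityError, match="baseline"):
            pv.load_cohort(path, schema)

    def test_duplicate_participant_visit(self, schema, tiny_frame, tmp_path):
        frame = pd.concat([tiny_frame, tiny_frame.iloc[[0]]])
        path = tmp_path / "dup.csv"
        frame.to_csv(path, index=False)
        with pytest.raises(IntegrityError, match="duplicate"):
            pv.load_cohort(path, schema)

    def test_unknown_column_named_in_error(self, schema, tiny_frame, tmp_path):
        tiny_frame["mystery_col"] = 1
        path = tmp_path / "unknown.csv"
        tiny_frame.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="mystery_col"):
            pv.load_cohort(path, schema)

    def test_sentinel_string_rejected(self, schema, tiny_frame, tmp_path):
        tiny_frame.loc[0, "grip_kg"] = "NA"
        path = tmp_path / "sentinel.csv"
        tiny_frame.to_csv(path, index=False)
        with pytest.raises(RangeError, match="grip_kg"):
            pv.load_cohort(path, schema)

    def test_anchor_at_baseline_rejected(self, schema, tiny_frame):
        tiny_frame.loc[0, "anchor_fitness"] = "better"
        with pytest.raises(IntegrityError, match="anchor"):
            pv.CohortTable(tiny_frame, schema)

    def test_missing_cells_preserved(self, schema, tiny_frame, tmp_path):
        item = schema.item_ids[0]
        tiny_frame.loc[0, item] = np.nan
        path = tmp_path / "missing.csv"
        pv.CohortTable(tiny_frame, schema).write(path)
        back = pv.load_cohort(path, schema)
        assert np.isnan(back.data.loc[0, item])


class TestDescriptives:
    def _cohort(self, schema):
        rows = []
        ages = {"telephone": [70, 80, 90], "face_to_face": [70, 80, 90],
                "none": [60, 65, 95]}
        sexes = {"telephone": ["female", "male", "female"],
                 "face_to_face": ["female", "male", "female"],
                 "none": ["male", "male", "female"]}
        i = 0
        for mode in ages:
            for age, sex in zip(ages[mode], sexes[mode]):
                rows.append({"pid": f"p{i}", "visit": "baseline", "age_years": age,
                             "sex": sex, "followup_mode": mode})
                i += 1
        return pv.CohortTable(make_cohort_frame(schema, rows), schema)

    def test_identical_groups_not_significant(self, schema):
        table = self._cohort(schema)
        desc = pv.describe_cohort(table, group_by="followup_mode",
                                  variables=("age_years",), reference="telephone")
        row = desc[(desc.variable == "age_years") & (desc.group == "face_to_face")]
        assert row["test"].iloc[0] == "t-test"
        assert row["p"].iloc[0] == pytest.approx(1.0)
        mean_row = desc[(desc.variable == "age_years") & (desc.group == "telephone")]
        assert mean_row["center"].iloc[0] == pytest.approx(80.0)

    def test_balanced_categorical_not_significant(self, schema):
        table = self._cohort(schema)
        desc = pv.describe_cohort(table, group_by="followup_mode",
                                  variables=(), categorical=("sex",),
                                  reference="telephone")
        row = desc[(desc.variable == "sex=female") & (desc.group == "face_to_face")]
        assert row["test"].iloc[0] == "chi-squared"
        assert row["p"].iloc[0] == pytest.approx(1.0)

    def test_row_order_invariance(self, cohort):
        a = pv.describe_cohort(cohort)
        shuffled = pv.CohortTable(
            cohort.data.sample(frac=1, random_state=0), cohort.schema)
        b = pv.describe_cohort(shuffled)
        merged = a.merge(b, on=["variable", "group"], suffixes=("_a", "_b"))
        assert len(merged) == len(a)
        assert np.allclose(merged["center_a"].astype(float),
                           merged["center_b"].astype(float), equal_nan=True)
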