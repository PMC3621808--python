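import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sportmed import coding
from sportmed.coding import (
    CodingError,
    assemble_analytic_table,
    code_cognition,
    code_coparticipation,
    code_modelling,
    code_sports,
    code_support,
    code_table,
    score_equipment,
)


class TestSportsCoding:
    @pytest.mark.parametrize(
        "s1, s2, hours, participant",
        [
            (0, 0, 0.0, 0),  # the explicit no-participation option
            (0.5, 0, 0.5, 1),  # smallest non-zero response: 30 min/week
            (5.0, 5.0, 10.0, 1),  # both sports at the grid maximum
            (1.5, 2.0, 3.5, 1),
        ],
    )
    def test_sum_and_dichotomy(self, s1, s2, hours, participant):
        h, p = code_sports(s1, s2)
        assert h == hours and p == participant

    def test_missing_propagates(self):
        h, p = code_sports(None, 2.0)
        assert math.isnan(h) and math.isnan(p)

    @pytest.mark.parametrize("bad", [0.25, 5.5, -1, 7])
    def test_off_grid_rejected(self, bad):
        with pytest.raises(CodingError, match=str(float(bad))):
            code_sports(bad, 0)

    @given(
        s1=st.sampled_from([i * 0.5 for i in range(11)]),
        s2=st.sampled_from([i * 0.5 for i in range(11)]),
    )
    @settings(derandomize=True, max_examples=50)
    def test_participant_iff_positive_hours(self, s1, s2):
        hours, participant = code_sports(s1, s2)
        assert participant == (hours > 0)


class TestEquipment:
    def test_extremes_and_count(self):
        assert score_equipment([0] * 8) == 0
        assert score_equipment([1] * 8) == 8
        # exactly bike, ball and shoes owned
        items = {"bike": 1, "ball": 1, "shoes": 1}
        vec = [items.get(name, 0) for name in coding.EQUIPMENT_ITEMS]
        assert score_equipment(vec) == 3

    def test_non_binary_rejected(self):
        with pytest.raises(CodingError, match="racket"):
            score_equipment([1, 2, 0, 0, 0, 0, 0, 0])

    def test_missing_item_gives_missing_score(self):
        assert math.isnan(score_equipment([1, None, 1, 1, 0, 0, 0, 0]))


class TestLabelMaps:
    @pytest.mark.parametrize(
        "fn, label, code",
        [
            (code_support, "always", 4),
            (code_support, "never", 0),
            (code_support, " Often ", 3),  # trimming + case folding
            (code_coparticipation, "2-4 days a week", 3),
            (code_coparticipation, "never", 0),
            (code_coparticipation, "every day", 7),
            (code_coparticipation, "5-6 days a week", 5.5),
            (code_cognition, 1, -2),
            (code_cognition, 3, 0),
            (code_cognition, 5, 2),
        ],
    )
    def test_stated_codes(self, fn, label, code):
        assert fn(label) == code

    def test_modelling_sums(self):
        assert code_modelling("none", "none") == 0
        assert code_modelling("2h", "3h") == 5
        assert code_modelling(">=5h", ">=5h") == 10

    @pytest.mark.parametrize(
        "fn, bad",
        [
            (code_support, "rarely"),
            (code_support, 2.5),
            (code_coparticipation, "twice"),
            (code_cognition, 0),
            (code_cognition, 6),
        ],
    )
    def test_unknown_labels_rejected(self, fn, bad):
        with pytest.raises(CodingError):
            fn(bad)

    @given(st.text(max_size=12))
    @settings(derandomize=True, max_examples=60)
    def test_maps_total_on_label_set_and_reject_rest(self, text):
        known = {k.lower() for k in coding.SUPPORT_LABELS}
        key = text.strip().lower()
        if key in known:
            assert code_support(text) in {0, 1, 2, 3, 4}
        else:
            try:
                float(key)
            except ValueError:
                if key:  # non-numeric unknown label
                    with pytest.raises(CodingError):
                        code_support(text)


def _toy_table(n=10):
    return pd.DataFrame(
        {
            "sex": [0, 1] * (n // 2),
            "pbc": np.arange(n, dtype=float) % 5 - 2,
            "sport_participant": [0, 1] * (n // 2),
        }
    )


class TestAnalyticTable:
    def test_nothing_missing_keeps_everything(self):
        table = _toy_table()
        kept, report = assemble_analytic_table(table, ["sex", "pbc", "sport_participant"])
        assert len(kept) == 10 and report.n_excluded == 0 and report.by_column == {}

    def test_exclusions_attributed_to_column(self):
        table = _toy_table()
        table.loc[[1, 4, 7], "pbc"] = np.nan
        kept, report = assemble_analytic_table(table, ["sex", "pbc"])
        assert len(kept) == 7
        assert report.by_column == {"pbc": 3}
        assert report.n_kept + report.n_excluded == report.n_input == 10
        assert list(kept.index) == [0, 2, 3, 5, 6, 8, 9]  # order preserved
        assert not kept[["sex", "pbc"]].isna().any().any()

    def test_absent_required_column_errors(self):
        with pytest.raises(CodingError, match="absent"):
            assemble_analytic_table(_toy_table(), ["sex", "attitude"])

    def test_no_complete_cases_errors(self):
        table = _toy_table()
        table["pbc"] = np.nan
        with pytest.raises(CodingError, match="no complete cases"):
            assemble_analytic_table(table, ["pbc"])


class TestCodeTable:
    def _raw(self):
        row = {
            "child_id": "k1",
            "school_id": "s1",
            "country_id": "BE",
            "sex": "girl",
            "age_years": 11.2,
            "parent_education": ">= 14 years",
            "sport1_duration": 1.5,
            "sport2_duration": 0,
            "financial_support": "Often",
            "logistic_support": "sometimes",
            "emotional_support": "always",
            "reinforcement": "never",
            "coparticipation": "once a week",
            "modelling_weekday": "1h",
            "modelling_weekend": "30min",
            "attitude": 5,
            "belief": 3,
            "enjoyment": 4,
            "pbc": 2,
        }
        for item in coding.EQUIPMENT_ITEMS:
            row[f"equipment_{item}"] = 1 if item in ("bike", "ball") else 0
        return pd.DataFrame([row])

    def test_codes_one_row_end_to_end(self):
        coded = code_table(self._raw())
        r = coded.iloc[0]
        assert r.sex == 0 and r.parent_education == ">=14"
        assert r.equipment == 2
        assert (r.financial, r.logistic, r.emotional, r.reinforcement) == (3, 2, 4, 0)
        assert r.coparticipation == 1 and r.modelling == 1.5
        assert (r.attitude, r.belief, r.enjoyment, r.pbc) == (2, 0, 1, -1)
        assert r.sport_hours == 1.5 and r.sport_participant == 1

    def test_codebook_override(self):
        raw = self._raw()
        raw.loc[0, "financial_support"] = "veel"
        codebook = {"support": {**coding.SUPPORT_LABELS, "veel": 3.0}}
        assert code_table(raw, codebook).iloc[0].financial == 3

    def test_unknown_label_raises(self):
        raw = self._raw()
        raw.loc[0, "reinforcement"] = "soms"
        with pytest.raises(CodingError, match="soms"):
            code_table(raw)
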