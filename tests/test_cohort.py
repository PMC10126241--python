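import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from iitscreen import (
    EgfrStratum,
    Sex,
    apply_eligibility,
    assign_egfr_stratum,
    egfr_mdrd,
    is_anaemic,
    label_id_guideline,
    label_iit,
    read_cohort,
    tsat_from_iron,
)
from iitscreen.cohort import stratum_counts


class TestMdrd:
    def test_reference_value(self):
        # 175 * 1.0^-1.154 * 60^-0.203 for a 60-year-old man
        assert egfr_mdrd(1.0, 60, Sex.MALE) == pytest.approx(76.23, abs=0.02)

    def test_female_factor(self):
        male = egfr_mdrd(1.3, 72, "male")
        assert egfr_mdrd(1.3, 72, "female") == pytest.approx(0.742 * male, rel=1e-12)

    def test_black_factor(self):
        base = egfr_mdrd(1.3, 72, "male")
        assert egfr_mdrd(1.3, 72, "male", black=True) == pytest.approx(1.212 * base, rel=1e-12)

    def test_creatinine_power_law(self):
        assert egfr_mdrd(2.0, 60, "male") == pytest.approx(
            egfr_mdrd(1.0, 60, "male") * 2.0 ** -1.154, rel=1e-12
        )
        assert egfr_mdrd(2.0, 60, "male") == pytest.approx(34.25, abs=0.02)

    @given(
        cr=st.floats(0.3, 8.0),
        age=st.floats(18.0, 95.0),
        delta=st.floats(0.05, 2.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_strictly_decreasing_in_creatinine_and_age(self, cr, age, delta):
        base = egfr_mdrd(cr, age, "male")
        assert egfr_mdrd(cr + delta, age, "male") < base
        if age + delta <= 110:
            assert egfr_mdrd(cr, age + delta, "male") < base

    def test_input_validation(self):
        with pytest.raises(ValueError):
            egfr_mdrd(0.0, 60, "male")
        with pytest.raises(ValueError):
            egfr_mdrd(1.0, 17, "male")


class TestDerivedLabels:
    def test_tsat_from_iron(self):
        assert tsat_from_iron(76, 323) == pytest.approx(23.53, abs=0.01)
        assert tsat_from_iron(0, 300) == 0.0
        assert tsat_from_iron(300, 300) == 100.0
        assert tsat_from_iron(330, 300) == 100.0  # clipped at saturation
        with pytest.raises(ValueError):
            tsat_from_iron(50, 0)

    @pytest.mark.parametrize(
        "hb,sex,expected",
        [
            (13.0, "male", False),  # WHO boundary: strictly below
            (11.9, "female", True),
            (12.5, "male", True),
            (12.5, "female", False),
        ],
    )
    def test_who_anaemia(self, hb, sex, expected):
        assert is_anaemic(hb, sex) is expected

    @pytest.mark.parametrize("tsat,expected", [(15, True), (20.0, False), (28, False)])
    def test_iit_label(self, tsat, expected):
        assert label_iit(tsat) is expected

    @pytest.mark.parametrize(
        "ferritin,tsat,expected",
        [(67, 15, True), (150, 25, False), (300, 15, False), (150, 15, True), (299, 19.9, True)],
    )
    def test_guideline_id_label(self, ferritin, tsat, expected):
        assert label_id_guideline(ferritin, tsat) is expected

    def test_missing_inputs_error(self):
        for fn, args in [
            (is_anaemic, (math.nan, "male")),
            (label_iit, (math.nan,)),
            (label_id_guideline, (math.nan, 15)),
        ]:
            with pytest.raises(ValueError):
                fn(*args)

    @given(tsat=st.floats(0.0, 100.0), delta=st.floats(0.001, 50.0))
    @settings(max_examples=50, derandomize=True)
    def test_iit_monotone_step(self, tsat, delta):
        # once non-IIT, any higher TSAT is still non-IIT
        if not label_iit(tsat):
            assert not label_iit(tsat + delta)


class TestEgfrStrata:
    @pytest.mark.parametrize(
        "egfr,expected",
        [
            (90.0, EgfrStratum.G_GE90),
            (59.999, EgfrStratum.G_30_60),
            (60.0, EgfrStratum.G_60_90),
            (29.9, EgfrStratum.G_LT30),
            (0.0, EgfrStratum.G_LT30),
            (250.0, EgfrStratum.G_GE90),
        ],
    )
    def test_half_open_bins(self, egfr, expected):
        assert assign_egfr_stratum(egfr) is expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            assign_egfr_stratum(-1.0)
        with pytest.raises(ValueError):
            assign_egfr_stratum(math.nan)

    def test_partition_property(self, default_cohort):
        counts = stratum_counts(default_cohort.df["egfr"])
        assert sum(counts.values()) == default_cohort.n


class TestReadCohort:
    def test_empty_file_errors(self, cohort_csv):
        path = cohort_csv([])
        with pytest.raises(ValueError, match="empty cohort"):
            read_cohort(path)

    def test_identity_parse(self, cohort_csv):
        path = cohort_csv([{"patient_id": "p1", "sex": "male", "rdw": 14.0, "tsat": 15}])
        cohort = read_cohort(path)
        assert cohort.n == 1
        assert cohort.df.loc[0, "rdw"] == 14.0
        assert cohort.df.loc[0, "tsat"] == 15.0

    def test_missing_token_and_parse_log(self, cohort_csv):
        path = cohort_csv(
            [
                {"patient_id": "p1", "sex": "female", "tsat": "NA", "rdw": 13.0},
                {"patient_id": "p2", "sex": "male", "tsat": "??", "rdw": 14.0},
            ]
        )
        cohort = read_cohort(path)
        assert np.isnan(cohort.df.loc[0, "tsat"]) and np.isnan(cohort.df.loc[1, "tsat"])
        assert cohort.parse_log == [("p2", "tsat", "??")]

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("patient_id,rdw\np1,14\n")
        with pytest.raises(ValueError, match="mandatory column"):
            read_cohort(path)

    def test_column_map(self, tmp_path):
        path = tmp_path / "mapped.csv"
        path.write_text("ID,Gender,RDW_pct\np1,male,14.5\n")
        cohort = read_cohort(
            path, column_map={"ID": "patient_id", "Gender": "sex", "RDW_pct": "rdw"}
        )
        assert cohort.df.loc[0, "rdw"] == 14.5


class TestEligibility:
    @staticmethod
    def _base(pid, **kw):
        row = {"patient_id": pid, "sex": "male", "age": 60, "hb": 14.0,
               "rdw": 14.0, "tsat": 25.0}
        row.update(kw)
        return row

    def test_anaemic_male_excluded(self, cohort_csv):
        cohort = read_cohort(cohort_csv([self._base("p1", hb=12.5)]))
        out = apply_eligibility(cohort)
        assert out.n == 0
        assert out.exclusion_log == [("p1", "anaemia")]

    def test_nonanaemic_female_retained_and_iit(self, cohort_csv):
        cohort = read_cohort(
            cohort_csv([self._base("p1", sex="female", hb=12.5, tsat=18)])
        )
        out = apply_eligibility(cohort)
        assert out.n == 1
        assert label_iit(out.df.loc[0, "tsat"])

    def test_tsat_derived_from_iron_tibc(self, cohort_csv):
        cohort = read_cohort(
            cohort_csv([self._base("p1", tsat="", serum_iron=51, tibc=354)])
        )
        out = apply_eligibility(cohort)
        assert out.n == 1
        assert out.df.loc[0, "tsat"] == pytest.approx(100 * 51 / 354, abs=1e-9)
        assert out.df.loc[0, "tsat"] == pytest.approx(14.4, abs=0.01)

    def test_exclusion_flag_and_age(self, cohort_csv):
        rows = [
            self._base("p1", excluded_reason="recent transfusion"),
            self._base("p2", age=17),
            self._base("p3"),
        ]
        out = apply_eligibility(read_cohort(cohort_csv(rows)))
        assert list(out.df["patient_id"]) == ["p3"]
        reasons = dict(out.exclusion_log)
        assert reasons["p1"] == "recent transfusion"
        assert "age" in reasons["p2"]

    def test_idempotent(self, cohort_csv):
        rows = [
            self._base("p1", hb=12.0),
            self._base("p2"),
            self._base("p3", tsat="", serum_iron=60, tibc=300),
        ]
        once = apply_eligibility(read_cohort(cohort_csv(rows)))
        twice = apply_eligibility(once)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert once.exclusion_log == twice.exclusion_log
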