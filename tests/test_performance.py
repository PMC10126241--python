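import numpy as np
import pytest

from iitscreen import (
    ConfusionMatrix,
    GeneratorParams,
    confusion,
    generate_cohort,
    metrics,
    quadrant_table,
    stratified_metrics,
)
from iitscreen.cohort import STRATA_BEST_TO_WORST, EgfrStratum, iit_labels
from iitscreen.performance import round_half_away


class TestConfusion:
    def test_all_correct(self):
        cm = confusion([True, False, True], [True, False, True])
        assert (cm.fp, cm.fn) == (0, 0) and (cm.tp, cm.tn) == (2, 1)

    def test_all_wrong(self):
        cm = confusion([True, False], [False, True])
        assert (cm.tp, cm.tn) == (0, 0) and (cm.fp, cm.fn) == (1, 1)

    def test_hand_case(self):
        cm = confusion([True, True, False, False], [True, False, True, False])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([True], [True, False])


class TestMetrics:
    def test_published_count_reconstruction(self):
        # 262 IIT / 535 non-IIT with 345 true and 85 false negatives
        cm = ConfusionMatrix(tp=262 - 85, fp=535 - 345, fn=85, tn=345)
        m = metrics(cm)
        assert m.as_percent(rounded=True) == {
            "sensitivity": 68.0,
            "specificity": 64.0,
            "ppv": 48.0,
            "npv": 80.0,
            "prevalence": 33.0,
        }
        assert m.n == 797
        lo, hi = m.ci["sensitivity"]
        assert lo < m.sensitivity < hi

    def test_degenerate_denominators_flagged(self):
        with pytest.warns(UserWarning):
            m = metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=0))
        assert m.sensitivity == 1.0 and m.ppv == 1.0
        assert m.specificity is None and m.npv is None
        assert set(m.undefined) == {"specificity", "npv"}

    def test_symmetric_case(self):
        m = metrics(ConfusionMatrix(10, 10, 10, 10))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (0.5, 0.5, 0.5, 0.5)
        assert m.prevalence == 0.5

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(64.49) == 64.0
        assert round_half_away(67.5) == 68.0
        assert round_half_away(0.5) == 1.0
        assert round_half_away(-0.5) == -1.0
        assert round_half_away(33.125, 1) == 33.1


class TestStratified:
    def test_single_stratum_collapses_to_overall(self, cohort_csv):
        from iitscreen import read_cohort

        rows = [
            {"patient_id": f"p{i}", "sex": "male", "age": 60, "hb": 14,
             "rdw": rdw, "tsat": tsat, "egfr": 70 + i}
            for i, (rdw, tsat) in enumerate(
                [(15, 10), (14.5, 15), (13.0, 30), (13.5, 25), (15.5, 28), (12.9, 12)]
            )
        ]
        cohort = read_cohort(cohort_csv(rows))
        labels = iit_labels(cohort)
        rep = stratified_metrics(cohort, "rdw", 14.2, labels)
        m = rep.per_stratum[EgfrStratum.G_60_90]
        assert m.n == rep.overall.n == 6
        assert m.sensitivity == rep.overall.sensitivity
        assert m.npv == rep.overall.npv
        assert rep.per_stratum[EgfrStratum.G_LT30] is None

    def test_two_record_strata_hand_case(self, cohort_csv):
        from iitscreen import read_cohort

        rows = [
            # G_GE90: one true positive, one true negative at cutoff 14.2
            {"patient_id": "a", "sex": "male", "age": 60, "hb": 14, "rdw": 15.0,
             "tsat": 10, "egfr": 95},
            {"patient_id": "b", "sex": "male", "age": 60, "hb": 14, "rdw": 13.0,
             "tsat": 30, "egfr": 95},
            # G_LT30: one false positive, one false negative
            {"patient_id": "c", "sex": "male", "age": 60, "hb": 14, "rdw": 15.0,
             "tsat": 30, "egfr": 20},
            {"patient_id": "d", "sex": "male", "age": 60, "hb": 14, "rdw": 13.0,
             "tsat": 10, "egfr": 20},
        ]
        cohort = read_cohort(cohort_csv(rows))
        rep = stratified_metrics(cohort, "rdw", 14.2, iit_labels(cohort))
        top = rep.per_stratum[EgfrStratum.G_GE90]
        bottom = rep.per_stratum[EgfrStratum.G_LT30]
        assert (top.sensitivity, top.specificity) == (1.0, 1.0)
        assert (bottom.sensitivity, bottom.specificity) == (0.0, 0.0)
        n, mean, sd = rep.marker_summary[EgfrStratum.G_GE90]
        assert n == 2 and mean == pytest.approx(14.0) and sd == pytest.approx(np.sqrt(2.0))

    def test_prevalence_invariant_to_cutoff(self, default_cohort):
        labels = iit_labels(default_cohort)
        r1 = stratified_metrics(default_cohort, "rdw", 13.0, labels)
        r2 = stratified_metrics(default_cohort, "rdw", 15.5, labels)
        assert r1.overall.prevalence == r2.overall.prevalence
        for s in STRATA_BEST_TO_WORST:
            assert r1.per_stratum[s].prevalence == r2.per_stratum[s].prevalence

    def test_class_reweighting_moves_ppv_not_sens(self, large_cohort):
        # duplicating positives changes prevalence and predictive values but
        # leaves the class-conditional sens/spec unchanged
        import pandas as pd
        from iitscreen.cohort import CohortTable

        labels = iit_labels(large_cohort)
        df = large_cohort.df
        dup = df.loc[labels].copy()
        dup["patient_id"] = dup["patient_id"] + "_dup"
        boosted = CohortTable(df=pd.concat([df, dup], ignore_index=True))
        r0 = stratified_metrics(large_cohort, "rdw", 14.2, labels)
        r1 = stratified_metrics(boosted, "rdw", 14.2, iit_labels(boosted))
        assert r1.overall.prevalence > r0.overall.prevalence
        assert r1.overall.sensitivity == pytest.approx(r0.overall.sensitivity, abs=1e-12)
        assert r1.overall.specificity == pytest.approx(r0.overall.specificity, abs=1e-12)
        assert r1.overall.ppv > r0.overall.ppv
        assert r1.overall.npv < r0.overall.npv

    def test_stratum_sizes_sum_to_cohort(self, default_cohort):
        rep = stratified_metrics(default_cohort, "rdw", 14.2, iit_labels(default_cohort))
        assert sum(rep.marker_summary[s][0] for s in STRATA_BEST_TO_WORST) == default_cohort.n


class TestQuadrant:
    def test_single_record(self, cohort_csv):
        from iitscreen import read_cohort

        cohort = read_cohort(cohort_csv([
            {"patient_id": "a", "sex": "male", "age": 60, "hb": 14,
             "rdw": 15.0, "tsat": 10, "egfr": 80},
        ]))
        table = quadrant_table(cohort, "rdw", 14.2, iit_labels(cohort))
        assert table["percent_of_cohort"].sum() == pytest.approx(100.0)
        cell = table[table["n"] == 1].iloc[0]
        assert cell["percent_of_cohort"] == 100.0
        assert cell["iit_prevalence"] == 1.0

    def test_cutoff_below_all_values(self, default_cohort):
        table = quadrant_table(default_cohort, "rdw", 5.0, iit_labels(default_cohort))
        below = table[table["marker_group"].str.contains("<")]
        assert (below["n"] == 0).all()
        assert table["percent_of_cohort"].sum() == pytest.approx(100.0)

    def test_hand_constructed_cells(self, cohort_csv):
        from iitscreen import read_cohort

        # 8 records: 2 per quadrant at split eGFR 60, cutoff 14.2
        rows = []
        combos = [(15.0, 80, 10), (15.0, 80, 30), (15.0, 40, 10), (15.0, 40, 10),
                  (13.0, 80, 30), (13.0, 80, 30), (13.0, 40, 10), (13.0, 40, 30)]
        for i, (rdw, egfr, tsat) in enumerate(combos):
            rows.append({"patient_id": f"p{i}", "sex": "male", "age": 60, "hb": 14,
                         "rdw": rdw, "egfr": egfr, "tsat": tsat})
        cohort = read_cohort(cohort_csv(rows))
        table = quadrant_table(cohort, "rdw", 14.2, iit_labels(cohort), egfr_split=(60.0,))
        assert (table["n"] == 2).all()
        assert (table["percent_of_cohort"] == 25.0).all()
        cell = table[(table["marker_group"] == "rdw >= 14.2")
                     & (table["egfr_group"] == "[60, inf)")].iloc[0]
        assert cell["iit_prevalence"] == 0.5

    def test_percentages_sum_property(self, large_cohort):
        table = quadrant_table(large_cohort, "rdw", 14.2, iit_labels(large_cohort),
                               egfr_split=(30.0, 60.0, 90.0))
        assert table["percent_of_cohort"].sum() == pytest.approx(100.0)
        assert table["n"].sum() == large_cohort.n
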