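"""Clinical pipeline: dichotomization, chi-square screening, 9-bit encoding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dpanet import clinical as cl

# Printed reference p-values for the 167-patient contingency tables (rounded
# to three decimals as reported; "<0.001" rows are asserted as upper bounds).
PRINTED_P = {
    "sex": 0.826,
    "age": 0.018,
    "tumor_size_mm": None,  # < 0.001
    "tumor_number": 0.152,
    "portal_vein_invasion": 0.001,
    "cirrhosis": 0.794,
    "hbv": 0.054,
    "nlr": 0.039,
    "alt": 0.417,
    "ast": 0.500,
    "akp": 0.054,
    "ggt": 0.065,
    "alb": 0.256,
    "tb": 0.020,
    "afp": 0.003,
    "cp_level": 0.132,
    "bclc": None,  # < 0.001
}


def table(variable):
    return cl.ContingencyTable(
        variable,
        np.asarray(cl.TABLE1_COUNTS[variable]),
        row_labels=[str(i) for i in range(len(cl.TABLE1_COUNTS[variable]))],
    )


class TestDichotomize:
    def make(self, **overrides):
        raw = {
            "sex": "male", "age": 65, "tumor_size_mm": 30, "tumor_number": 1,
            "portal_vein_invasion": "no", "cirrhosis": "yes", "hbv": "yes",
            "nlr": 1.5, "alt": 22, "ast": 30, "akp": 80, "ggt": 40,
            "alb": 45, "tb": 12, "afp": 4, "cp_level": "A", "bclc": "A",
        }
        raw.update(overrides)
        return cl.ClinicalRecord("p1", raw, label=0)

    @pytest.mark.parametrize(
        "var,value,expected",
        [
            ("age", 65, 1),          # at/above the 60-year cutoff
            ("age", 59.999, 0),      # strictly below -> low category
            ("age", 60, 1),          # boundary belongs to the high category
            ("tumor_size_mm", 50, 1),
            ("nlr", 2.79, 0),
            ("bclc", "B", 2),        # index within ordered {0, A, B, C}
            ("bclc", "0", 0),
        ],
    )
    def test_category_assignment(self, var, value, expected):
        rec = cl.dichotomize_record(self.make(**{var: value}))
        assert rec.dichotomized[var] == expected

    def test_unknown_category_reports_patient_and_variable(self):
        with pytest.raises(cl.ClinicalDataError, match="p1.*bclc"):
            cl.dichotomize_record(self.make(bclc="D"))

    def test_missing_variable_reported(self):
        rec = self.make()
        del rec.raw["afp"]
        with pytest.raises(cl.ClinicalDataError, match="p1.*afp"):
            cl.dichotomize_record(rec)


class TestContingency:
    @given(
        st.lists(
            st.tuples(st.integers(0, 3), st.integers(0, 1)),
            min_size=1, max_size=60,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_counts_equal_direct_tally(self, assignments):
        records = [
            cl.ClinicalRecord(f"p{i}", {}, label=lab, dichotomized={"bclc": cat})
            for i, (cat, lab) in enumerate(assignments)
        ]
        tab = cl.build_contingency_table(records, "bclc")
        for cat in range(4):
            for lab in (0, 1):
                expected = sum(1 for c, l in assignments if c == cat and l == lab)
                assert tab.counts[cat, lab] == expected
        assert tab.counts.sum() == len(assignments)

    def test_reference_age_split(self):
        recs = cl.records_from_reference_counts(seed=3)
        tab = cl.build_contingency_table(recs, "age")
        np.testing.assert_array_equal(tab.counts, [[55, 47], [47, 18]])

    def test_empty_cohort_errors(self):
        with pytest.raises(cl.ClinicalDataError, match="empty"):
            cl.build_contingency_table([], "age")

    def test_single_category_table_rejected_downstream(self):
        tab = cl.ContingencyTable("age", np.array([[10, 5]]), ["<60"])
        with pytest.raises(cl.ClinicalDataError, match="degenerate|single"):
            cl.pearson_chi_square(tab)


class TestChiSquare:
    @pytest.mark.parametrize("variable,printed", sorted(PRINTED_P.items()))
    def test_reference_p_values_reproduced(self, variable, printed):
        """Every reference table p-value matches its printed rounding."""
        res = cl.pearson_chi_square(table(variable))
        if printed is None:
            assert res.p_value < 0.001
        else:
            assert round(res.p_value, 3) == pytest.approx(printed)

    def test_bclc_df(self):
        res = cl.pearson_chi_square(table("bclc"))
        assert res.df == 3

    def test_independence_gives_zero_statistic(self):
        tab = cl.ContingencyTable("x", np.array([[10, 10], [10, 10]]), ["a", "b"])
        res = cl.pearson_chi_square(tab)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_agrees_with_brute_force_oracle(self, rng):
        """1,000 random r x 2 tables against an explicit O/E loop + chi2 sf."""
        for _ in range(1000):
            r = int(rng.integers(2, 5))
            counts = rng.integers(1, 40, size=(r, 2))
            res = cl.pearson_chi_square(
                cl.ContingencyTable("x", counts, [str(i) for i in range(r)])
            )
            total = counts.sum()
            stat = 0.0
            for i in range(r):
                for j in range(2):
                    e = counts[i].sum() * counts[:, j].sum() / total
                    stat += (counts[i, j] - e) ** 2 / e
            assert res.statistic == pytest.approx(stat, abs=1e-10)
            assert res.p_value == pytest.approx(
                float(stats.chi2.sf(stat, r - 1)), abs=1e-10
            )

    def test_row_permutation_invariance(self, rng):
        counts = np.array([[17, 5], [78, 39], [1, 3], [6, 18]])
        base = cl.pearson_chi_square(
            cl.ContingencyTable("x", counts, list("abcd"))
        ).statistic
        for _ in range(10):
            perm = rng.permutation(4)
            s = cl.pearson_chi_square(
                cl.ContingencyTable("x", counts[perm], list("abcd"))
            ).statistic
            assert s == pytest.approx(base, rel=1e-12)

    def test_zero_cell_allowed_zero_marginal_not(self):
        # a zero cell (as in the albumin table) is fine
        cl.pearson_chi_square(table("alb"))
        bad = cl.ContingencyTable("x", np.array([[0, 0], [5, 7]]), ["a", "b"])
        with pytest.raises(cl.ClinicalDataError, match="marginal"):
            cl.pearson_chi_square(bad)


class TestSelection:
    def results(self):
        return {v: cl.pearson_chi_square(table(v)) for v in cl.TABLE1_COUNTS}

    def test_reference_selection_is_the_seven_encoded_variables(self):
        sel = cl.select_significant_variables(self.results(), alpha=0.05)
        assert sel == [
            "age", "tumor_size_mm", "portal_vein_invasion", "nlr", "tb",
            "afp", "bclc",
        ]

    def test_alpha_one_returns_everything(self):
        assert set(cl.select_significant_variables(self.results(), alpha=1.0)) == set(
            cl.TABLE1_COUNTS
        )

    def test_nothing_significant(self):
        res = {v: cl.ChiSquareResult(0.0, 1, 0.5) for v in ("age", "afp")}
        assert cl.select_significant_variables(res, 0.05) == []

    def test_empty_results_error(self):
        with pytest.raises(cl.ClinicalDataError):
            cl.select_significant_variables({}, 0.05)


class TestEncoding:
    def rec(self, **cats):
        d = {"age": 0, "tumor_size_mm": 0, "portal_vein_invasion": 0,
             "nlr": 0, "tb": 0, "afp": 0, "bclc": 0}
        d.update(cats)
        return cl.ClinicalRecord("p", {}, 0, dichotomized=d)

    def test_all_high_bclc_b(self):
        vec = cl.encode_clinical_vector(
            self.rec(age=1, tumor_size_mm=1, portal_vein_invasion=1,
                     nlr=1, tb=1, afp=1, bclc=2)
        )
        np.testing.assert_array_equal(vec, [1, 1, 1, 1, 1, 1, 0, 1, 0])

    def test_all_low_bclc_0(self):
        np.testing.assert_array_equal(
            cl.encode_clinical_vector(self.rec()), np.zeros(9, dtype=int)
        )

    def test_bclc_a_code(self):
        vec = cl.encode_clinical_vector(self.rec(age=1, bclc=1))
        np.testing.assert_array_equal(vec[6:], [0, 0, 1])

    def test_missing_selected_variable(self):
        rec = self.rec()
        del rec.dichotomized["tb"]
        with pytest.raises(cl.ClinicalDataError, match="tb"):
            cl.encode_clinical_vector(rec)

    @given(
        age=st.integers(0, 1), size=st.integers(0, 1), pvi=st.integers(0, 1),
        nlr=st.integers(0, 1), tb=st.integers(0, 1), afp=st.integers(0, 1),
        bclc=st.integers(0, 3),
    )
    @settings(max_examples=64, deadline=None)
    def test_encode_decode_identity(self, age, size, pvi, nlr, tb, afp, bclc):
        rec = self.rec(age=age, tumor_size_mm=size, portal_vein_invasion=pvi,
                       nlr=nlr, tb=tb, afp=afp, bclc=bclc)
        vec = cl.encode_clinical_vector(rec)
        assert set(np.unique(vec)) <= {0, 1}
        decoded = cl.decode_clinical_vector(vec)
        assert decoded == rec.dichotomized
        np.testing.assert_array_equal(
            cl.encode_clinical_vector(cl.ClinicalRecord("q", {}, 0, decoded)), vec
        )

    def test_illegal_bclc_code_rejected(self):
        with pytest.raises(cl.ClinicalDataError, match="BCLC"):
            cl.decode_clinical_vector(np.array([0, 0, 0, 0, 0, 0, 1, 1, 0]))


class TestCohortLevel:
    def test_report_frame_and_csv_roundtrip(self, tmp_path):
        recs = cl.records_from_reference_counts(seed=0)
        rep = cl.chi_square_report(recs)
        assert rep.shape[0] == 17
        assert rep[rep.selected].variable.tolist() == list(cl.VECTOR_ORDER)
        path = tmp_path / "report.csv"
        rep.to_csv(path, index=False)
        back = pd.read_csv(path)
        assert back.p_value.between(0, 1).all()

    def test_cohort_report_prevalence(self):
        recs = cl.records_from_reference_counts(seed=0)
        rep = cl.cohort_report(recs)
        assert rep["n_er"] == 65 and rep["n_patients"] == 167
        assert rep["er_prevalence_pct"] == 38.9

    def test_read_clinical_csv_missing_value_errors(self, tmp_path):
        recs = cl.records_from_reference_counts(seed=0)[:5]
        rows = []
        for r in recs:
            row = {"patient_id": r.patient_id, "label": "ER" if r.label else "NER"}
            row.update(r.raw)
            rows.append(row)
        df = pd.DataFrame(rows, columns=cl.CSV_COLUMNS)
        good = tmp_path / "ok.csv"
        df.to_csv(good, index=False)
        assert len(cl.read_clinical_csv(good)) == 5

        df.loc[2, "afp"] = np.nan
        bad = tmp_path / "bad.csv"
        df.to_csv(bad, index=False)
        with pytest.raises(cl.ClinicalDataError, match="missing values"):
            cl.read_clinical_csv(bad)
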