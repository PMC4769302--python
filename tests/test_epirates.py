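import datetime as dt

import numpy as np
import pytest

from codelistkit import (
    CaseRecord,
    Registration,
    compare_rates,
    financial_year,
    incidence,
    prevalence,
    year_labels,
)
from codelistkit.epirates import fy_span, read_registrations, write_rates, write_registrations
from codelistkit.errors import GridMismatchError, MissingRegistrationError


def _case(pid, iso):
    return CaseRecord(pid, dt.date.fromisoformat(iso), 1, frozenset({"C1"}))


def _reg(pid, start, end=None, sex="female"):
    return Registration(
        pid, sex, dt.date.fromisoformat(start),
        dt.date.fromisoformat(end) if end else None,
    )


class TestFinancialYear:
    @pytest.mark.parametrize(
        "iso, label",
        [
            ("2000-04-01", "2000/01"),
            ("2001-03-31", "2000/01"),
            ("2001-04-01", "2001/02"),
            ("1999-12-25", "1999/00"),
            ("2009-04-01", "2009/10"),
        ],
    )
    def test_boundaries(self, iso, label):
        assert financial_year(dt.date.fromisoformat(iso)) == label

    def test_label_changes_exactly_once_across_366_days(self):
        days = [dt.date(2000, 10, 1) + dt.timedelta(days=i) for i in range(366)]
        labels = [financial_year(d) for d in days]
        changes = sum(a != b for a, b in zip(labels, labels[1:]))
        assert changes == 1
        assert labels[0] == "2000/01" and labels[-1] == "2001/02"

    def test_year_labels_range(self):
        assert year_labels(1999, 2001) == ["1999/00", "2000/01", "2001/02"]
        assert fy_span("2000/01") == (dt.date(2000, 4, 1), dt.date(2001, 3, 31))


class TestPrevalence:
    def test_patient_prevalent_from_onset_year_onward(self):
        regs = [_reg("p1", "1999-01-01", "2005-12-31")]
        cases = [_case("p1", "2001-06-01")]
        table = prevalence(cases, regs, year_labels(2000, 2003))
        by_year = table.set_index("year")["numerator"]
        assert by_year["2000/01"] == 0
        assert by_year["2001/02"] == 1
        assert by_year["2002/03"] == 1
        assert (table["denominator"] == 1).all()

    def test_zero_cases_gives_zero_numerators(self):
        regs = [_reg("p1", "1999-01-01")]
        table = prevalence([], regs, year_labels(2000, 2002))
        assert (table["numerator"] == 0).all()

    def test_case_missing_from_registrations_is_an_error(self):
        with pytest.raises(MissingRegistrationError, match="p9"):
            prevalence([_case("p9", "2001-06-01")], [_reg("p1", "1999-01-01")],
                       year_labels(2000, 2001))

    def test_registration_window_bounds_the_denominator(self):
        regs = [_reg("p1", "2001-04-01", "2002-03-31"), _reg("p2", "1999-01-01")]
        table = prevalence([], regs, year_labels(2000, 2002))
        assert table.set_index("year")["denominator"].tolist() == [1, 2, 1]

    def test_zero_denominator_flagged_as_nan_not_zero(self):
        regs = [_reg("p1", "2005-01-01")]
        table = prevalence([], regs, year_labels(2000, 2001))
        assert table["rate"].isna().all()
        assert (table["denominator"] == 0).all()

    def test_non_decreasing_for_closed_cohort(self):
        regs = [_reg(f"p{i}", "1999-01-01") for i in range(30)]
        cases = [_case(f"p{i}", f"200{i % 5}-06-01") for i in range(10)]
        table = prevalence(cases, regs, year_labels(2000, 2006))
        rates = table["rate"].to_numpy()
        assert (np.diff(rates) >= 0).all()


class TestIncidence:
    def test_incident_in_exactly_one_year(self):
        regs = [_reg("p1", "1999-01-01")]
        cases = [_case("p1", "2001-06-01")]
        table = incidence(cases, regs, year_labels(2000, 2003))
        assert table.set_index("year")["numerator"].tolist() == [0, 1, 0, 0]

    def test_prior_cases_leave_the_at_risk_denominator(self):
        regs = [_reg("p1", "1999-01-01"), _reg("p2", "1999-01-01")]
        cases = [_case("p1", "2000-06-01")]
        table = incidence(cases, regs, year_labels(2000, 2001))
        den = table.set_index("year")["denominator"]
        assert den["2000/01"] == 2
        assert den["2001/02"] == 1  # p1 already a case

    def test_event_orderings_against_hand_computed_table(self):
        # Enumerate the orderings of (reg_start, event, reg_end) on toy data.
        regs = [
            _reg("in_window", "2000-05-01", "2003-03-31"),
            _reg("event_before_reg_same_fy", "2001-07-01", "2003-03-31"),
            _reg("event_before_reg_far", "2003-04-10", None),
            _reg("event_after_reg_end", "2000-05-01", "2001-03-31"),
        ]
        cases = [
            _case("in_window", "2001-06-01"),            # counted in 2001/02
            _case("event_before_reg_same_fy", "2001-05-01"),  # reg overlaps 2001/02 -> counted
            _case("event_before_reg_far", "2001-05-01"), # onset year never registered -> excluded
            _case("event_after_reg_end", "2002-05-01"),  # onset year after reg end -> excluded
        ]
        table = incidence(cases, regs, year_labels(2001, 2002))
        num = table.set_index("year")["numerator"]
        assert num["2001/02"] == 2
        assert num["2002/03"] == 0
        assert table.attrs["n_excluded_cases"] == 2

    def test_numerator_never_exceeds_denominator(self):
        regs = [_reg(f"p{i}", "1999-01-01", sex=("male" if i % 2 else "female")) for i in range(40)]
        cases = [_case(f"p{i}", f"200{i % 3}-06-01") for i in range(12)]
        for table in (
            incidence(cases, regs, year_labels(2000, 2004), by_sex=True),
            prevalence(cases, regs, year_labels(2000, 2004), by_sex=True),
        ):
            assert (table["numerator"] <= table["denominator"]).all()


class TestStrata:
    def test_sex_strata_add_up_to_all(self):
        regs = [
            _reg(f"p{i}", "1999-01-01", sex=["male", "female", "unknown"][i % 3])
            for i in range(30)
        ]
        cases = [_case(f"p{i}", "2001-06-01") for i in range(7)]
        for table in (
            prevalence(cases, regs, year_labels(2000, 2002), by_sex=True),
            incidence(cases, regs, year_labels(2000, 2002), by_sex=True),
        ):
            for year, grp in table.groupby("year"):
                g = grp.set_index("stratum")
                for col in ("numerator", "denominator"):
                    assert (
                        g.loc["male", col] + g.loc["female", col] + g.loc["unknown", col]
                        == g.loc["all", col]
                    )


class TestCompareRates:
    def test_identical_tables_give_zero_differences(self):
        regs = [_reg("p1", "1999-01-01")]
        cases = [_case("p1", "2001-06-01")]
        table = prevalence(cases, regs, year_labels(2000, 2002))
        cmp_ = compare_rates(table, table)
        assert (cmp_.table["rate_diff"] == 0).all()

    def test_hand_built_three_year_difference(self):
        import pandas as pd

        grid = {"year": year_labels(2000, 2002), "stratum": ["all"] * 3}
        a = pd.DataFrame({**grid, "numerator": [2, 3, 4], "denominator": [10, 10, 10],
                          "rate": [0.2, 0.3, 0.4]})
        b = pd.DataFrame({**grid, "numerator": [1, 1, 4], "denominator": [10, 10, 10],
                          "rate": [0.1, 0.1, 0.4]})
        cmp_ = compare_rates(a, b)
        assert cmp_.table["rate_diff"].tolist() == pytest.approx([0.1, 0.2, 0.0])
        assert cmp_.max_diff_rows.iloc[0]["year"] == "2001/02"  # argmax year

    def test_mismatched_grids_rejected(self):
        regs = [_reg("p1", "1999-01-01")]
        a = prevalence([], regs, year_labels(2000, 2002))
        b = prevalence([], regs, year_labels(2000, 2001))
        with pytest.raises(GridMismatchError):
            compare_rates(a, b)


def test_registration_and_rate_io_round_trip(tmp_path):
    regs = [_reg("p1", "1999-01-01", "2005-12-31"), _reg("p2", "2000-02-02", sex="male")]
    path = tmp_path / "regs.csv"
    write_registrations(regs, path)
    assert read_registrations(path) == regs

    table = prevalence([_case("p1", "2001-06-01")], regs, year_labels(2000, 2001))
    out = tmp_path / "rates.csv"
    write_rates(table, out)
    text = out.read_text()
    assert "rate_percent" in text
    assert "50.0000" in text  # 1 of 2 registered patients prevalent in 2001/02
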