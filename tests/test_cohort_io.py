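"""Loader validation, CPI adjustment, linkage filters and exposure coding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import taxiv
from taxiv.exceptions import DataError


def _individual_rows(n=5, **overrides):
    base = {
        "state_code": ["S01", "S02", "S03", "S01", "S02"][:n],
        "year": [2003, 2004, 2003, 2004, 2003][:n],
        "edentulous": [0, 1, 0, 0, 0][:n],
        "drinks_per_day": [1.0, 2.5, 0.5, 3.0, 1.2][:n],
        "age": [45, 60, 35, 50, 70][:n],
        "sex": ["male", "female", "male", "female", "male"][:n],
        "race_ethnicity": ["White", "Black", "White", "Hispanic", "Other"][:n],
        "education": ["college_graduate", "some_college", "high_school_graduate",
                      "college_graduate", "elementary"][:n],
        "smoking": ["never", "current", "former", "never", "never"][:n],
    }
    base.update(overrides)
    return pd.DataFrame(base)


def _tax_rows():
    return pd.DataFrame({
        "state_code": ["S01", "S01", "S02", "S02", "S03", "S03"],
        "year": [2003, 2004] * 3,
        "beer_tax": [0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
        "wine_tax": [1.0, 1.1, 1.2, 1.3, 1.4, 1.5],
        "spirits_tax": [5.0, 5.5, 6.0, 6.5, 7.0, 7.5],
    })


class TestLoadIndividuals:
    def test_well_formed_fixture_loads_clean(self, tmp_path):
        path = tmp_path / "cohort.csv"
        _individual_rows().to_csv(path, index=False)
        df, report = taxiv.load_individuals(path)
        assert len(df) == 5 and report.n_dropped == 0
        assert report.n_input == report.n_retained + report.n_dropped

    def test_negative_exposure_rejected_with_reason(self, tmp_path):
        rows = _individual_rows()
        rows.loc[2, "drinks_per_day"] = -1.0
        path = tmp_path / "cohort.csv"
        rows.to_csv(path, index=False)
        df, report = taxiv.load_individuals(path)
        assert len(df) == 4
        assert report.drops == {"negative exposure": 1}

    def test_unknown_categorical_level_rejected(self, tmp_path):
        rows = _individual_rows()
        rows.loc[1, "smoking"] = "sometimes"
        path = tmp_path / "cohort.csv"
        rows.to_csv(path, index=False)
        df, report = taxiv.load_individuals(path)
        assert len(df) == 4 and report.drops == {"unknown smoking level": 1}

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        rows = _individual_rows().drop(columns=["smoking"])
        path = tmp_path / "cohort.csv"
        rows.to_csv(path, index=False)
        with pytest.raises(DataError, match="smoking"):
            taxiv.load_individuals(path)

    def test_column_map_renames_and_flags_unknown_sources(self, tmp_path):
        rows = _individual_rows().rename(columns={"drinks_per_day": "AVEDRNK"})
        path = tmp_path / "cohort.csv"
        rows.to_csv(path, index=False)
        df, _ = taxiv.load_individuals(path, column_map={"drinks_per_day": "AVEDRNK"})
        assert len(df) == 5
        with pytest.raises(DataError, match="NOPE"):
            taxiv.load_individuals(path, column_map={"drinks_per_day": "NOPE"})

    def test_year_restriction(self, tmp_path):
        rows = _individual_rows()
        rows.loc[0, "year"] = 1999
        path = tmp_path / "cohort.csv"
        rows.to_csv(path, index=False)
        df, report = taxiv.load_individuals(path, years=(2003, 2004))
        assert len(df) == 4 and "year outside study years" in report.drops


class TestLoadTaxes:
    def test_fixture_loads(self, tmp_path):
        path = tmp_path / "taxes.csv"
        _tax_rows().to_csv(path, index=False)
        df, report = taxiv.load_taxes(path)
        assert len(df) == 6 and report.n_dropped == 0

    def test_duplicate_state_year_is_hard_error(self, tmp_path):
        rows = pd.concat([_tax_rows(), _tax_rows().iloc[[0]]])
        path = tmp_path / "taxes.csv"
        rows.to_csv(path, index=False)
        with pytest.raises(DataError, match=r"S01"):
            taxiv.load_taxes(path)

    def test_negative_tax_rejected_with_reason(self, tmp_path):
        rows = _tax_rows()
        rows.loc[3, "wine_tax"] = -0.5
        path = tmp_path / "taxes.csv"
        rows.to_csv(path, index=False)
        df, report = taxiv.load_taxes(path)
        assert len(df) == 5 and report.drops == {"negative tax": 1}


class TestCpiAdjustment:
    def test_flat_cpi_is_identity(self):
        taxes = _tax_rows()
        out = taxiv.adjust_to_base_year(taxes, {2003: 100, 2004: 100, 2012: 100}, 2012)
        pd.testing.assert_frame_equal(out, taxes)

    def test_deflation_arithmetic(self):
        taxes = _tax_rows().iloc[[0]].assign(beer_tax=1.00)
        out = taxiv.adjust_to_base_year(taxes, {2003: 100, 2012: 110}, 2012)
        assert out["beer_tax"].iloc[0] == pytest.approx(1.10)

    def test_already_real_passthrough(self):
        taxes = _tax_rows()
        out = taxiv.adjust_to_base_year(taxes, {}, 2012, already_real=True)
        assert out is taxes

    def test_missing_cpi_year_is_error(self):
        with pytest.raises(DataError, match="2004"):
            taxiv.adjust_to_base_year(_tax_rows(), {2003: 100, 2012: 110}, 2012)


class TestLinkAndFilter:
    def test_age_filter_counts(self):
        rows = _individual_rows()
        rows.loc[0, "age"] = 29
        ds = taxiv.link_and_filter(rows, _tax_rows())
        assert ds.n == 4
        assert ds.meta["filter_report"]["drops"]["age below 30"] == 1

    def test_current_drinker_restriction(self):
        rows = _individual_rows()
        rows.loc[1, "drinks_per_day"] = 0.0
        ds = taxiv.link_and_filter(rows, _tax_rows())
        assert ds.n == 4
        assert ds.meta["filter_report"]["drops"][
            "not a current drinker (zero exposure)"] == 1

    def test_all_valid_keeps_n_and_three_instruments(self):
        ds = taxiv.link_and_filter(_individual_rows(), _tax_rows())
        assert ds.n == 5
        assert ds.Z.shape == (5, 3)
        assert ds.z_names == ["beer_tax", "wine_tax", "spirits_tax"]
        assert ds.c_names[0] == "const"

    def test_missing_state_year_is_hard_error(self):
        rows = _individual_rows()
        rows.loc[0, "state_code"] = "S99"
        with pytest.raises(DataError, match=r"S99"):
            taxiv.link_and_filter(rows, _tax_rows())

    def test_filter_counts_partition_input(self):
        rows = _individual_rows()
        rows.loc[0, "age"] = 12
        rows.loc[1, "drinks_per_day"] = 0.0
        ds = taxiv.link_and_filter(rows, _tax_rows())
        rep = ds.meta["filter_report"]
        assert rep["n_input"] == rep["n_retained"] + sum(rep["drops"].values())

    def test_round_trip_generator_to_loader(self, calib_truth, calib_study,
                                            calib_data, tmp_path):
        individuals, taxes = calib_study
        individuals.to_csv(tmp_path / "cohort.csv", index=False)
        taxes.to_csv(tmp_path / "taxes.csv", index=False)
        ind2, rep_i = taxiv.load_individuals(tmp_path / "cohort.csv")
        tax2, rep_t = taxiv.load_taxes(tmp_path / "taxes.csv")
        assert rep_i.n_dropped == 0 and rep_t.n_dropped == 0
        ds2 = taxiv.link_and_filter(ind2.loc[~ind2["negative_control"]], tax2)
        assert ds2.n == calib_data.n
        np.testing.assert_allclose(ds2.x, calib_data.x, rtol=0, atol=1e-12)
        np.testing.assert_allclose(ds2.Z, calib_data.Z, rtol=0, atol=1e-12)
        np.testing.assert_allclose(ds2.C, calib_data.C, rtol=0, atol=1e-12)

    def test_row_order_invariance(self, calib_study):
        individuals, taxes = calib_study
        adults = individuals.loc[~individuals["negative_control"]]
        shuffled = adults.sample(frac=1.0, random_state=1)
        ds_a = taxiv.link_and_filter(adults, taxes)
        ds_b = taxiv.link_and_filter(shuffled, taxes)
        fa, fb = taxiv.fit_first_stage(ds_a), taxiv.fit_first_stage(ds_b)
        assert fa.partial_f == pytest.approx(fb.partial_f, rel=1e-9)
        la, lb = taxiv.fit_2sls_lpm(ds_a), taxiv.fit_2sls_lpm(ds_b)
        assert la.coef == pytest.approx(lb.coef, rel=1e-9)


class TestCategoriseDrinks:
    @pytest.mark.parametrize("x,expected", [
        (0.1, ">0-2"), (2.0, ">0-2"), (2.0001, ">2-<5"),
        (4.999, ">2-<5"), (5.0, ">=5"), (12.0, ">=5"),
    ])
    def test_boundaries(self, x, expected):
        assert taxiv.categorise_drinks(x) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            taxiv.categorise_drinks(0.0)
        with pytest.raises(ValueError):
            taxiv.categorise_drinks([1.0, -2.0])

    @given(st.floats(min_value=1e-6, max_value=50, allow_nan=False))
    def test_assignment_consistent_with_interval_definition(self, x):
        cat = taxiv.categorise_drinks(x)
        if x <= 2:
            assert cat == ">0-2"
        elif x < 5:
            assert cat == ">2-<5"
        else:
            assert cat == ">=5"
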