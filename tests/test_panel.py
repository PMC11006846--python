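import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hemobayes as hb
from hemobayes.panel import REGISTRY, SUMMARY_COLUMNS, summary_table


class TestRegistry:
    def test_panel_has_sixteen_modelled_variables_plus_derived(self):
        assert len(hb.PANEL_VARIABLES) == 16
        assert len(REGISTRY) == 17
        assert REGISTRY["log10pCO2"].derived
        assert "log10pCO2" not in hb.PANEL_VARIABLES

    def test_hard_bounds_are_ordered(self):
        for spec in REGISTRY.values():
            if spec.hard_bounds is not None:
                lo, hi = spec.hard_bounds
                assert lo < hi


class TestReadWrite:
    def test_single_record_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [("1", "Bas", "pH", 7.54)], columns=["animal_id", "treatment", "variable", "value"]
        )
        p = tmp_path / "t.csv"
        df.to_csv(p, index=False)
        table = hb.read_study_table(p)
        assert len(table) == 1
        rec = table.records[0]
        assert (rec.animal_id, rec.treatment, rec.variable, rec.value) == ("1", "Bas", "pH", 7.54)

    def test_unknown_variable_rejected_by_name(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("animal_id,treatment,variable,value\n1,Bas,pHX,7.5\n")
        with pytest.raises(hb.ValidationError) as e:
            hb.read_study_table(p)
        assert any("pHX" in line for line in e.value.report)

    def test_unknown_treatment_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("animal_id,treatment,variable,value\n1,Post,pH,7.5\n")
        with pytest.raises(hb.ValidationError):
            hb.read_study_table(p)

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "animal_id,treatment,variable,value\n1,Bas,pH,7.5\n1,Bas,pH,7.6\n"
        )
        with pytest.raises(hb.ValidationError) as e:
            hb.read_study_table(p)
        assert any("duplicate" in line for line in e.value.report)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("animal_id,treatment,value\n1,Bas,7.5\n")
        with pytest.raises(hb.ValidationError):
            hb.read_study_table(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("animal_id,treatment,variable,value\n")
        with pytest.raises(hb.ValidationError):
            hb.read_study_table(p)

    def test_generated_cohort_round_trips_bit_for_value(self, tmp_path):
        table = hb.generate_cohort(hb.default_study_config(seed=4))
        p = tmp_path / "cohort.csv"
        hb.write_study_table(table, p)
        back = hb.read_study_table(p)
        assert len(back) == len(table)
        pd.testing.assert_frame_equal(back.df, table.df)


class TestDeriveLog10:
    def test_powers_of_ten(self, rng):
        df = pd.DataFrame(
            [("1", "Bas", "pCO2", 100.0), ("2", "Bas", "pCO2", 1.0)],
            columns=["animal_id", "treatment", "variable", "value"],
        )
        out = hb.derive_log10_pco2(hb.make_study_table(df))
        vals = dict(zip(out.df[out.df.variable == "log10pCO2"].animal_id,
                        out.df[out.df.variable == "log10pCO2"].value))
        assert vals["1"] == pytest.approx(2.0)
        assert vals["2"] == pytest.approx(0.0)
        # originals untouched
        assert (out.df.variable == "pCO2").sum() == 2

    def test_arbitrary_value_matches_log10(self):
        df = pd.DataFrame(
            [("1", "Bas", "pCO2", 23.40)], columns=["animal_id", "treatment", "variable", "value"]
        )
        out = hb.derive_log10_pco2(hb.make_study_table(df))
        v = out.df.loc[out.df.variable == "log10pCO2", "value"].iloc[0]
        assert v == pytest.approx(math.log10(23.40), abs=1e-12)

    def test_nonpositive_pco2_is_domain_error(self):
        df = pd.DataFrame(
            [("1", "Bas", "pCO2", 0.5), ("2", "Bas", "pCO2", -1.0)],
            columns=["animal_id", "treatment", "variable", "value"],
        )
        # -1.0 violates the hard bound already at validation
        with pytest.raises(hb.HemobayesError):
            hb.derive_log10_pco2(hb.make_study_table(df))


class TestPairing:
    def test_incomplete_pair_dropped(self, tiny_table):
        pairs = hb.pair_records(tiny_table, "pH")
        assert len(pairs) == 5  # animal 5 has no CO2 value
        assert "5" not in set(pairs.animal_id)
        row = pairs[pairs.animal_id == "1"].iloc[0]
        assert (row.before, row.after) == (7.50, 7.10)

    def test_no_treated_records_gives_empty(self):
        df = pd.DataFrame(
            [("1", "Bas", "pH", 7.5), ("2", "Bas", "pH", 7.4)],
            columns=["animal_id", "treatment", "variable", "value"],
        )
        pairs = hb.pair_records(hb.make_study_table(df), "pH")
        assert len(pairs) == 0

    def test_pair_count_bounded_by_smaller_stratum(self):
        table = hb.generate_cohort(hb.default_study_config(seed=9))
        for v in hb.PANEL_VARIABLES:
            n_bas = len(table.values(v, "Bas"))
            n_co2 = len(table.values(v, "CO2"))
            assert len(hb.pair_records(table, v)) <= min(n_bas, n_co2)

    def test_numeric_ids_sorted_numerically(self):
        df = pd.DataFrame(
            [("10", "Bas", "pH", 7.5), ("10", "CO2", "pH", 7.0),
             ("2", "Bas", "pH", 7.4), ("2", "CO2", "pH", 7.1)],
            columns=["animal_id", "treatment", "variable", "value"],
        )
        pairs = hb.pair_records(hb.make_study_table(df), "pH")
        assert list(pairs.animal_id) == ["2", "10"]


class TestSummarize:
    def test_symmetric_triple(self):
        s = hb.summarize([1, 2, 3])
        assert (s.min, s.q50, s.mean, s.max, s.n_obs) == (1, 2, 2, 3, 3)
        assert s.sd == pytest.approx(1.0)

    def test_constant_input(self):
        s = hb.summarize([5, 5, 5, 5])
        assert s.sd == 0
        assert s.min == s.q25 == s.q50 == s.q75 == s.max == 5

    def test_normal_quartile_recovery(self, rng):
        x = rng.standard_normal(10_000)
        s = hb.summarize(x)
        assert s.q25 == pytest.approx(-0.674, abs=0.05)

    def test_insufficient_data(self):
        with pytest.raises(hb.InsufficientDataError):
            hb.summarize([1.0])

    @given(
        st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40),
        st.floats(-100, 100),
        st.floats(0.01, 50),
    )
    def test_affine_equivariance_and_permutation_invariance(self, xs, b, a):
        x = np.asarray(xs)
        s = hb.summarize(x)
        perm = hb.summarize(np.random.default_rng(0).permutation(x))
        for attr in ("min", "q25", "q50", "q75", "max", "mean", "sd"):
            assert getattr(perm, attr) == pytest.approx(getattr(s, attr), rel=1e-9, abs=1e-9)
        t = hb.summarize(a * x + b)
        for attr in ("min", "q25", "q50", "q75", "max", "mean"):
            assert getattr(t, attr) == pytest.approx(a * getattr(s, attr) + b, rel=1e-9, abs=1e-6)
        assert t.sd == pytest.approx(abs(a) * s.sd, rel=1e-9, abs=1e-6)

    def test_summary_table_columns_follow_report_order(self):
        table = hb.generate_cohort(hb.default_study_config(seed=1))
        out = summary_table(table)
        assert list(out.columns) == list(SUMMARY_COLUMNS)
        ph = out[(out.variable == "pH") & (out.treatment == "Bas")].iloc[0]
        assert ph["Min"] <= ph["Q.25"] <= ph["Q.50"] <= ph["Q.75"] <= ph["Max"]
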