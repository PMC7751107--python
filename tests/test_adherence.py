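"""PDC engine: stockpiling, carryover, hospital pause, and its day-grid twin."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import adhercost as ac
from adhercost.adherence import build_coverage, build_patient_axis, compute_pdc_panel, pdc_day_grid
from adhercost.cohort import build_observation_periods
from adhercost.drugs import DddTable

from conftest import random_claim_scenario

IDX = pd.Timestamp("2010-01-01")


def make_case(disp_rows, stay_rows=(), death=None):
    cohort = pd.DataFrame({"patient_id": ["X"], "index_date": [IDX],
                           "death_date": [death]})
    stays = pd.DataFrame(list(stay_rows), columns=["patient_id", "admit_date",
                                                   "discharge_date", "icd_code"])
    disp = pd.DataFrame(list(disp_rows), columns=["patient_id", "atc_code",
                                                  "dispense_date", "amount_mg"])
    periods = build_observation_periods(cohort, stays)
    return disp, periods, stays


def day(n):
    return IDX + pd.Timedelta(days=n)


class TestCoverageSemantics:
    def test_supply_crossing_year_boundary_becomes_stock(self):
        # 40 days of ramipril dispensed 10 days before the year-1/2 boundary
        disp, periods, stays = make_case(
            [("X", "C09AA05", day(355), 400.0)])
        panel = compute_pdc_panel(disp, periods, stays).set_index(
            ["drug_class", "period_index"])
        assert panel.loc[("ACE", 1), "covered_days"] == 10
        assert panel.loc[("ACE", 2), "covered_days"] == 30
        assert panel.loc[("ACE", 2), "stock_in_days"] == pytest.approx(30.0)
        assert panel.loc[("ACE", 1), "stock_out_days"] == pytest.approx(30.0)

    def test_same_day_dispensations_stockpile_consecutively(self):
        disp, periods, stays = make_case(
            [("X", "C09AA05", day(0), 300.0), ("X", "C09AA05", day(0), 300.0)])
        panel = compute_pdc_panel(disp, periods, stays).set_index(
            ["drug_class", "period_index"])
        assert panel.loc[("ACE", 1), "covered_days"] == 60

    def test_supply_pauses_during_hospital_stay(self):
        # 30 days' supply the day before a 10-day stay: consumption resumes
        # after discharge, total non-hospital covered days stays 30
        disp, periods, stays = make_case(
            [("X", "C09AA05", day(9), 300.0)],
            [("X", day(10), day(20), "I50")])
        panel = compute_pdc_panel(disp, periods, stays).set_index(
            ["drug_class", "period_index"])
        assert panel.loc[("ACE", 1), "covered_days"] == 30
        assert panel.loc[("ACE", 1), "denominator_days"] == 355
        grid = pdc_day_grid(disp, periods, stays).set_index(
            ["drug_class", "period_index"])
        assert grid.loc[("ACE", 1), "covered_days"] == 30

    def test_supply_runs_in_hospital_alternative(self):
        disp, periods, stays = make_case(
            [("X", "C09AA05", day(9), 300.0)],
            [("X", day(10), day(20), "I50")])
        panel = compute_pdc_panel(disp, periods, stays,
                                  supply_runs_in_hospital=True).set_index(
            ["drug_class", "period_index"])
        assert panel.loc[("ACE", 1), "covered_days"] == 30
        assert panel.loc[("ACE", 1), "denominator_days"] == 365

    def test_no_dispensations_gives_zero_pdc_everywhere(self):
        disp, periods, stays = make_case([])
        panel = compute_pdc_panel(disp, periods, stays)
        assert (panel["pdc"] == 0).all()
        assert (panel["covered_days"] == 0).all()

    def test_full_year_supply_gives_pdc_one(self):
        disp, periods, stays = make_case([("X", "C09AA05", day(0), 3650.0)])
        panel = compute_pdc_panel(disp, periods, stays).set_index(
            ["drug_class", "period_index"])
        assert panel.loc[("ACE", 1), "pdc"] == pytest.approx(1.0)

    def test_hospital_corrected_denominator_arithmetic(self):
        # 200 covered days, 365 survived, 30 hospital -> 200/335
        disp, periods, stays = make_case(
            [("X", "C09AA05", day(40), 2000.0)],
            [("X", day(0), day(30), "I21.0")])
        panel = compute_pdc_panel(disp, periods, stays).set_index(
            ["drug_class", "period_index"])
        assert panel.loc[("ACE", 1), "denominator_days"] == 335
        assert panel.loc[("ACE", 1), "pdc"] == pytest.approx(200 / 335)

    def test_dispensation_after_death_dropped_with_warning(self, caplog):
        disp, periods, stays = make_case(
            [("X", "C09AA05", day(200), 300.0)],
            death=IDX + pd.Timedelta(days=100))
        with caplog.at_level(logging.WARNING, logger="adhercost.adherence"):
            panel = compute_pdc_panel(disp, periods, stays)
        assert "after death" in caplog.text
        assert (panel["covered_days"] == 0).all()

    def test_pre_year_stock_carries_into_first_followup_year(self):
        disp, periods, stays = make_case([("X", "C09AA05", day(-20), 500.0)])
        panel = compute_pdc_panel(disp, periods, stays).set_index(
            ["drug_class", "period_index"])
        assert panel.loc[("ACE", -1), "covered_days"] == 20
        assert panel.loc[("ACE", 1), "covered_days"] == 30
        assert panel.loc[("ACE", 1), "stock_in_days"] == pytest.approx(30.0)

    def test_zero_denominator_flags_undefined_pdc(self):
        disp, periods, stays = make_case(
            [("X", "C09AA05", day(0), 300.0)],
            [("X", day(365), day(750), "I50")])
        panel = compute_pdc_panel(disp, periods, stays).set_index(
            ["drug_class", "period_index"])
        assert panel.loc[("ACE", 2), "denominator_days"] == 0
        assert np.isnan(panel.loc[("ACE", 2), "pdc"])


class TestClassRules:
    def make_panel(self):
        return pd.DataFrame({
            "patient_id": ["X"] * 6,
            "drug_class": ["BB"] * 3 + ["ACE"] * 3,
            "period_index": [1, 2, 3] * 2,
            "pdc": [0.5, 0.2, 0.1, 0.9, 0.8, 0.7],
        })

    def test_bb_first_year_rule_replaces_later_years(self):
        out = ac.apply_class_rules(self.make_panel(), bb_first_year_only=True)
        bb = out[out["drug_class"] == "BB"].sort_values("period_index")
        assert list(bb["pdc"]) == [0.5, 0.5, 0.5]
        ace = out[out["drug_class"] == "ACE"].sort_values("period_index")
        assert list(ace["pdc"]) == [0.9, 0.8, 0.7]

    def test_rule_disabled_is_identity(self):
        panel = self.make_panel()
        out = ac.apply_class_rules(panel, bb_first_year_only=False)
        pd.testing.assert_frame_equal(out, panel)


class TestOracleEquivalence:
    def test_engine_matches_day_grid_on_random_scenarios(self):
        rng = np.random.default_rng(123)
        for _ in range(150):
            disp, periods, stays = random_claim_scenario(rng)
            a = compute_pdc_panel(disp, periods, stays)
            b = pdc_day_grid(disp, periods, stays)
            m = a.merge(b, on=["patient_id", "drug_class", "period_index"],
                        suffixes=("_e", "_g"))
            assert (m["covered_days_e"] == m["covered_days_g"]).all()
            assert (m["denominator_days_e"] == m["denominator_days_g"]).all()

    def test_conservation_of_supplied_days(self):
        # sum of covered + discarded supply == sum of days supplied (+-0.5/chain)
        rng = np.random.default_rng(321)
        table = DddTable.default()
        for _ in range(100):
            disp, periods, stays = random_claim_scenario(rng)
            if len(disp) == 0:
                continue
            from adhercost.cohort import _merged_stay_intervals
            from adhercost.drugs import classify_atc
            axis = build_patient_axis(periods,
                                      _merged_stay_intervals(stays).get("X", []))
            disp = disp.assign(cls=[classify_atc(c) for c in disp["atc_code"]])
            for cls, grp in disp.groupby("cls"):
                ledger = build_coverage(grp, axis, table)
                supplied = sum(table.days_supplied(a, c)
                               for a, c in zip(grp["amount_mg"], grp["atc_code"]))
                covered = sum(c for _, _, c in ledger.chains)
                n_chains = max(len(ledger.chains), 1)
                assert abs(covered + ledger.discarded - supplied) <= 0.5 * n_chains + 1e-9

    def test_adding_a_dispensation_never_decreases_coverage(self):
        rng = np.random.default_rng(555)
        for _ in range(60):
            disp, periods, stays = random_claim_scenario(rng)
            extra = pd.DataFrame({
                "patient_id": ["X"], "atc_code": ["C09AA05"],
                "dispense_date": [IDX + pd.Timedelta(days=int(rng.integers(-300, 1000)))],
                "amount_mg": [float(rng.integers(100, 1000))]})
            base = compute_pdc_panel(disp, periods, stays)
            more = compute_pdc_panel(pd.concat([disp, extra], ignore_index=True),
                                     periods, stays)
            m = base.merge(more, on=["patient_id", "drug_class", "period_index"],
                           suffixes=("_b", "_m"))
            assert (m["covered_days_m"] >= m["covered_days_b"]).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.integers(min_value=-2000, max_value=2000),
           seed=st.integers(min_value=0, max_value=50))
    def test_translation_invariance(self, shift, seed):
        disp, periods, stays = random_claim_scenario(np.random.default_rng(seed))
        d = pd.Timedelta(days=shift)
        disp2, stays2 = disp.copy(), stays.copy()
        if len(disp2):
            disp2["dispense_date"] = pd.to_datetime(disp2["dispense_date"]) + d
        if len(stays2):
            stays2["admit_date"] = pd.to_datetime(stays2["admit_date"]) + d
            stays2["discharge_date"] = pd.to_datetime(stays2["discharge_date"]) + d
        periods2 = periods.assign(start=periods["start"] + d,
                                  end=periods["end"] + d)
        a = compute_pdc_panel(disp, periods, stays)
        b = compute_pdc_panel(disp2, periods2, stays2)
        pd.testing.assert_frame_equal(a, b)
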