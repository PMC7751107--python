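"""Index-event selection, inclusion cascade, observation periods, sensitivity filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from adhercost.cohort import (CohortInputError, apply_inclusion_cascade,
                              build_observation_periods, normalize_spells,
                              select_index_event, sensitivity_filter)
from adhercost.io import spells_from_patients
from adhercost.simulate import SimConfig, simulate_dataset
import adhercost as ac


def stays_frame(rows):
    return pd.DataFrame(rows, columns=["patient_id", "admit_date",
                                       "discharge_date", "icd_code"])


class TestIndexEvent:
    def test_earliest_qualifying_admission_wins(self):
        stays = stays_frame([
            ("A", "2010-02-01", "2010-02-10", "I21.0"),
            ("A", "2009-05-01", "2009-05-08", "I21.4"),
        ])
        idx = select_index_event(stays)
        assert list(idx["patient_id"]) == ["A"]
        assert idx.loc[0, "index_date"] == pd.Timestamp("2009-05-01")

    def test_non_infarction_codes_do_not_qualify(self):
        stays = stays_frame([("A", "2010-02-01", "2010-02-10", "I20.0")])
        assert len(select_index_event(stays)) == 0

    def test_admission_outside_window_excluded(self):
        stays = stays_frame([("A", "2012-03-01", "2012-03-09", "I21.0")])
        assert len(select_index_event(stays)) == 0

    def test_malformed_dates_raise_with_context(self):
        stays = stays_frame([("A", "not-a-date", "2010-02-10", "I21.0")])
        with pytest.raises(CohortInputError, match="admit_date"):
            select_index_event(stays)


class TestObservationPeriods:
    def test_survivor_three_full_years(self):
        cohort = pd.DataFrame({"patient_id": ["A"],
                               "index_date": [pd.Timestamp("2010-01-01")],
                               "death_date": [pd.NaT]})
        per = build_observation_periods(cohort, stays_frame([]))
        fu = per[per["period_index"] > 0]
        assert list(fu["period_index"]) == [1, 2, 3]
        assert (fu["days_survived"] == 365).all()
        assert (fu["hospital_days"] == 0).all()
        pre = per[per["period_index"] == -1].iloc[0]
        assert pre["end"] == pd.Timestamp("2010-01-01")

    def test_death_mid_followup_truncates_and_omits_later_years(self):
        idx = pd.Timestamp("2010-01-01")
        cohort = pd.DataFrame({"patient_id": ["A"], "index_date": [idx],
                               "death_date": [idx + pd.Timedelta(days=400)]})
        per = build_observation_periods(cohort, stays_frame([])).set_index("period_index")
        assert per.loc[1, "days_survived"] == 365
        # death on day 400 -> 35 survived days into year 2 (death day exclusive)
        assert per.loc[2, "days_survived"] == 35
        assert 3 not in per.index

    def test_stay_straddling_year_boundary_splits_hospital_days(self):
        idx = pd.Timestamp("2010-01-01")
        boundary = idx + pd.Timedelta(days=365)
        stays = stays_frame([
            ("A", boundary - pd.Timedelta(days=6), boundary + pd.Timedelta(days=4), "I50"),
        ])
        cohort = pd.DataFrame({"patient_id": ["A"], "index_date": [idx],
                               "death_date": [pd.NaT]})
        per = build_observation_periods(cohort, stays).set_index("period_index")
        assert per.loc[1, "hospital_days"] == 6
        assert per.loc[2, "hospital_days"] == 4

    def test_overlapping_stays_count_each_day_once(self):
        idx = pd.Timestamp("2010-01-01")
        stays = stays_frame([
            ("A", idx + pd.Timedelta(days=10), idx + pd.Timedelta(days=20), "I50"),
            ("A", idx + pd.Timedelta(days=15), idx + pd.Timedelta(days=25), "I50"),
        ])
        cohort = pd.DataFrame({"patient_id": ["A"], "index_date": [idx],
                               "death_date": [pd.NaT]})
        per = build_observation_periods(cohort, stays).set_index("period_index")
        assert per.loc[1, "hospital_days"] == 15


def _crafted_universe():
    """Ten patients: one per exclusion reason, three fully eligible."""
    idx = pd.Timestamp("2010-06-01")
    patients, stays, docs, spell_rows, cov = [], [], [], [], []

    def add(pid, *, icd="I21.0", admit=idx, death=None, enroll_lag=400,
            doc_lag=60, ins=( -400, 1200), missing_cov=False):
        patients.append({"patient_id": pid, "sex": "male",
                         "birth_date": admit - pd.Timedelta(days=365 * 70),
                         "death_date": death,
                         "dmp_cad_enrollment": admit - pd.Timedelta(days=enroll_lag),
                         "bimd_quintile": 2})
        stays.append((pid, admit, admit + pd.Timedelta(days=7), icd))
        if doc_lag is not None:
            docs.append({"patient_id": pid,
                         "doc_date": admit - pd.Timedelta(days=doc_lag)})
        spell_rows.append({"patient_id": pid,
                           "start": admit + pd.Timedelta(days=ins[0]),
                           "end": admit + pd.Timedelta(days=ins[1])})
        for year in (1, 2, 3):
            cov.append({"patient_id": pid, "year": year,
                        "bmi_group": np.nan if missing_cov else "normal",
                        "smoker": 0, "nyha": 0, "dmp_copd": 0, "dmp_asthma": 0,
                        "dmp_diabetes1": 0, "dmp_diabetes2": 0,
                        "hmg_per_month": 100.0, "angina_pectoris": 0,
                        "peripheral_vascular_disease": 0, "dyslipidemia": 0,
                        "congestive_heart_failure": 0, "hypertension": 0,
                        "dialysis": 0})

    add("ok1"); add("ok2"); add("ok3")
    add("no_ami", icd="I20.0")                                  # never an I21
    add("late_ami", admit=pd.Timestamp("2012-05-01"))           # outside window
    add("enrolled_after", enroll_lag=-10)                       # DMP after index
    add("stale_doc", doc_lag=200)                               # last doc 200 d before
    add("gap", ins=(-400, 500))                                 # insurance ends early
    add("early_death", death=idx + pd.Timedelta(days=20))       # died at day 20
    add("missing_cov", missing_cov=True)                        # BMI missing
    return (pd.DataFrame(patients), stays_frame(stays), pd.DataFrame(docs),
            pd.DataFrame(spell_rows), pd.DataFrame(cov))


class TestInclusionCascade:
    def test_each_exclusion_reason_hits_exactly_once(self):
        patients, stays, docs, spells, cov = _crafted_universe()
        idx = select_index_event(stays)
        res = apply_inclusion_cascade(patients, idx, docs, spells, cov)
        excluded = dict(zip(res.exclusions["patient_id"], res.exclusions["excluded_at"]))
        assert excluded == {
            "no_ami": "index_event", "late_ami": "index_event",
            "enrolled_after": "dmp_enrolled", "stale_doc": "dmp_documented",
            "gap": "insured", "early_death": "survived_30d",
            "missing_cov": "covariates_complete",
        }
        assert sorted(res.cohort["patient_id"]) == ["ok1", "ok2", "ok3"]
        assert res.attrition["n_after"].iloc[-1] == 3

    def test_attrition_counts_are_monotone_and_consistent(self):
        patients, stays, docs, spells, cov = _crafted_universe()
        res = apply_inclusion_cascade(patients, select_index_event(stays), docs,
                                      spells, cov)
        att = res.attrition
        assert (att["n_after"] <= att["n_before"]).all()
        assert (att["n_before"] - att["n_excluded"] == att["n_after"]).all()
        assert (att["n_before"].iloc[1:].to_numpy()
                == att["n_after"].iloc[:-1].to_numpy()).all()

    def test_filter_order_permutation_leaves_cohort_unchanged(self):
        patients, stays, docs, spells, cov = _crafted_universe()
        idx = select_index_event(stays)
        base = apply_inclusion_cascade(patients, idx, docs, spells, cov)
        names = [s for s, _ in ac.cohort.CASCADE_STEPS]
        for order in itertools.islice(itertools.permutations(names), 0, 24, 5):
            res = apply_inclusion_cascade(patients, idx, docs, spells, cov,
                                          step_order=tuple(order))
            assert set(res.cohort["patient_id"]) == set(base.cohort["patient_id"])

    def test_death_boundary_day_30_excluded_day_31_kept(self):
        patients, stays, docs, spells, cov = _crafted_universe()
        idx0 = pd.Timestamp("2010-06-01")
        patients.loc[patients["patient_id"] == "ok1", "death_date"] = \
            idx0 + pd.Timedelta(days=30)
        patients.loc[patients["patient_id"] == "ok2", "death_date"] = \
            idx0 + pd.Timedelta(days=31)
        res = apply_inclusion_cascade(patients, select_index_event(stays), docs,
                                      spells, cov)
        ids = set(res.cohort["patient_id"])
        assert "ok1" not in ids and "ok2" in ids

    def test_doc_exactly_180_days_before_index_counts(self):
        patients, stays, docs, spells, cov = _crafted_universe()
        docs.loc[docs["patient_id"] == "ok1", "doc_date"] = \
            pd.Timestamp("2010-06-01") - pd.Timedelta(days=180)
        res = apply_inclusion_cascade(patients, select_index_event(stays), docs,
                                      spells, cov)
        assert "ok1" in set(res.cohort["patient_id"])


class TestSpells:
    def test_abutting_spells_merge_but_gaps_do_not(self):
        spells = pd.DataFrame({
            "patient_id": ["A", "A", "B", "B"],
            "start": ["2009-01-01", "2009-06-01", "2009-01-01", "2009-06-03"],
            "end": ["2009-06-01", "2010-01-01", "2009-06-01", "2010-01-01"],
        })
        merged = normalize_spells(spells)
        assert len(merged[merged["patient_id"] == "A"]) == 1
        assert len(merged[merged["patient_id"] == "B"]) == 2


class TestSensitivityFilters:
    @pytest.fixture(scope="class")
    def generated(self):
        data = simulate_dataset(SimConfig(n_patients=80, seed=9, hosp_rate=1.5))
        periods = build_observation_periods(data.patients, data.hospital_stays)
        return data.patients, periods

    def test_hospital_share_drops_majority_hospitalized(self):
        idx = pd.Timestamp("2010-01-01")
        cohort = pd.DataFrame({"patient_id": ["A"], "index_date": [idx],
                               "death_date": [idx + pd.Timedelta(days=729)]})
        stays = stays_frame([("A", idx, idx + pd.Timedelta(days=400), "I21.0")])
        periods = build_observation_periods(cohort, stays)
        kept = sensitivity_filter(cohort, periods, "hospital_share")
        assert len(kept) == 0
        kept_all = sensitivity_filter(cohort, periods, "hospital_share", threshold=1.0)
        assert len(kept_all) == 1

    def test_survivors_only_drops_exactly_the_deceased(self, generated):
        cohort, periods = generated
        kept = sensitivity_filter(cohort, periods, "survivors_only")
        assert set(kept["patient_id"]) == set(
            cohort.loc[cohort["death_date"].isna(), "patient_id"])

    def test_survivors_only_is_identity_without_deaths(self):
        data = simulate_dataset(SimConfig(n_patients=30, seed=2, death_hazard=0.0))
        periods = build_observation_periods(data.patients, data.hospital_stays)
        kept = sensitivity_filter(data.patients, periods, "survivors_only")
        assert len(kept) == 30

    def test_unknown_mode_raises(self, generated):
        cohort, periods = generated
        with pytest.raises(CohortInputError, match="unknown sensitivity mode"):
            sensitivity_filter(cohort, periods, "bogus")
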