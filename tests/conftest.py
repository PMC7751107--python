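"""Shared fixtures: synthetic pipelines and randomized claim scenarios."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import adhercost as ac
from adhercost.cohort import build_observation_periods
from adhercost.costs import aggregate_costs
from adhercost.frames import build_model_frame, make_cost_gamm
from adhercost.io import spells_from_patients
from adhercost.simulate import CostTruth, SimConfig, simulate_dataset


def run_claims_pipeline(config: SimConfig) -> dict:
    """Full claims -> model-frame pipeline on a synthetic dataset."""
    data = simulate_dataset(config)
    index_events = ac.select_index_event(data.hospital_stays)
    cascade = ac.apply_inclusion_cascade(
        data.patients, index_events, data.dmp_docs,
        spells_from_patients(data.patients), data.covariates)
    periods = build_observation_periods(cascade.cohort, data.hospital_stays)
    panel = ac.compute_pdc_panel(data.dispensations, periods, data.hospital_stays)
    cost_panel = aggregate_costs(data.cost_items, periods)
    frame = build_model_frame(cost_panel, panel, cascade.cohort,
                              data.covariates, periods)
    return {"data": data, "cascade": cascade, "periods": periods,
            "pdc_panel": panel, "cost_panel": cost_panel, "frame": frame}


def fit_study_model(frame, **kw):
    model = make_cost_gamm(**kw)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(frame, frame["response"])
    return model


def random_claim_scenario(rng: np.random.Generator):
    """One random small claim set: a patient, stays, and dispensations."""
    idx = pd.Timestamp("2010-01-01") + pd.Timedelta(days=int(rng.integers(0, 300)))
    death = None
    if rng.random() < 0.3:
        death = idx + pd.Timedelta(days=int(rng.integers(31, 1095)))
    cohort = pd.DataFrame({"patient_id": ["X"], "index_date": [idx],
                           "death_date": [death]})
    stay_rows = []
    for _ in range(int(rng.integers(0, 4))):
        admit = idx + pd.Timedelta(days=int(rng.integers(-300, 1000)))
        stay_rows.append({"patient_id": "X", "admit_date": admit,
                          "discharge_date": admit + pd.Timedelta(days=int(rng.integers(1, 30))),
                          "icd_code": "I50"})
    stays = pd.DataFrame(stay_rows, columns=["patient_id", "admit_date",
                                             "discharge_date", "icd_code"])
    nd = int(rng.integers(0, 11))
    disp = pd.DataFrame({
        "patient_id": ["X"] * nd,
        "atc_code": rng.choice(["C09AA05", "C07AB07", "C10AA01", "B01AC06"], nd),
        "dispense_date": [idx + pd.Timedelta(days=int(rng.integers(-400, 1100)))
                          for _ in range(nd)],
        "amount_mg": np.round(rng.uniform(0.5, 2000.0, nd), 3),
    }, columns=["patient_id", "atc_code", "dispense_date", "amount_mg"])
    periods = build_observation_periods(cohort, stays)
    return disp, periods, stays


@pytest.fixture(scope="session")
def small_pipeline():
    return run_claims_pipeline(SimConfig(n_patients=60, seed=7))


@pytest.fixture(scope="session")
def recovery_setup():
    """Study conditions for the parameter-recovery experiment (fixed seed)."""
    truth = CostTruth.nonlinear(floor_at_zero=False)
    cfg = SimConfig(n_patients=1000, seed=0, cost_model=truth)
    out = run_claims_pipeline(cfg)
    out["truth"] = truth
    out["model"] = fit_study_model(out["frame"])
    return out


@pytest.fixture(scope="session")
def null_setup():
    """Null smooth truth (all f == 0) for calibration checks (fixed seed)."""
    truth = CostTruth.null(floor_at_zero=False)
    cfg = SimConfig(n_patients=1000, seed=0, cost_model=truth)
    out = run_claims_pipeline(cfg)
    out["truth"] = truth
    out["model"] = fit_study_model(out["frame"])
    return out
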