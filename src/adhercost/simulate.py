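"""Synthetic claims generator with known ground truth.

Emulates the input data of a post-AMI adherence/cost analysis: one index
infarction hospitalization per patient, per-class adherence propensities with
yearly deviations, dispensation streams that realize the target PDCs when run
through the adherence engine, hospital stays, death times, and yearly costs
generated as covariate effects + smooth functions of the PDC mean/deviation +
a patient random intercept + Gaussian noise.

Every random draw flows from a single seeded generator, so a configuration
(including its seed) maps to byte-identical output tables.

The cost-generating truth evaluates its smooth functions at the *realized*
adherence quantities — the clipped yearly PDC targets, their mean over the
patient's observed years and the deviations from that mean — i.e. exactly
the quantities the downstream decomposition reconstructs, which makes the
generator the generative twin of the fitted model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .adherence import build_patient_axis
from .cohort import YEAR_DAYS, _merged_stay_intervals, build_observation_periods
from .costs import COST_CATEGORIES
from .drugs import DRUG_CLASSES, DddTable


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


# --------------------------------------------------------------------- truth
def _quadratic(amplitude: float):
    return lambda x: amplitude * ((np.asarray(x, dtype=float) - 50.0) / 50.0) ** 2


def _sine(amplitude: float, half_period: float = 60.0):
    return lambda d: amplitude * np.sin(np.pi * np.asarray(d, dtype=float) / half_period)


def _zero(x):
    return np.zeros_like(np.asarray(x, dtype=float))


#: default smooth-truth amplitudes (euros) per (class, sex)
BETWEEN_AMPLITUDES = {
    ("ACE", "male"): 2000.0, ("ACE", "female"): 2500.0,
    ("BB", "male"): 1800.0, ("BB", "female"): 2200.0,
    ("STATIN", "male"): 2400.0, ("STATIN", "female"): 2000.0,
    ("APA", "male"): 3500.0, ("APA", "female"): 2800.0,
}
WITHIN_AMPLITUDES = {
    ("ACE", "male"): 2200.0, ("ACE", "female"): 2800.0,
    ("BB", "male"): 3000.0, ("BB", "female"): 2400.0,
    ("STATIN", "male"): 2000.0, ("STATIN", "female"): 2600.0,
    ("APA", "male"): 3200.0, ("APA", "female"): 2500.0,
}

DEFAULT_COVARIATE_EFFECTS = {
    "age_group[>=75]": -1500.0,
    "sex[female]": -150.0,
    "bimd_quintile[3]": -900.0,
    "bimd_quintile[5]": -800.0,
    "smoker": 150.0,
    "nyha[2]": 1500.0,
    "nyha[3]": 2900.0,
    "nyha[4]": 4500.0,
    "dmp_copd": 1200.0,
    "deceased": 11000.0,
    "hmg_per_month": 1.1,
    "days_survived_c": 30.0,
    "angina_pectoris": 2100.0,
    "peripheral_vascular_disease": 4400.0,
    "dyslipidemia": 500.0,
    "congestive_heart_failure": 2100.0,
    "hypertension": 1900.0,
    "dialysis": 23500.0,
}


@dataclass
class CostTruth:
    """Generative model of yearly total cost (euros, reference-year scale)."""

    baseline: float = 12000.0
    year_effect: float = -3000.0              # per follow-up year beyond the first
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    f_between: dict = field(default_factory=dict)   # (class, sex) -> f(percent)
    f_within: dict = field(default_factory=dict)    # (class, sex) -> f(pp deviation)
    sigma_patient: float = 2000.0
    sigma_resid: float = 3000.0
    floor_at_zero: bool = True
    category_shares: tuple = (0.2, 0.2, 0.4, 0.1, 0.1)
    smooth_params: dict = field(default_factory=dict)   # serializable description

    def __post_init__(self):
        if self.sigma_patient < 0 or self.sigma_resid < 0:
            raise SimConfigError("sigma_patient and sigma_resid must be >= 0")
        if abs(sum(self.category_shares) - 1.0) > 1e-9:
            raise SimConfigError("category_shares must sum to 1")

    @classmethod
    def nonlinear(cls, **kw) -> "CostTruth":
        """Default truth: quadratic between-smooths, sinusoidal within-smooths."""
        fb = {k: _quadratic(a) for k, a in BETWEEN_AMPLITUDES.items()}
        fw = {k: _sine(a) for k, a in WITHIN_AMPLITUDES.items()}
        params = {"between": {f"{c}:{s}": a for (c, s), a in BETWEEN_AMPLITUDES.items()},
                  "within": {f"{c}:{s}": a for (c, s), a in WITHIN_AMPLITUDES.items()},
                  "shape": "quadratic/sine"}
        return cls(f_between=fb, f_within=fw, smooth_params=params, **kw)

    @classmethod
    def null(cls, **kw) -> "CostTruth":
        """All smooth truths identically zero (calibration scenario)."""
        keys = [(c, s) for c in DRUG_CLASSES for s in ("male", "female")]
        return cls(f_between={k: _zero for k in keys},
                   f_within={k: _zero for k in keys},
                   smooth_params={"shape": "zero"}, **kw)

    def f_b(self, cls: str, sex: str):
        return self.f_between.get((cls, sex), _zero)

    def f_w(self, cls: str, sex: str):
        return self.f_within.get((cls, sex), _zero)


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults mirror the published cohort where the source reports them
    (index window, follow-up length, sex mix, covariate prevalences, yearly
    death risk, per-class adherence levels); free quantities (refill timing,
    effect sizes) are fixed package choices documented in the methods note.
    """

    n_patients: int = 1000
    seed: int = 0
    index_window: tuple[str, str] = ("2009-01-01", "2011-12-31")
    followup_years: int = 3
    class_list: tuple = DRUG_CLASSES
    #: per-class Beta(a, b) for the person-level mean PDC
    adherence_mean_dist: dict = field(default_factory=lambda: {
        "ACE": (2.8, 1.2), "BB": (1.9, 2.1), "STATIN": (3.2, 0.8), "APA": (1.8, 2.2)})
    #: per-class SD of yearly deviations (fraction units)
    adherence_dev_sd: dict = field(default_factory=lambda: {
        "ACE": 0.12, "BB": 0.12, "STATIN": 0.10, "APA": 0.14})
    death_hazard: float = 0.07
    hosp_rate: float = 0.4                    # expected non-index stays / year
    hosp_los_meanlog: float = 1.8             # lognormal LOS (days)
    hosp_los_sdlog: float = 0.7
    cost_model: CostTruth = field(default_factory=CostTruth.nonlinear)
    male_share: float = 0.674
    covariate_prevalences: dict = field(default_factory=lambda: {
        "bmi_group": {"underweight": 0.01, "normal": 0.21, "overweight": 0.46,
                      "obese": 0.32},
        "smoker": 0.12,
        "nyha": {0: 0.48, 1: 0.03, 2: 0.12, 3: 0.19, 4: 0.18},
        "dmp_copd": 0.08, "dmp_asthma": 0.025, "dmp_diabetes1": 0.003,
        "dmp_diabetes2": 0.44,
        "angina_pectoris": 0.45, "peripheral_vascular_disease": 0.85,
        "dyslipidemia": 0.83, "congestive_heart_failure": 0.58,
        "hypertension": 0.96, "dialysis": 0.03,
    })
    refill_days: int = 30
    reference_atc: dict = field(default_factory=lambda: {
        "ACE": "C09AA05", "BB": "C07AB07", "STATIN": "C10AA01", "APA": "B01AC06"})
    # ineligibility injections (all zero by default: a fully eligible cohort)
    frac_no_dmp_enrollment: float = 0.0
    frac_no_recent_doc: float = 0.0
    frac_insurance_gap: float = 0.0
    frac_early_death: float = 0.0
    frac_missing_covariate: float = 0.0

    def __post_init__(self):
        if self.n_patients <= 0:
            raise SimConfigError(f"n_patients must be positive, got {self.n_patients}")
        if not 0.0 <= self.death_hazard < 1.0:
            raise SimConfigError("death_hazard must be in [0, 1)")
        for cls, (a, b) in self.adherence_mean_dist.items():
            if a <= 0 or b <= 0:
                raise SimConfigError(f"Beta parameters for {cls} must be positive")
        for cls, sd in self.adherence_dev_sd.items():
            if sd < 0:
                raise SimConfigError(f"adherence_dev_sd for {cls} must be >= 0")
        for key in ("male_share", "frac_no_dmp_enrollment", "frac_no_recent_doc",
                    "frac_insurance_gap", "frac_early_death", "frac_missing_covariate"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{key} must be a probability, got {v}")


# ----------------------------------------------------------------- population
def generate_population(config: SimConfig, rng: np.random.Generator | None = None):
    """Patient master table + per-year covariate table.

    Returns ``(patients, covariates)``.  Patients carry an index date inside
    the index window, sex, birth/death dates, DMP CAD enrollment, one
    insurance spell and the deprivation quintile; covariates carry the
    per-year model covariates.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_patients
    lo = pd.Timestamp(config.index_window[0])
    hi = pd.Timestamp(config.index_window[1])
    span = (hi - lo).days + 1

    pid = np.array([f"P{i:06d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.male_share, "male", "female")
    index_date = lo + pd.to_timedelta(rng.integers(0, span, n), unit="D")
    age = np.clip(rng.normal(72.0, 10.0, n), 35.0, 95.0)
    birth_date = index_date - pd.to_timedelta((age * 365.25).astype(int), unit="D")

    fu_days = config.followup_years * YEAR_DAYS
    death_offset = np.full(n, -1)
    early = rng.random(n) < config.frac_early_death
    for i in range(n):
        for y in range(config.followup_years):
            if rng.random() < config.death_hazard:
                if y == 0:
                    day0 = int(rng.integers(0, 31)) if early[i] \
                        else int(rng.integers(31, YEAR_DAYS))
                else:
                    day0 = int(rng.integers(0, YEAR_DAYS))
                death_offset[i] = y * YEAR_DAYS + day0
                break
    death_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    has_death = death_offset >= 0
    death_date[has_death] = (index_date[has_death]
                             + pd.to_timedelta(death_offset[has_death], unit="D"))

    enroll_lag = rng.integers(200, 1500, n)
    no_dmp = rng.random(n) < config.frac_no_dmp_enrollment
    dmp_enroll = index_date - pd.to_timedelta(enroll_lag, unit="D")
    dmp_enroll = dmp_enroll.where(~no_dmp, index_date + pd.Timedelta(days=10))

    ins_start = index_date - pd.to_timedelta(YEAR_DAYS + rng.integers(0, 200, n), unit="D")
    ins_end = index_date + pd.to_timedelta(fu_days + rng.integers(10, 200, n), unit="D")
    gap = rng.random(n) < config.frac_insurance_gap
    ins_end = ins_end.where(~gap, index_date + pd.Timedelta(days=500))

    patients = pd.DataFrame({
        "patient_id": pid, "sex": sex,
        "birth_date": birth_date, "death_date": death_date.values,
        "index_date": index_date,
        "dmp_cad_enrollment": dmp_enroll,
        "insurance_start": ins_start, "insurance_end": ins_end,
        "bimd_quintile": rng.integers(1, 6, n),
    })

    prev = config.covariate_prevalences

    def cat_draw(dist: dict, size: int):
        keys = list(dist)
        probs = np.array([dist[k] for k in keys], dtype=float)
        probs = probs / probs.sum()
        return rng.choice(np.array(keys, dtype=object), p=probs, size=size)

    bmi = cat_draw(prev["bmi_group"], n)
    nyha = cat_draw(prev["nyha"], n).astype(int)
    flags = {k: (rng.random(n) < prev[k]).astype(int)
             for k in ("smoker", "dmp_copd", "dmp_asthma", "dmp_diabetes1",
                       "dmp_diabetes2", "angina_pectoris",
                       "peripheral_vascular_disease", "dyslipidemia",
                       "congestive_heart_failure", "hypertension", "dialysis")}
    missing = rng.random(n) < config.frac_missing_covariate

    cov_rows = []
    for year in range(1, config.followup_years + 1):
        hmg = np.round(rng.lognormal(6.0, 0.8, n), 2)
        df = pd.DataFrame({
            "patient_id": pid, "year": year,
            "bmi_group": bmi, "smoker": flags["smoker"], "nyha": nyha,
            "dmp_copd": flags["dmp_copd"], "dmp_asthma": flags["dmp_asthma"],
            "dmp_diabetes1": flags["dmp_diabetes1"],
            "dmp_diabetes2": flags["dmp_diabetes2"],
            "hmg_per_month": hmg,
            "angina_pectoris": flags["angina_pectoris"],
            "peripheral_vascular_disease": flags["peripheral_vascular_disease"],
            "dyslipidemia": flags["dyslipidemia"],
            "congestive_heart_failure": flags["congestive_heart_failure"],
            "hypertension": flags["hypertension"], "dialysis": flags["dialysis"],
        })
        if year == 1:
            df.loc[missing, "bmi_group"] = np.nan
        cov_rows.append(df)
    covariates = pd.concat(cov_rows, ignore_index=True)
    return patients, covariates


def generate_dmp_docs(config: SimConfig, patients: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """DMP documentation dates: quarterly from enrollment to the index date."""
    rows = []
    no_recent = rng.random(len(patients)) < config.frac_no_recent_doc
    for i, pat in patients.iterrows():
        start = min(pat["dmp_cad_enrollment"], pat["index_date"])
        last_allowed = (pat["index_date"] - pd.Timedelta(days=181) if no_recent[i]
                        else pat["index_date"] - pd.Timedelta(days=int(rng.integers(1, 120))))
        d = start
        dates = []
        while d < pat["index_date"]:
            if d < last_allowed:
                dates.append(d)
            d = d + pd.Timedelta(days=90)
        # eligible patients always have a documentation at last_allowed (for
        # the ineligible injection this lies > 180 days before the index)
        if last_allowed >= start:
            dates.append(last_allowed)
        for d in dates:
            rows.append({"patient_id": pat["patient_id"], "doc_date": d})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ adherence
def generate_adherence_truth(config: SimConfig, population: pd.DataFrame,
                             rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ground-truth adherence: person means, yearly deviations, realized targets.

    Yearly deviations are recentred to sum to zero over the patient's observed
    follow-up years; the realized yearly target is ``clip(m + d_y, 0, 1)``.
    ``m_star``/``d_star`` are the decomposition-consistent quantities (mean of
    the realized targets over observed years and the deviations from it).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    fu = config.followup_years
    rows = []
    for _, pat in population.iterrows():
        death = pat["death_date"]
        if pd.isna(death):
            observed = fu
        else:
            off = (pd.Timestamp(death) - pat["index_date"]).days
            observed = min(fu, -(-off // YEAR_DAYS))  # years with >=1 survived day
        for cls in config.class_list:
            a, b = config.adherence_mean_dist[cls]
            m = float(rng.beta(a, b))
            sd = config.adherence_dev_sd[cls]
            d = rng.normal(0.0, sd, fu) if sd > 0 else np.zeros(fu)
            if observed >= 2:
                d[:observed] -= d[:observed].mean()
            elif observed == 1:
                d[0] = 0.0
            target = np.clip(m + d, 0.0, 1.0)
            m_star = float(target[:observed].mean()) if observed else np.nan
            for y in range(1, fu + 1):
                rows.append({
                    "patient_id": pat["patient_id"], "drug_class": cls,
                    "period_index": y, "observed": y <= observed,
                    "pdc_person_mean": m, "pdc_year_dev": float(d[y - 1]),
                    "target_pdc": float(target[y - 1]),
                    "m_star": m_star,
                    "d_star": float(target[y - 1] - m_star) if y <= observed else np.nan,
                })
    return pd.DataFrame(rows)


def generate_hospital_stays(config: SimConfig, population: pd.DataFrame,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Index AMI stay plus Poisson background stays, truncated at death."""
    rng = rng or np.random.default_rng(config.seed + 2)
    rows = []
    for _, pat in population.iterrows():
        pid, idx = pat["patient_id"], pat["index_date"]
        death = pat["death_date"]
        death_off = ((pd.Timestamp(death) - idx).days if pd.notna(death) else None)

        def add_stay(start_off: int, los: int, icd: str):
            if death_off is not None:
                if start_off >= death_off:
                    return
                los = min(los, death_off - start_off)
            los = max(1, los)
            rows.append({"patient_id": pid,
                         "admit_date": idx + pd.Timedelta(days=start_off),
                         "discharge_date": idx + pd.Timedelta(days=start_off + los),
                         "icd_code": icd})

        los_index = int(np.clip(round(rng.lognormal(config.hosp_los_meanlog,
                                                    config.hosp_los_sdlog)), 1, 60))
        add_stay(0, los_index, "I21.4")
        fu_days = config.followup_years * YEAR_DAYS
        horizon = fu_days if death_off is None else min(fu_days, death_off)
        n_stays = rng.poisson(config.hosp_rate * horizon / YEAR_DAYS)
        for _ in range(n_stays):
            start_off = int(rng.integers(1, max(horizon, 2)))
            los = int(np.clip(round(rng.lognormal(config.hosp_los_meanlog,
                                                  config.hosp_los_sdlog)), 1, 60))
            add_stay(start_off, los, "I50.9")
    stays = pd.DataFrame(rows)
    return stays.sort_values(["patient_id", "admit_date"]).reset_index(drop=True)


def generate_dispensations(
    targets: pd.DataFrame,
    population: pd.DataFrame,
    hospital_stays: pd.DataFrame,
    ddd_table: DddTable | None = None,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Dispensation stream realizing the target PDCs under the adherence engine.

    For each patient x class x period the needed covered days are
    ``round(target * eligible_days)``; refills of ``config.refill_days`` days
    are dated back-to-back starting at the period's first eligible day, so the
    engine reproduces each target within half a day of the period denominator.
    Pre-index targets (period -1) seed the pre-year from the person mean.
    """
    config = config or SimConfig()
    ddd_table = ddd_table or DddTable.default()
    rng = rng or np.random.default_rng(config.seed + 3)
    if ((targets["target_pdc"] < 0) | (targets["target_pdc"] > 1)).any():
        raise SimConfigError("target PDC outside [0, 1]")

    cohort_like = population[["patient_id", "index_date", "death_date"]]
    periods = build_observation_periods(cohort_like, hospital_stays)
    stay_map = _merged_stay_intervals(hospital_stays)

    rows = []
    tgt = targets.set_index(["patient_id", "drug_class", "period_index"])["target_pdc"]
    pre_mean = (targets[targets["period_index"] == 1]
                .set_index(["patient_id", "drug_class"])["pdc_person_mean"])
    for pid, per_pat in periods.groupby("patient_id"):
        axis = build_patient_axis(per_pat, stay_map.get(pid, []))
        for cls in config.class_list:
            atc = config.reference_atc[cls]
            ddd = ddd_table.resolve(atc)
            for p in sorted(axis.period_slices):
                i0, i1 = axis.period_slices[p]
                n_allowed = i1 - i0
                if n_allowed <= 0:
                    continue
                if p == -1:
                    t = float(np.clip(pre_mean.get((pid, cls), 0.0), 0.0, 1.0))
                else:
                    t = float(tgt.get((pid, cls, p), 0.0))
                needed = int(math.floor(t * n_allowed + 0.5))
                pos = i0
                while needed > 0:
                    chunk = min(config.refill_days, needed)
                    day = pd.Timestamp(np.datetime64(int(axis.allowed[pos]), "D"))
                    rows.append({"patient_id": pid, "atc_code": atc,
                                 "dispense_date": day,
                                 "amount_mg": chunk * ddd})
                    pos += chunk
                    needed -= chunk
    disp = pd.DataFrame(rows, columns=["patient_id", "atc_code", "dispense_date",
                                       "amount_mg"])
    return disp.sort_values(["patient_id", "atc_code", "dispense_date"]).reset_index(drop=True)


# ----------------------------------------------------------------------- costs
def _effect_sum(row: dict, effects: dict) -> float:
    total = 0.0
    for label, eff in effects.items():
        if "[" in label:
            col, level = label[:-1].split("[", 1)
            if str(row.get(col)) == level:
                total += eff
        else:
            total += eff * float(row.get(label, 0.0))
    return total


def generate_hospital_and_costs(
    config: SimConfig,
    population: pd.DataFrame,
    covariates: pd.DataFrame,
    adherence_truth: pd.DataFrame,
    hospital_stays: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
):
    """Hospital-stay table + cost line items + patient intercepts.

    Yearly total cost = baseline + covariate effects + year effect +
    sum of between-smooths at the realized PDC mean + sum of within-smooths
    at the realized yearly deviation + patient intercept + Gaussian noise,
    floored at zero (configurable) and split across the five cost categories
    in fixed proportions.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
    truth = config.cost_model
    if hospital_stays is None:
        hospital_stays = generate_hospital_stays(config, population, rng)

    b_i = rng.normal(0.0, truth.sigma_patient, len(population))
    intercepts = pd.DataFrame({"patient_id": population["patient_id"],
                               "patient_intercept": b_i})

    adh = adherence_truth[adherence_truth["observed"]]
    adh_map = adh.set_index(["patient_id", "drug_class", "period_index"])

    cov = covariates.set_index(["patient_id", "year"])
    rows = []
    for i, pat in population.reset_index(drop=True).iterrows():
        pid, idx, sex = pat["patient_id"], pat["index_date"], pat["sex"]
        death = pat["death_date"]
        death_off = ((pd.Timestamp(death) - idx).days if pd.notna(death) else None)
        for year in range(1, config.followup_years + 1):
            start_off = (year - 1) * YEAR_DAYS
            if death_off is not None and death_off <= start_off:
                break
            days_surv = YEAR_DAYS if death_off is None else \
                min(YEAR_DAYS, death_off - start_off)
            row = cov.loc[(pid, year)].to_dict()
            row.update({"sex": sex, "bimd_quintile": pat["bimd_quintile"],
                        "age_group": _age_group_at(pat["birth_date"],
                                                   idx + pd.Timedelta(days=start_off)),
                        "deceased": int(death_off is not None
                                        and start_off <= death_off < start_off + YEAR_DAYS),
                        "days_survived_c": days_surv - 365.0})
            total = truth.baseline + truth.year_effect * (year - 1)
            total += _effect_sum(row, truth.covariate_effects)
            for cls in config.class_list:
                key = (pid, cls, year)
                if key not in adh_map.index:
                    continue
                arow = adh_map.loc[key]
                total += float(truth.f_b(cls, sex)(100.0 * arow["m_star"]))
                total += float(truth.f_w(cls, sex)(100.0 * arow["d_star"]))
            total += b_i[i] + rng.normal(0.0, truth.sigma_resid)
            if truth.floor_at_zero:
                total = max(total, 0.0)
            service = idx + pd.Timedelta(days=start_off + min(180, max(days_surv - 1, 0)))
            for cat, share in zip(COST_CATEGORIES, truth.category_shares):
                rows.append({"patient_id": pid, "service_date": service,
                             "category": cat, "amount_eur": total * share})
    cost_items = pd.DataFrame(rows)
    return hospital_stays, cost_items, intercepts


def _age_group_at(birth, when) -> str:
    age = (pd.Timestamp(when) - pd.Timestamp(birth)).days / 365.25
    if age < 55:
        return "<55"
    if age < 65:
        return "55-64"
    if age < 75:
        return "65-74"
    return ">=75"


# -------------------------------------------------------------------- bundle
@dataclass
class SimulatedData:
    patients: pd.DataFrame
    covariates: pd.DataFrame
    dmp_docs: pd.DataFrame
    hospital_stays: pd.DataFrame
    dispensations: pd.DataFrame
    cost_items: pd.DataFrame
    adherence_truth: pd.DataFrame
    patient_intercepts: pd.DataFrame
    config: SimConfig


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """Run the full generator with a single seeded random stream."""
    rng = np.random.default_rng(config.seed)
    patients, covariates = generate_population(config, rng)
    dmp_docs = generate_dmp_docs(config, patients, rng)
    adherence_truth = generate_adherence_truth(config, patients, rng)
    hospital_stays = generate_hospital_stays(config, patients, rng)
    dispensations = generate_dispensations(adherence_truth, patients, hospital_stays,
                                           config=config, rng=rng)
    _, cost_items, intercepts = generate_hospital_and_costs(
        config, patients, covariates, adherence_truth, hospital_stays, rng)
    return SimulatedData(patients=patients, covariates=covariates, dmp_docs=dmp_docs,
                         hospital_stays=hospital_stays, dispensations=dispensations,
                         cost_items=cost_items, adherence_truth=adherence_truth,
                         patient_intercepts=intercepts, config=config)


def write_dataset(data: SimulatedData, out_dir) -> None:
    """Write the five input CSVs plus ground-truth sidecars (ISO-8601 dates)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.patients.to_csv(out / "patients.csv", index=False, date_format="%Y-%m-%d")
    data.covariates.to_csv(out / "covariates.csv", index=False)
    data.dmp_docs.to_csv(out / "dmp_docs.csv", index=False, date_format="%Y-%m-%d")
    data.hospital_stays.to_csv(out / "hospital_stays.csv", index=False,
                               date_format="%Y-%m-%d")
    data.dispensations.to_csv(out / "dispensations.csv", index=False,
                              date_format="%Y-%m-%d")
    data.cost_items.to_csv(out / "costs.csv", index=False, date_format="%Y-%m-%d")
    data.adherence_truth.to_csv(out / "truth_adherence.csv", index=False)
    data.patient_intercepts.to_csv(out / "truth_patient_intercepts.csv", index=False)
    truth = data.config.cost_model
    params = {"baseline": truth.baseline, "year_effect": truth.year_effect,
              "covariate_effects": truth.covariate_effects,
              "sigma_patient": truth.sigma_patient,
              "sigma_resid": truth.sigma_resid,
              "category_shares": list(truth.category_shares),
              "smooth_params": truth.smooth_params,
              "seed": data.config.seed, "n_patients": data.config.n_patients}
    (out / "truth_cost_params.json").write_text(json.dumps(params, indent=2))
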