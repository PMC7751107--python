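"""Model-frame assembly: join costs, decomposed PDC and covariates per patient-year.

The resulting frame has one row per patient x follow-up year with the cost
response, the parametric covariates of the study model (age group, sex, BMI
group, deprivation quintile, smoking, NYHA class, DMP enrollments, death
indicator, HMG euros/month, year after the index event, days survived, and
six comorbidity indicators) and the eight smooth covariates (per-class PDC
mean and PDC deviation, percent scale).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .costs import category_model_inputs
from .decompose import decompose_pdc, decomposition_wide
from .drugs import CLASS_LABELS, DRUG_CLASSES
from .gamm import CostGAMM, SmoothSpec, Term

AGE_LEVELS = ("<55", "55-64", "65-74", ">=75")
BMI_LEVELS = ("normal", "underweight", "overweight", "obese")
BIMD_LEVELS = (1, 2, 3, 4, 5)
NYHA_LEVELS = (0, 1, 2, 3, 4)
SEX_LEVELS = ("male", "female")

COMORBIDITY_FLAGS = ("angina_pectoris", "peripheral_vascular_disease",
                     "dyslipidemia", "congestive_heart_failure",
                     "hypertension", "dialysis")
DMP_FLAGS = ("dmp_copd", "dmp_asthma", "dmp_diabetes1", "dmp_diabetes2")

SMOOTH_COLS = tuple(f"{c.lower()}_{k}" for c in DRUG_CLASSES for k in ("mean", "dev"))


def age_group(age_years: pd.Series) -> pd.Series:
    bins = [-np.inf, 55, 65, 75, np.inf]
    return pd.cut(age_years, bins=bins, right=False, labels=AGE_LEVELS).astype(str)


def build_model_frame(
    cost_panel: pd.DataFrame,
    pdc_panel: pd.DataFrame,
    cohort: pd.DataFrame,
    covariates: pd.DataFrame,
    periods: pd.DataFrame,
    response: str = "total",
    within: str = "deviation",
) -> pd.DataFrame:
    """One row per patient x follow-up year, ready for :class:`CostGAMM`."""
    panel = cost_panel.copy()
    panel["response"] = category_model_inputs(panel, response)
    frame = panel[["patient_id", "period_index", "response"]]

    wide = decomposition_wide(decompose_pdc(pdc_panel, within=within))
    frame = frame.merge(wide, on=["patient_id", "period_index"], how="inner")

    per = periods[periods["period_index"] > 0][
        ["patient_id", "period_index", "start", "days_survived"]]
    frame = frame.merge(per, on=["patient_id", "period_index"], how="left")

    pat = cohort[["patient_id", "sex", "birth_date", "death_date",
                  "bimd_quintile", "index_date"]].copy()
    for c in ("birth_date", "death_date", "index_date"):
        pat[c] = pd.to_datetime(pat[c])
    frame = frame.merge(pat, on="patient_id", how="inner")

    cov = covariates.rename(columns={"year": "period_index"})
    frame = frame.merge(cov, on=["patient_id", "period_index"], how="left")

    frame["start"] = pd.to_datetime(frame["start"])
    age = (frame["start"] - frame["birth_date"]).dt.days / 365.25
    frame["age_group"] = age_group(age)
    end = frame["start"] + pd.Timedelta(days=365)
    frame["deceased"] = (frame["death_date"].notna()
                         & (frame["death_date"] >= frame["start"])
                         & (frame["death_date"] < end)).astype(int)
    frame["year_after_ami"] = frame["period_index"].astype(int)
    frame["days_survived_c"] = frame["days_survived"] - 365.0

    model_cols = (["patient_id", "period_index", "response", "sex", "age_group",
                   "bmi_group", "bimd_quintile", "smoker", "nyha", "deceased",
                   "hmg_per_month", "year_after_ami", "days_survived_c"]
                  + list(DMP_FLAGS) + list(COMORBIDITY_FLAGS) + list(SMOOTH_COLS))
    out = frame[model_cols].dropna().reset_index(drop=True)
    return out


def default_parametric_terms(survivors_only: bool = False) -> list[Term]:
    """The study model's parametric covariate block.

    With ``survivors_only`` the death indicator and the days-survived
    covariate are omitted, as they are constant in a surviving cohort.
    """
    terms = [
        Term("age_group", "categorical", AGE_LEVELS),
        Term("sex", "categorical", SEX_LEVELS),
        Term("bmi_group", "categorical", BMI_LEVELS),
        Term("bimd_quintile", "categorical", BIMD_LEVELS),
        Term("smoker", "numeric"),
        Term("nyha", "categorical", NYHA_LEVELS),
        Term("dmp_copd", "numeric"),
        Term("dmp_asthma", "numeric"),
        Term("dmp_diabetes1", "numeric"),
        Term("dmp_diabetes2", "numeric"),
    ]
    if not survivors_only:
        terms += [Term("deceased", "numeric")]
    terms += [
        Term("hmg_per_month", "numeric"),
        Term("year_after_ami", "numeric"),
    ]
    if not survivors_only:
        terms += [Term("days_survived_c", "numeric")]
    terms += [Term(c, "numeric") for c in COMORBIDITY_FLAGS]
    return terms


def default_smooth_specs(rank: int = 10) -> list[SmoothSpec]:
    """Sixteen sex-stratified smooths: 4 classes x {mean, dev} x {male, female}."""
    specs = []
    for cls in DRUG_CLASSES:
        for kind, word in (("mean", "PDC mean"), ("dev", "PDC deviation")):
            for sex in SEX_LEVELS:
                specs.append(SmoothSpec(
                    name=f"s({word} {CLASS_LABELS[cls]}) {sex}",
                    col=f"{cls.lower()}_{kind}",
                    by_col="sex", by_val=sex, rank=rank))
    return specs


def make_cost_gamm(survivors_only: bool = False, rank: int = 10,
                   smooth_variances: str = "estimate") -> CostGAMM:
    """The study model, configured: parametric block + 16 smooths + patient
    random intercepts."""
    return CostGAMM(parametric=default_parametric_terms(survivors_only),
                    smooths=default_smooth_specs(rank),
                    group_col="patient_id",
                    smooth_variances=smooth_variances)
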