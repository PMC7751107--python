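"""Cohort construction: index-event selection, inclusion cascade, observation periods.

The analysis cohort consists of patients with an index hospitalization whose
main discharge diagnosis is acute myocardial infarction (ICD-10 I21) inside a
fixed index window.  Observation time is anchored on the index *admission*
date: the pre-year is [index-365, index) and follow-up year y is
[index+(y-1)*365, index+y*365), all half-open so day counts are additive.

Inclusion filters (each logged in an attrition table):

1. enrollment in the DMP for coronary artery disease before the index admission;
2. at least one DMP documentation date within the 180 days before the index;
3. continuous insurance from one year before the index until three years after
   (or until death, if earlier);
4. survival beyond 30 days after the index admission (death on day 30 excludes,
   day 31 keeps);
5. complete model covariates (listwise over the observed follow-up years).

Two sensitivity filters are provided: dropping patients who spent more than
half of their survived follow-up days in hospital, and restricting to patients
surviving the full 3-year follow-up.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

YEAR_DAYS = 365
FOLLOWUP_YEARS = 3
PRE_PERIOD = -1

#: covariate columns required per observed follow-up year (listwise exclusion)
COVARIATE_COLUMNS = [
    "bmi_group", "smoker", "nyha", "dmp_copd", "dmp_asthma", "dmp_diabetes1",
    "dmp_diabetes2", "hmg_per_month", "angina_pectoris", "peripheral_vascular_disease",
    "dyslipidemia", "congestive_heart_failure", "hypertension", "dialysis",
]

CASCADE_STEPS = (
    ("index_event", "qualifying AMI (ICD-10 I21) admission inside index window"),
    ("dmp_enrolled", "DMP CAD enrollment before index admission"),
    ("dmp_documented", "DMP documentation within 180 days before index"),
    ("insured", "continuous insurance 1 year before to 3 years after index (or death)"),
    ("survived_30d", "survived more than 30 days after index admission"),
    ("covariates_complete", "complete model covariates"),
)


class CohortInputError(ValueError):
    """Raised for malformed cohort inputs (bad dates, unknown modes)."""


def _as_date(s: pd.Series, name: str) -> pd.Series:
    try:
        return pd.to_datetime(s, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise CohortInputError(f"malformed date in column {name!r}: {exc}") from exc


def select_index_event(
    hospital_stays: pd.DataFrame,
    window: tuple[str, str] = ("2009-01-01", "2011-12-31"),
) -> pd.DataFrame:
    """Earliest I21 admission inside the window per patient.

    Returns one row per qualifying patient with columns
    ``patient_id, admit_date, discharge_date, icd_code``.
    """
    stays = hospital_stays.copy()
    stays["admit_date"] = _as_date(stays["admit_date"], "admit_date")
    stays["discharge_date"] = _as_date(stays["discharge_date"], "discharge_date")
    if (stays["admit_date"] > stays["discharge_date"]).any():
        bad = stays.loc[stays["admit_date"] > stays["discharge_date"]].index[:5].tolist()
        raise CohortInputError(f"admit_date after discharge_date at rows {bad}")
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    qual = stays[
        stays["icd_code"].astype(str).str.upper().str.startswith("I21")
        & (stays["admit_date"] >= lo)
        & (stays["admit_date"] <= hi)
    ]
    idx = (
        qual.sort_values(["patient_id", "admit_date", "discharge_date"])
        .groupby("patient_id", as_index=False)
        .first()
    )
    return idx[["patient_id", "admit_date", "discharge_date", "icd_code"]].rename(
        columns={"admit_date": "index_date"}
    )


def normalize_spells(spells: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/abutting insurance spells per patient (half-open dates)."""
    sp = spells.copy()
    sp["start"] = _as_date(sp["start"], "start")
    sp["end"] = _as_date(sp["end"], "end")
    out = []
    for pid, grp in sp.sort_values(["patient_id", "start"]).groupby("patient_id"):
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # abutting counts as continuous
                cur_e = max(cur_e, e)
            else:
                out.append((pid, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            out.append((pid, cur_s, cur_e))
    return pd.DataFrame(out, columns=["patient_id", "start", "end"])


def _continuously_insured(spells: pd.DataFrame, need_start: pd.Series,
                          need_end: pd.Series) -> pd.Series:
    """Per patient: does one merged spell cover [need_start, need_end)?"""
    merged = normalize_spells(spells)
    need = pd.DataFrame({"need_start": need_start, "need_end": need_end})
    covered = pd.Series(False, index=need.index)
    by_pid = dict(tuple(merged.groupby("patient_id")))
    for pid, row in need.iterrows():
        grp = by_pid.get(pid)
        if grp is None:
            continue
        ok = ((grp["start"] <= row["need_start"]) & (grp["end"] >= row["need_end"])).any()
        covered.loc[pid] = bool(ok)
    return covered


@dataclass
class CascadeResult:
    cohort: pd.DataFrame          # patients surviving all filters, with index_date
    attrition: pd.DataFrame       # one row per step: n_before, n_excluded, n_after
    exclusions: pd.DataFrame      # patient_id -> first step at which excluded


def apply_inclusion_cascade(
    patients: pd.DataFrame,
    index_events: pd.DataFrame,
    dmp_docs: pd.DataFrame,
    spells: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    doc_lookback_days: int = 180,
    death_exclusion_days: int = 30,
    step_order: tuple[str, ...] | None = None,
) -> CascadeResult:
    """Apply the inclusion/exclusion cascade and log attrition.

    ``patients`` must carry ``patient_id, death_date, dmp_cad_enrollment``;
    ``covariates`` (optional) carries per-year covariate values used for the
    listwise completeness check.  ``step_order`` permutes the order of the
    order-independent filters (the final cohort is invariant to it).
    """
    pats = patients.set_index("patient_id", drop=False)
    pats["death_date"] = _as_date(pats["death_date"], "death_date")
    pats["dmp_cad_enrollment"] = _as_date(pats["dmp_cad_enrollment"], "dmp_cad_enrollment")
    idx = index_events.set_index("patient_id")["index_date"]

    docs = dmp_docs.copy()
    docs["doc_date"] = _as_date(docs["doc_date"], "doc_date")

    # --- evaluate every predicate on the full patient universe ------------
    flags = pd.DataFrame(index=pats.index)
    flags["index_event"] = pats.index.isin(idx.index)

    aligned_idx = idx.reindex(pats.index)
    flags["dmp_enrolled"] = pats["dmp_cad_enrollment"].notna() & (
        pats["dmp_cad_enrollment"] < aligned_idx
    )

    docs = docs.merge(aligned_idx.rename("index_date"), left_on="patient_id", right_index=True)
    recent = docs[
        (docs["doc_date"] >= docs["index_date"] - pd.Timedelta(days=doc_lookback_days))
        & (docs["doc_date"] < docs["index_date"])
    ]
    flags["dmp_documented"] = pats.index.isin(recent["patient_id"])

    death = pats["death_date"]
    followup_end = aligned_idx + pd.Timedelta(days=FOLLOWUP_YEARS * YEAR_DAYS)
    # insurance is required up to death (exclusive) or the end of follow-up
    need_end = followup_end.where(death.isna(), np.minimum(followup_end, death))
    need_start = aligned_idx - pd.Timedelta(days=YEAR_DAYS)
    flags["insured"] = _continuously_insured(spells, need_start, need_end)

    days_to_death = (death - aligned_idx).dt.days
    flags["survived_30d"] = death.isna() | (days_to_death > death_exclusion_days)

    if covariates is not None:
        cov = covariates.copy()
        missing_any = (
            cov.set_index("patient_id")[COVARIATE_COLUMNS].isna().any(axis=1).groupby(level=0).any()
        )
        base_cols = [c for c in ("sex", "birth_date", "bimd_quintile") if c in pats.columns]
        base_missing = pats[base_cols].isna().any(axis=1) if base_cols else False
        flags["covariates_complete"] = (
            pats.index.isin(missing_any.index)
            & ~pats.index.map(missing_any).fillna(True).astype(bool)
            & ~base_missing
        )
    else:
        flags["covariates_complete"] = True

    # predicates other than index_event are meaningless without an index date
    for col in flags.columns:
        if col != "index_event":
            flags[col] &= flags["index_event"]

    order = step_order or tuple(name for name, _ in CASCADE_STEPS)
    if set(order) != {name for name, _ in CASCADE_STEPS}:
        raise CohortInputError(f"step_order must permute {[n for n, _ in CASCADE_STEPS]}")

    descriptions = dict(CASCADE_STEPS)
    remaining = pd.Series(True, index=pats.index)
    rows, excl = [], {}
    for name in order:
        n_before = int(remaining.sum())
        newly_excluded = remaining & ~flags[name]
        for pid in pats.index[newly_excluded]:
            excl[pid] = name
        remaining &= flags[name]
        rows.append(
            {"step": name, "description": descriptions[name], "n_before": n_before,
             "n_excluded": int(newly_excluded.sum()), "n_after": int(remaining.sum())}
        )

    cohort = pats.loc[remaining].copy()
    cohort["index_date"] = idx.reindex(cohort.index)
    attrition = pd.DataFrame(rows)
    exclusions = pd.DataFrame(
        sorted(excl.items()), columns=["patient_id", "excluded_at"]
    )
    return CascadeResult(cohort=cohort.reset_index(drop=True), attrition=attrition,
                         exclusions=exclusions)


def _merged_stay_intervals(stays: pd.DataFrame) -> dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]]:
    st = stays.copy()
    st["admit_date"] = _as_date(st["admit_date"], "admit_date")
    st["discharge_date"] = _as_date(st["discharge_date"], "discharge_date")
    out: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = {}
    for pid, grp in st.sort_values(["patient_id", "admit_date"]).groupby("patient_id"):
        merged: list[tuple[pd.Timestamp, pd.Timestamp]] = []
        for a, d in zip(grp["admit_date"], grp["discharge_date"]):
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], d))
            else:
                merged.append((a, d))
        out[pid] = merged
    return out


def build_observation_periods(cohort: pd.DataFrame, hospital_stays: pd.DataFrame) -> pd.DataFrame:
    """One row per patient x period with survived and hospital day counts.

    Hospital days are the union of stay intervals [admit, discharge)
    intersected with the period and with the survived span.  Survived days run
    up to the death date exclusive (a death 400 days after the index leaves
    35 survived days in year 2).  Follow-up periods lying entirely after death
    are omitted; the pre-year is always emitted.
    """
    stays = _merged_stay_intervals(hospital_stays)
    rows = []
    for _, pat in cohort.iterrows():
        pid, index_date = pat["patient_id"], pd.Timestamp(pat["index_date"])
        death = pat.get("death_date")
        death = pd.Timestamp(death) if pd.notna(death) else None
        lived_end_cap = death if death is not None else None
        for period in (PRE_PERIOD, 1, 2, 3):
            if period == PRE_PERIOD:
                start = index_date - pd.Timedelta(days=YEAR_DAYS)
                end = index_date
            else:
                start = index_date + pd.Timedelta(days=(period - 1) * YEAR_DAYS)
                end = start + pd.Timedelta(days=YEAR_DAYS)
            lived_end = end if lived_end_cap is None else min(end, lived_end_cap)
            days_survived = max(0, (lived_end - start).days)
            if period != PRE_PERIOD and days_survived == 0:
                continue
            hosp = 0
            for a, d in stays.get(pid, ()):
                lo, hi = max(a, start), min(d, lived_end)
                if hi > lo:
                    hosp += (hi - lo).days
            rows.append(
                {"patient_id": pid, "period_index": period, "start": start, "end": end,
                 "days_in_period": YEAR_DAYS, "days_survived": days_survived,
                 "hospital_days": hosp}
            )
    return pd.DataFrame(rows)


def sensitivity_filter(
    cohort: pd.DataFrame,
    periods: pd.DataFrame,
    mode: str,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Sensitivity-analysis cohort filters.

    ``hospital_share`` drops patients whose follow-up hospital days exceed
    ``threshold`` of their survived follow-up days; ``survivors_only`` drops
    patients dying inside the 3-year follow-up window.
    """
    if mode == "hospital_share":
        fu = periods[periods["period_index"] > 0]
        shares = fu.groupby("patient_id").apply(
            lambda g: g["hospital_days"].sum() / max(g["days_survived"].sum(), 1),
            include_groups=False,
        )
        drop = set(shares.index[shares > threshold])
        return cohort[~cohort["patient_id"].isin(drop)].reset_index(drop=True)
    if mode == "survivors_only":
        death = pd.to_datetime(cohort["death_date"], format="ISO8601")
        index_date = pd.to_datetime(cohort["index_date"], format="ISO8601")
        end = index_date + pd.Timedelta(days=FOLLOWUP_YEARS * YEAR_DAYS)
        keep = death.isna() | (death >= end)
        return cohort[keep].reset_index(drop=True)
    raise CohortInputError(f"unknown sensitivity mode {mode!r}")
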