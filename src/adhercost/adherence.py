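"""Proportion-of-days-covered (PDC) engine.

Dispensed mass is converted to fractional days of supply via the DDD table.
Coverage follows stockpiling semantics: a dispensation's supply begins on the
day it is dispensed or, if earlier supply is still running, on the day after
that supply is exhausted, and then covers consecutive eligible days at one
DDD per day.  Days spent in hospital do not consume supply (medication is
assumed to be provided by the hospital), so supply is paused during stays and
the PDC denominator for a period is ``days_survived - hospital_days``.
Supply crossing a period boundary is carried as medication stock into the
later period; supply extending beyond death or the end of follow-up is
discarded.

Fractional supply is accumulated along each unbroken chain of coverage and
rounded half-up once per chain; a sub-half-day remainder left when a chain
breaks is dropped.

Two implementations are provided: the interval-arithmetic engine
(:func:`compute_pdc_panel`, used by the pipeline) and a deliberately naive
day-by-day simulation (:func:`pdc_day_grid`) kept as an independent reference
for validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import PRE_PERIOD, _merged_stay_intervals
from .drugs import DRUG_CLASSES, DddTable, classify_atc

logger = logging.getLogger(__name__)

PERIODS = (PRE_PERIOD, 1, 2, 3)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _epoch_days(dates) -> np.ndarray:
    return pd.to_datetime(dates).values.astype("datetime64[D]").astype(np.int64)


@dataclass
class PatientAxis:
    """Eligible-day axis of one patient: survived, non-hospital days.

    ``allowed`` holds epoch-day numbers in increasing order; period ``p``
    occupies compressed positions ``[period_slices[p][0], period_slices[p][1])``.
    """

    allowed: np.ndarray
    period_slices: dict[int, tuple[int, int]]
    period_bounds: dict[int, tuple[int, int]]   # epoch-day [start, end) per period

    @property
    def n(self) -> int:
        return len(self.allowed)


def build_patient_axis(
    periods_pat: pd.DataFrame,
    stay_intervals: list[tuple[pd.Timestamp, pd.Timestamp]],
    supply_runs_in_hospital: bool = False,
) -> PatientAxis:
    """Compressed day axis for one patient from their observation periods."""
    starts = _epoch_days(periods_pat["start"])
    ends = _epoch_days(periods_pat["end"])
    lived = starts + periods_pat["days_survived"].to_numpy(np.int64)
    lo, hi = int(starts.min()), int(ends.max())
    mask = np.zeros(hi - lo, dtype=bool)
    for s, le in zip(starts, lived):
        mask[s - lo : le - lo] = True
    if not supply_runs_in_hospital:
        for a, d in stay_intervals:
            a_, d_ = _epoch_days([a])[0], _epoch_days([d])[0]
            mask[max(a_ - lo, 0) : max(d_ - lo, 0)] = False
    allowed = (lo + np.flatnonzero(mask)).astype(np.int64)
    slices, bounds = {}, {}
    for s, e, p in zip(starts, ends, periods_pat["period_index"]):
        i0 = int(np.searchsorted(allowed, s))
        i1 = int(np.searchsorted(allowed, e))
        slices[int(p)] = (i0, i1)
        bounds[int(p)] = (int(s), int(e))
    return PatientAxis(allowed=allowed, period_slices=slices, period_bounds=bounds)


@dataclass
class CoverageLedger:
    """Coverage of one patient x drug class on the compressed day axis."""

    patient_id: str
    drug_class: str
    chains: list = field(default_factory=list)        # (start_pos, supply, covered)
    members: list = field(default_factory=list)       # per chain: [(pos, supply, disp_period)]
    discarded: float = 0.0


def build_coverage(
    dispensations: pd.DataFrame,
    axis: PatientAxis,
    ddd_table: DddTable,
    patient_id: str = "",
    drug_class: str = "",
) -> CoverageLedger:
    """Run the stockpiling interval arithmetic for one patient x class.

    ``dispensations`` must contain ``dispense_date, atc_code, amount_mg`` for
    the class in question, already restricted to this patient.
    """
    ledger = CoverageLedger(patient_id=patient_id, drug_class=drug_class)
    if len(dispensations) == 0 or axis.n == 0:
        return ledger
    days = _epoch_days(dispensations["dispense_date"])
    order = np.argsort(days, kind="stable")
    supplies = np.array(
        [ddd_table.days_supplied(a, c)
         for a, c in zip(dispensations["amount_mg"], dispensations["atc_code"])]
    )[order]
    days = days[order]

    # period of the dispensation date (for stock attribution)
    def date_period(t: int) -> int:
        for p, (s, e) in axis.period_bounds.items():
            if s <= t < e:
                return p
        return PRE_PERIOD if t < axis.period_bounds[PRE_PERIOD][0] else max(axis.period_bounds)

    chains: list[list] = []     # [start_pos, supply_total]
    members: list[list] = []
    for t, s in zip(days, supplies):
        pos = int(np.searchsorted(axis.allowed, t))
        if pos >= axis.n:
            ledger.discarded += s
            continue
        if chains:
            c0, stot = chains[-1]
            if pos <= c0 + _round_half_up(stot):
                chains[-1][1] = stot + s
                members[-1].append((pos, s, date_period(int(t))))
                continue
            # close previous chain: sub-half-day remainder is dropped
        chains.append([pos, s])
        members.append([(pos, s, date_period(int(t)))])

    for (c0, stot), mem in zip(chains, members):
        r = _round_half_up(stot)
        covered = max(0, min(c0 + r, axis.n) - c0)
        ledger.chains.append((c0, stot, covered))
        ledger.members.append(mem)
        ledger.discarded += max(0.0, stot - covered)
    return ledger


def _ledger_period_stats(ledger: CoverageLedger, axis: PatientAxis):
    """Covered days per period plus carried-stock diagnostics.

    ``stock_in[p]``: covered days inside period p supplied by dispensations
    dated in an earlier period.  ``stock_out[p]``: supply dispensed in or
    before p whose coverage extends past p's end (medication stock held at
    the boundary).  Attribution within a chain is first-in-first-out.
    """
    covered = {p: 0 for p in axis.period_slices}
    stock_in = {p: 0.0 for p in axis.period_slices}
    stock_out = {p: 0.0 for p in axis.period_slices}
    ordered = sorted(axis.period_slices, key=lambda p: axis.period_slices[p][0])
    for (c0, stot, cov), mem in zip(ledger.chains, ledger.members):
        for p in ordered:
            i0, i1 = axis.period_slices[p]
            covered[p] += max(0, min(c0 + cov, i1) - max(c0, i0))
        cum = 0.0
        for pos, s, disp_period in mem:
            u, v = c0 + cum, c0 + min(cum + s, float(cov))
            cum += s
            if v <= u:
                continue
            for p in ordered:
                i0, i1 = axis.period_slices[p]
                if p > disp_period:
                    stock_in[p] += max(0.0, min(v, float(i1)) - max(u, float(i0)))
                if p >= disp_period:
                    stock_out[p] += max(0.0, v - float(i1))
    return covered, stock_in, stock_out


def compute_pdc_panel(
    dispensations: pd.DataFrame,
    periods: pd.DataFrame,
    hospital_stays: pd.DataFrame,
    ddd_table: DddTable | None = None,
    classes: tuple[str, ...] = DRUG_CLASSES,
    supply_runs_in_hospital: bool = False,
    bb_first_year_only: bool = False,
) -> pd.DataFrame:
    """Per patient x drug class x period PDC panel (interval-arithmetic engine).

    Returns columns ``patient_id, drug_class, period_index, covered_days,
    denominator_days, pdc, stock_in_days, stock_out_days``; ``pdc`` is NaN
    where the denominator is zero (row flagged, excluded from modelling).
    """
    ddd_table = ddd_table or DddTable.default()
    disp = dispensations.copy()
    disp["drug_class"] = [classify_atc(c) for c in disp["atc_code"]]
    unknown = disp["drug_class"].isna()
    if unknown.any():
        logger.debug("ignoring %d dispensations outside the four drug classes", unknown.sum())
    disp = disp[~unknown]
    disp["_day"] = _epoch_days(disp["dispense_date"])

    stay_map = _merged_stay_intervals(hospital_stays)
    rows = []
    disp_by_pid = dict(tuple(disp.groupby("patient_id")))
    for pid, per_pat in periods.groupby("patient_id"):
        axis = build_patient_axis(per_pat, stay_map.get(pid, []), supply_runs_in_hospital)
        pdisp = disp_by_pid.get(pid)
        if supply_runs_in_hospital:
            denom = {int(p): int(ds) for p, ds in zip(per_pat["period_index"],
                                                      per_pat["days_survived"])}
        else:
            denom = {
                int(p): int(ds) - int(hd)
                for p, ds, hd in zip(per_pat["period_index"], per_pat["days_survived"],
                                     per_pat["hospital_days"])
            }
        last_lived = int(max(_epoch_days(per_pat["start"])
                             + per_pat["days_survived"].to_numpy(np.int64)))
        died = last_lived < int(_epoch_days(per_pat["end"]).max())
        for cls in classes:
            cdisp = (pdisp[pdisp["drug_class"] == cls]
                     if pdisp is not None else disp.iloc[0:0])
            if len(cdisp) > 0 and died:
                after_death = cdisp["_day"] >= last_lived
                if after_death.any():
                    logger.warning(
                        "patient %s: dropping %d %s dispensations dated after death",
                        pid, int(after_death.sum()), cls)
                    cdisp = cdisp[~after_death]
            ledger = build_coverage(cdisp, axis, ddd_table, pid, cls)
            covered, stock_in, stock_out = _ledger_period_stats(ledger, axis)
            for p in sorted(axis.period_slices):
                d = denom[p]
                cov = covered.get(p, 0)
                rows.append(
                    {"patient_id": pid, "drug_class": cls, "period_index": p,
                     "covered_days": cov, "denominator_days": d,
                     "pdc": cov / d if d > 0 else np.nan,
                     "stock_in_days": stock_in.get(p, 0.0),
                     "stock_out_days": stock_out.get(p, 0.0)}
                )
    panel = pd.DataFrame(rows)
    if bb_first_year_only:
        panel = apply_class_rules(panel, bb_first_year_only=True)
    return panel


def apply_class_rules(panel: pd.DataFrame, bb_first_year_only: bool = False) -> pd.DataFrame:
    """Class-specific PDC post-processing.

    With ``bb_first_year_only`` the beta-blocker PDC of follow-up years 2 and 3
    is replaced by the year-1 value (guidelines recommend beta-blockers only
    for the first one to two years after the infarction, so adherence is then
    judged by the first-year PDC and the within-person deviation is zero).
    """
    if not bb_first_year_only:
        return panel
    out = panel.copy()
    bb = out["drug_class"] == "BB"
    y1 = out[bb & (out["period_index"] == 1)].set_index("patient_id")["pdc"]
    later = bb & out["period_index"].isin([2, 3])
    out.loc[later, "pdc"] = out.loc[later, "patient_id"].map(y1).to_numpy()
    return out


def pdc_day_grid(
    dispensations: pd.DataFrame,
    periods: pd.DataFrame,
    hospital_stays: pd.DataFrame,
    ddd_table: DddTable | None = None,
    classes: tuple[str, ...] = DRUG_CLASSES,
    supply_runs_in_hospital: bool = False,
) -> pd.DataFrame:
    """Naive day-by-day PDC simulation (validation reference).

    Walks every calendar day of every patient keeping a running medication
    stock: supply dispensed on a day is added to the stock; on each eligible
    (survived, non-hospital) day a stock of at least half a day covers the day
    and one day of supply is consumed; a stock below half a day is forfeited.
    Hospital days neither consume nor forfeit stock.
    """
    ddd_table = ddd_table or DddTable.default()
    disp = dispensations.copy()
    disp["drug_class"] = [classify_atc(c) for c in disp["atc_code"]]
    disp = disp[disp["drug_class"].notna()]
    disp["_day"] = _epoch_days(disp["dispense_date"])
    disp["_supply"] = [ddd_table.days_supplied(a, c)
                       for a, c in zip(disp["amount_mg"], disp["atc_code"])]
    stay_map = _merged_stay_intervals(hospital_stays)

    rows = []
    disp_by_pid = dict(tuple(disp.groupby("patient_id")))
    for pid, per_pat in periods.groupby("patient_id"):
        starts = _epoch_days(per_pat["start"])
        ends = _epoch_days(per_pat["end"])
        lived = starts + per_pat["days_survived"].to_numpy(np.int64)
        lo, hi = int(starts.min()), int(ends.max())
        span = hi - lo
        survived = np.zeros(span, dtype=bool)
        for s, le in zip(starts, lived):
            survived[s - lo : le - lo] = True
        hospital = np.zeros(span, dtype=bool)
        for a, d in stay_map.get(pid, ()):
            a_, d_ = _epoch_days([a])[0], _epoch_days([d])[0]
            hospital[max(a_ - lo, 0) : max(min(d_ - lo, span), 0)] = True
        eligible = survived if supply_runs_in_hospital else (survived & ~hospital)
        period_of = np.full(span, -99, dtype=int)
        for s, e, p in zip(starts, ends, per_pat["period_index"]):
            period_of[s - lo : e - lo] = int(p)
        last_lived = int(lived.max())
        pdisp = disp_by_pid.get(pid)
        for cls in classes:
            add = np.zeros(span)
            if pdisp is not None:
                for t, s in zip(pdisp.loc[pdisp["drug_class"] == cls, "_day"],
                                pdisp.loc[pdisp["drug_class"] == cls, "_supply"]):
                    if t >= last_lived:
                        continue  # dispensed after death / past follow-up: no coverage
                    add[min(max(int(t) - lo, 0), span - 1)] += s
            covered = {int(p): 0 for p in per_pat["period_index"]}
            denom = {int(p): 0 for p in per_pat["period_index"]}
            stock = 0.0
            for i in range(span):
                stock += add[i]
                if not survived[i]:
                    continue
                if not eligible[i]:
                    continue  # hospital day: stock frozen
                p = int(period_of[i])
                denom[p] += 1
                if stock >= 0.5:
                    covered[p] += 1
                    stock -= 1.0
                else:
                    stock = 0.0
            for p in sorted(covered):
                d = denom[p]
                rows.append({"patient_id": pid, "drug_class": cls, "period_index": p,
                             "covered_days": covered[p], "denominator_days": d,
                             "pdc": covered[p] / d if d > 0 else np.nan})
    return pd.DataFrame(rows)
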