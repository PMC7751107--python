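"""Cost aggregation: line items -> per-patient per-year category totals.

Costs fall into five categories (ambulatory, medication, hospitalization,
rehabilitation, remedial and aid products).  Each line item is inflated to
reference-year euros using a calendar-year -> cumulative-factor table and
summed within patient x observation period x category; the total is the sum
of the five categories.  Items dated outside every observation period are
dropped (with a logged count) — in particular items after death, which a
well-formed claims extract should not contain.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COST_CATEGORIES = ("ambulatory", "medication", "hospitalization",
                   "rehabilitation", "remedial_aid")


class CostInputError(ValueError):
    """Raised for unknown categories or missing inflation years."""


def inflation_table(factors: dict[int, float] | None, reference_year: int) -> dict[int, float]:
    """Normalize an inflation map; the reference year itself has factor 1."""
    table = dict(factors or {})
    table.setdefault(reference_year, 1.0)
    if abs(table[reference_year] - 1.0) > 1e-12:
        raise CostInputError(
            f"inflation factor of reference year {reference_year} must be 1, "
            f"got {table[reference_year]}")
    return table


def aggregate_costs(
    cost_items: pd.DataFrame,
    periods: pd.DataFrame,
    inflation: dict[int, float] | None = None,
    reference_year: int = 2014,
    followup_only: bool = True,
) -> pd.DataFrame:
    """Aggregate cost line items into a patient x period cost panel.

    ``cost_items`` columns: ``patient_id, service_date, category, amount_eur``.
    Returns one row per patient x period with one column per category plus
    ``total`` (reference-year euros).
    """
    items = cost_items.copy()
    bad = ~items["category"].isin(COST_CATEGORIES)
    if bad.any():
        raise CostInputError(
            f"unknown cost categories: {sorted(items.loc[bad, 'category'].unique())}")
    items["service_date"] = pd.to_datetime(items["service_date"], format="ISO8601")
    table = inflation_table(inflation, reference_year)
    years = items["service_date"].dt.year
    missing = sorted(set(years.unique()) - set(table))
    if inflation is not None and missing:
        raise CostInputError(f"inflation table missing years {missing}")
    factor = years.map(lambda y: table.get(y, 1.0))
    items["amount_adj"] = items["amount_eur"] * factor

    per = periods.copy()
    if followup_only:
        per = per[per["period_index"] > 0]
    per["start"] = pd.to_datetime(per["start"])
    # survived span: items after death do not belong to any period
    per["lived_end"] = per["start"] + pd.to_timedelta(per["days_survived"], unit="D")

    items = items.reset_index(drop=True).reset_index(names="_item")
    merged = items.merge(per[["patient_id", "period_index", "start", "lived_end"]],
                         on="patient_id", how="left")
    inside = (merged["service_date"] >= merged["start"]) & \
             (merged["service_date"] < merged["lived_end"])
    # periods are disjoint, so an item matches at most one period
    matched = merged[inside]
    n_dropped = len(items) - matched["_item"].nunique()
    if n_dropped:
        logger.info("dropped %d cost items outside any observation period", n_dropped)

    agg = (matched.groupby(["patient_id", "period_index", "category"], observed=True)
           ["amount_adj"].sum().unstack("category"))
    # complete the panel: every patient x period, every category
    full_index = pd.MultiIndex.from_frame(per[["patient_id", "period_index"]])
    agg = agg.reindex(full_index).reindex(columns=list(COST_CATEGORIES)).fillna(0.0)
    agg["total"] = agg[list(COST_CATEGORIES)].sum(axis=1)
    return agg.reset_index()


def category_model_inputs(panel: pd.DataFrame, category: str = "total") -> pd.Series:
    """Response vector for one category (or ``total``), aligned to the panel rows."""
    if category != "total" and category not in COST_CATEGORIES:
        raise CostInputError(f"unknown category {category!r}; "
                             f"choose from {('total',) + COST_CATEGORIES}")
    return panel[category]
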