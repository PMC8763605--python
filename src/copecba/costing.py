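"""Microcosting engine: utilization records -> per-dyad cost lines in 2019 USD.

Each utilization record is one quantity of one service for one dyad in one
period (the year before randomization, or the year after). Category-specific
rules convert quantities to cost:

* hospital charges are deflated by a cost-to-charge ratio,
* institutional days are multiplied by per-diem rates,
* timed visits and caregiver hours are valued at fringe-loaded,
  inflation-adjusted replacement wages,
* simple units (meals, bus trips, doses, miles, equipment) are multiplied
  by their unit rate.

Records carrying the attribute ``precosted`` have their quantity
interpreted directly as 2019 USD (unit rate 1); intervention-delivery
lines costed upstream from accounting records, and synthetic cohorts,
enter this way.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .categories import (
    ALL_CATEGORIES,
    ATTRIBUTE_REQUIRED,
    PRECOSTED,
    report_category,
)
from .config import UnitCostConfig, inflate
from .errors import CostingError, DataError, ParameterError

RECORD_COLUMNS = ["dyad_id", "arm", "period", "category", "quantity", "attribute"]
COST_COLUMNS = ["dyad_id", "arm", "period", "report_category", "cost_usd2019"]


@dataclass(frozen=True)
class UtilizationRecord:
    dyad_id: str
    arm: str
    period: str
    category: str
    quantity: float
    attribute: str | None = None

    def __post_init__(self) -> None:
        if self.category not in ALL_CATEGORIES:
            raise DataError(f"unknown cost category {self.category!r}")
        if self.arm not in ("cope", "usual_care"):
            raise DataError(f"unknown arm {self.arm!r}")
        if self.period not in ("baseline", "month12"):
            raise DataError(f"unknown period {self.period!r}")
        if self.quantity < 0:
            raise DataError(f"negative quantity for dyad {self.dyad_id}")
        if (self.category in ATTRIBUTE_REQUIRED and not self.attribute):
            raise DataError(
                f"category {self.category!r} requires an attribute "
                f"(dyad {self.dyad_id})"
            )


# --- elementary costing rules ----------------------------------------------


def cost_inpatient_or_ed(mean_charge: float, divisor: float) -> float:
    """Hospital billed charge -> approximate economic cost via a
    cost-to-charge ratio (divide by 3.4 under the default)."""
    if mean_charge < 0 or divisor <= 0:
        raise ParameterError("charge must be >= 0 and divisor > 0")
    return mean_charge / divisor


def cost_nursing_home(days: float, stay_type: str, rate: float) -> float:
    """Institutional days times a daily rate. ``rate`` is the facility's
    published daily rate for long-term stays, or the (already inflated)
    federal per-diem for rehabilitation stays."""
    if days < 0 or rate < 0:
        raise ParameterError("days and rate must be >= 0")
    if stay_type not in ("long_term", "rehab"):
        raise ParameterError(f"unknown stay type {stay_type!r}")
    return days * rate

def cost_timed_visit(visits: float, minutes_per_visit: float, wage: float) -> float:
    """Visits of fixed duration valued at an hourly wage (already
    fringe-loaded and inflated)."""
    if visits < 0 or minutes_per_visit < 0 or wage < 0:
        raise ParameterError("visits, minutes and wage must be >= 0")
    return visits * (minutes_per_visit / 60.0) * wage

def cost_respite(days: float, hha_wage: float, hours_per_day: float) -> float:
    """Overnight respite proxied as home-health-aide hours per facility day."""
    if days < 0 or hha_wage < 0 or hours_per_day < 0:
        raise ParameterError("inputs must be >= 0")
    return days * hours_per_day * hha_wage

def cost_simple_units(quantity: float, unit_rate: float) -> float:
    if quantity < 0 or unit_rate < 0:
        raise ParameterError("quantity and unit rate must be >= 0")
    return quantity * unit_rate

def cost_adult_day(days: float, rate: float, hours_per_day: float) -> float:
    if days < 0 or rate < 0 or hours_per_day < 0:
        raise ParameterError("inputs must be >= 0")
    return days * hours_per_day * rate


def cost_caregiver_time(
    weekly_hours: float,
    weeks: float,
    occupation: str | None,
    employed: bool,
    config: UnitCostConfig,
) -> float:
    """Value caregiver supervision/assistance time at a replacement wage.

    Weekly hours are capped at ``caregiving_cap_hours_per_day`` x 7 (the
    cap is stated per day but hours are reported per week). Employed
    caregivers with a known occupation are valued at their occupational
    wage; otherwise the home-health-aide wage applies. Both wages carry
    fringe benefits and inflation.
    """
    if weekly_hours < 0 or weeks < 0:
        raise ParameterError("hours and weeks must be >= 0")
    cap = config.caregiving_cap_hours_per_day * 7.0
    hours = min(weekly_hours, cap) * weeks
    if employed and occupation:
        wage = config.occupation_wage_2019(occupation)
    else:
        wage = config.wage_2019(config.hha_wage)
    return hours * wage


# --- per-record dispatch -----------------------------------------------------


def _lookup(table: dict, key: str, table_name: str) -> float:
    if key not in table:
        raise CostingError(f"{table_name} has no entry for {key!r}")
    return table[key]


def cost_record(record: UtilizationRecord, config: UnitCostConfig) -> float:
    """Cost one utilization record in 2019 USD."""
    cat, qty, attr = record.category, record.quantity, record.attribute
    if attr == PRECOSTED:
        return qty  # already 2019 USD

    if cat in ("formal_staff_training", "screening", "ot_apn_client_time",
               "ot_apn_outside_work", "travel_time", "debriefing",
               "supplies", "lab_testing"):
        # delivery lines are costed upstream from accounting records and
        # arrive as dollar quantities
        return qty
    if cat == "mileage":
        return cost_simple_units(qty, config.mileage_rate)
    if cat == "care_plan":
        # quantity = months of care-management service
        return cost_simple_units(qty, config.cm_cost_month)
    if cat == "nursing_home_long_term":
        rate = _lookup(config.nursing_home_daily_rates, attr, "nursing_home_daily_rates")
        return cost_nursing_home(qty, "long_term", rate)
    if cat == "nursing_home_rehab":
        rate = inflate(config.rehab_per_diem, config.wage_year,
                       config.target_year, config.inflation_index)
        return cost_nursing_home(qty, "rehab", rate)
    if cat == "respite":
        return cost_respite(qty, config.wage_2019(config.hha_wage),
                            config.respite_hha_hours_per_day)
    if cat in ("inpatient", "ed"):
        charge = _lookup(config.charge_table, attr, "charge_table")
        return qty * cost_inpatient_or_ed(charge, config.cost_to_charge_divisor)
    if cat == "outpatient":
        rate = _lookup(config.cpt_cost_table, attr, "cpt_cost_table")
        rate = inflate(rate, config.wage_year, config.target_year,
                       config.inflation_index)
        return cost_simple_units(qty, rate)
    if cat == "medications":
        rate = _lookup(config.wac_table, attr, "wac_table")
        return cost_simple_units(qty, rate)
    if cat == "dme":
        rate = _lookup(config.dme_table, attr, "dme_table")
        return cost_simple_units(qty, rate)
    if cat == "visiting_nurse":
        return cost_timed_visit(qty, config.visiting_nurse_minutes,
                                config.wage_2019(config.visiting_nurse_wage))
    if cat == "hha":
        return cost_timed_visit(qty, config.hha_minutes,
                                config.wage_2019(config.hha_wage))
    if cat == "social_worker":
        return cost_timed_visit(qty, config.social_worker_minutes,
                                config.wage_2019(config.social_worker_wage))
    if cat == "meals":
        return cost_simple_units(qty, config.meal_cost)
    if cat == "transportation":
        fare = inflate(config.transport_fare, config.wage_year,
                       config.target_year, config.inflation_index)
        return cost_simple_units(qty, fare)
    if cat == "adult_day":
        return cost_adult_day(qty, config.adult_day_rate,
                              config.adult_day_hours_per_day)
    if cat == "caregiver_time":
        # quantity = weekly hours; occupation key in attribute (empty ->
        # unemployed/unknown, valued at the HHA replacement wage)
        return cost_caregiver_time(qty, config.caregiving_weeks_per_period,
                                   attr, bool(attr), config)
    raise CostingError(f"no costing rule for category {cat!r}")


def aggregate_costs(
    records,
    config: UnitCostConfig,
) -> pd.DataFrame:
    """Cost a batch of records into report-row cost lines.

    Accepts a list of :class:`UtilizationRecord` or a DataFrame with the
    utilization CSV columns. Every record yields exactly one cost line, so
    the total is conserved; all failing records are collected and reported
    together in one :class:`CostingError`.
    """
    if isinstance(records, pd.DataFrame):
        records = records_from_frame(records)
    rows, failures = [], []
    for rec in records:
        try:
            cost = cost_record(rec, config)
        except (CostingError, ParameterError) as exc:
            failures.append((rec.dyad_id, f"{rec.category}: {exc}"))
            continue
        rows.append((rec.dyad_id, rec.arm, rec.period,
                     report_category(rec.category), cost))
    if failures:
        listing = "; ".join(f"dyad {d}: {m}" for d, m in failures[:20])
        raise CostingError(
            f"{len(failures)} record(s) could not be costed: {listing}",
            failures=failures,
        )
    return pd.DataFrame(rows, columns=COST_COLUMNS)


# --- CSV I/O -----------------------------------------------------------------


def records_from_frame(frame: pd.DataFrame) -> list[UtilizationRecord]:
    missing = set(RECORD_COLUMNS[:5]) - set(frame.columns)
    if missing:
        raise DataError(f"utilization table missing columns: {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        attr = getattr(row, "attribute", None)
        if pd.isna(attr) or attr == "":
            attr = None
        out.append(UtilizationRecord(
            dyad_id=str(row.dyad_id), arm=row.arm, period=row.period,
            category=row.category, quantity=float(row.quantity),
            attribute=attr,
        ))
    return out


def read_utilization_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"dyad_id": str, "attribute": str})


def write_cost_lines(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False, float_format="%.17g")


def read_cost_lines(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"dyad_id": str})
    missing = set(COST_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"cost-line table missing columns: {sorted(missing)}")
    return frame
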