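"""Unit-cost tables: wage rates, per-diem rates, per-event charges, caps,
and the fringe-benefit and inflation adjustments applied before costing.

All wages enter in the dollars of ``wage_year`` (2015 by default, the
source year of the occupational wage data), receive a multiplicative
fringe-benefit load, and are then inflated to ``target_year`` (2019)
with a CPI-style annual index. Fringe and inflation commute, so the
order is presentational; this module applies fringe first.

Money values are kept unrounded throughout; rounding to cents happens
only when a report is rendered (see :mod:`copecba.payment`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError, ParameterError


def hourly_rate_with_fringe(base_wage: float, fringe_rate: float) -> float:
    """Load a base hourly wage with a fringe-benefit rate.

    Fringe benefits (payroll taxes, insurance, paid leave) are modeled as
    a flat proportional add-on: ``base_wage * (1 + fringe_rate)``. The
    default load used throughout the package is 31.3%.
    """
    if base_wage < 0 or fringe_rate < 0:
        raise ParameterError(
            f"wage and fringe rate must be non-negative, got "
            f"base_wage={base_wage}, fringe_rate={fringe_rate}"
        )
    return base_wage * (1.0 + fringe_rate)


def inflate(amount: float, from_year: int, to_year: int, index: dict[int, float]) -> float:
    """Convert ``amount`` from ``from_year`` dollars to ``to_year`` dollars.

    Uses the ratio of the annual price index: ``amount * index[to] / index[from]``.
    Identity when the years coincide.
    """
    for year in (from_year, to_year):
        if year not in index:
            raise ConfigError(f"inflation index has no entry for year {year}")
    if from_year == to_year:
        return amount
    return amount * index[to_year] / index[from_year]


@dataclass
class UnitCostConfig:
    """All rates, caps and conversion factors the costing rules need.

    Scalar defaults are the study's published values; the lookup tables
    (occupation wages, facility rates, diagnosis charges, procedure costs,
    drug prices, equipment prices) ship with illustrative defaults and are
    meant to be replaced with jurisdiction-specific tables.
    """

    fringe_rate: float = 0.313
    cost_to_charge_divisor: float = 3.4
    mileage_rate: float = 0.58            # USD/mile
    visiting_nurse_minutes: float = 30.0  # minutes/visit
    hha_minutes: float = 60.0             # minutes/visit
    respite_hha_hours_per_day: float = 8.0
    adult_day_rate: float = 12.80         # USD/hour, already 2019
    adult_day_hours_per_day: float = 8.0
    meal_cost: float = 11.92              # USD, already 2019
    transport_fare: float = 1.50          # USD/round-trip, wage-year dollars
    social_worker_wage: float = 31.09     # USD/h, wage-year dollars
    social_worker_minutes: float = 60.0
    caregiving_cap_hours_per_day: float = 16.0
    caregiving_weeks_per_period: float = 52.0
    rehab_per_diem: float = 450.00        # USD/day, wage-year dollars
    hha_wage: float = 10.87               # USD/h, wage-year dollars
    visiting_nurse_wage: float = 34.14    # USD/h, wage-year dollars
    cm_cost_month: float = 108.10         # USD/month, care management, 2019
    wage_year: int = 2015
    target_year: int = 2019
    occupation_wage_table: dict[str, float] = field(default_factory=dict)
    inflation_index: dict[int, float] = field(default_factory=dict)
    nursing_home_daily_rates: dict[str, float] = field(default_factory=dict)
    charge_table: dict[str, float] = field(default_factory=dict)
    cpt_cost_table: dict[str, float] = field(default_factory=dict)
    wac_table: dict[str, float] = field(default_factory=dict)
    dme_table: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fringe_rate < 0:
            raise ConfigError("fringe_rate must be >= 0")
        if self.cost_to_charge_divisor <= 0:
            raise ConfigError("cost_to_charge_divisor must be > 0")
        if not 0 < self.caregiving_cap_hours_per_day <= 24:
            raise ConfigError("caregiving_cap_hours_per_day must be in (0, 24]")
        scalar_rates = (
            "mileage_rate", "visiting_nurse_minutes", "hha_minutes",
            "respite_hha_hours_per_day", "adult_day_rate",
            "adult_day_hours_per_day", "meal_cost", "transport_fare",
            "social_worker_wage", "social_worker_minutes",
            "caregiving_weeks_per_period", "rehab_per_diem", "hha_wage",
            "visiting_nurse_wage", "cm_cost_month",
        )
        for name in scalar_rates:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for table_name in ("occupation_wage_table", "nursing_home_daily_rates",
                           "charge_table", "cpt_cost_table", "wac_table",
                           "dme_table"):
            table = getattr(self, table_name)
            for key, rate in table.items():
                if rate < 0:
                    raise ConfigError(f"{table_name}[{key!r}] must be >= 0")
        if self.inflation_index:
            for year in (self.wage_year, self.target_year):
                if year not in self.inflation_index:
                    raise ConfigError(
                        f"inflation index has no entry for year {year}"
                    )

    # --- derived rates ------------------------------------------------

    def inflation_factor(self, from_year: int | None = None) -> float:
        from_year = self.wage_year if from_year is None else from_year
        return inflate(1.0, from_year, self.target_year, self.inflation_index)

    def wage_2019(self, base_wage: float) -> float:
        """Wage-year hourly wage -> fringe-loaded target-year wage."""
        return inflate(
            hourly_rate_with_fringe(base_wage, self.fringe_rate),
            self.wage_year, self.target_year, self.inflation_index,
        )

    def occupation_wage_2019(self, occupation: str | None) -> float:
        """Fringe-loaded, inflated wage for an occupation; falls back to
        the home-health-aide wage when the occupation is missing or not
        in the table (the replacement-cost convention for unpaid care)."""
        if occupation and occupation in self.occupation_wage_table:
            return self.wage_2019(self.occupation_wage_table[occupation])
        return self.wage_2019(self.hha_wage)

    # --- serialization ------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "UnitCostConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.inflation_index = {int(k): float(v) for k, v in cfg.inflation_index.items()}
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "UnitCostConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        """Serialize in declaration order; stable, so a loaded default
        config round-trips byte-identically."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=False, default_flow_style=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def default(cls) -> "UnitCostConfig":
        """The packaged default table (study values plus illustrative lookups)."""
        ref = importlib.resources.files("copecba").joinpath("data/default_costs.yaml")
        with importlib.resources.as_file(ref) as path:
            return cls.from_yaml(path)


def load_rate_csv(path: str | Path) -> dict[str, float]:
    """Read a two-column (key, rate) CSV into a lookup table."""
    import pandas as pd

    frame = pd.read_csv(path)
    if frame.shape[1] != 2:
        raise ConfigError(f"{path}: rate tables must have exactly two columns")
    keys = frame.iloc[:, 0].astype(str)
    rates = frame.iloc[:, 1].astype(float)
    return dict(zip(keys, rates))
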