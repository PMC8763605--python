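"""HCBS payment-model calculator and cost-sharing feasibility check.

The payment model asks what share of a beneficiary's annual
home-and-community-based-services (HCBS) care-plan allowance the program
would consume if covered as a benefit. The program is delivered over 4
months of a 12-month benefit year; care-management (CM) services continue
all year. With a flat agency overhead rate:

    monthly program cost  = total delivery cost / delivery months
    with overhead         = monthly cost x (1 + overhead rate)
    annual program cost   = with-overhead x delivery months
                            + CM cost/month x 12
    share consumed        = annual program cost / (monthly limit x 12)

All intermediate values stay unrounded; display rounding is half-up
(that is how $528.0125/month turns into the reported $739.22 after
overhead rather than $739.21).

The cost-sharing check compares the copayment a participant would pay
per month against the program's maximum cost-share (a percentage of the
monthly spending limit; 9% for state-funded benefit category 2, none for
the Medicaid-waiver category 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import ParameterError
from .reference import DELIVERY_COMPONENTS

#: monthly care-plan spending limits (USD) by benefit category
CATEGORY_LIMITS = {2: 3143.0, 3: 6286.0}
#: participant cost-sharing rate by benefit category
CATEGORY_SHARE_RATES = {1: 0.09, 2: 0.09, 3: 0.0}


def round_half_up(value: float, digits: int = 2) -> float:
    """Decimal round-half-up (report rendering only; never used in math)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PaymentModelParams:
    care_plan_limit_month: float = CATEGORY_LIMITS[2]
    overhead_rate: float = 0.40
    cm_cost_month: float = 108.10
    delivery_months: int = 4
    benefit_year_months: int = 12
    cope_total_delivery_cost: float = field(
        default_factory=lambda: sum(DELIVERY_COMPONENTS.values())
    )

    def __post_init__(self) -> None:
        for name in ("care_plan_limit_month", "overhead_rate", "cm_cost_month",
                     "delivery_months", "benefit_year_months",
                     "cope_total_delivery_cost"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.delivery_months > self.benefit_year_months:
            raise ParameterError("delivery_months must be <= benefit_year_months")

    @classmethod
    def for_category(cls, category: int, **overrides) -> "PaymentModelParams":
        if category not in CATEGORY_LIMITS:
            raise ParameterError(f"no care-plan limit for category {category}")
        overrides.setdefault("care_plan_limit_month", CATEGORY_LIMITS[category])
        return cls(**overrides)


@dataclass
class CostShareParams:
    share_rate: float = CATEGORY_SHARE_RATES[2]
    copay_per_session: float = 25.0
    sessions_per_month: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.share_rate <= 1.0:
            raise ParameterError("share_rate must be in [0, 1]")
        if self.copay_per_session < 0 or self.sessions_per_month < 0:
            raise ParameterError("copay and sessions must be >= 0")


# --- operations --------------------------------------------------------------


def monthly_cope_cost(total_delivery_cost: float, delivery_months: int) -> float:
    """Per-dyad delivery cost spread over the delivery period, unrounded."""
    if delivery_months < 1:
        raise ParameterError("delivery_months must be >= 1")
    if total_delivery_cost < 0:
        raise ParameterError("total_delivery_cost must be >= 0")
    return total_delivery_cost / delivery_months


def add_overhead(monthly_cost: float, overhead_rate: float) -> float:
    if overhead_rate < 0 or monthly_cost < 0:
        raise ParameterError("cost and overhead rate must be >= 0")
    return monthly_cost * (1.0 + overhead_rate)


def percent_consumed(params: PaymentModelParams) -> tuple[float, float]:
    """Share of the annual care-plan allowance consumed by the program.

    Returns ``(share, annual_cost)`` where share is a proportion and
    annual_cost is the with-overhead program cost over its delivery
    months plus a full year of CM services.
    """
    if params.care_plan_limit_month <= 0:
        raise ParameterError("care_plan_limit_month must be > 0")
    monthly = monthly_cope_cost(params.cope_total_delivery_cost,
                                params.delivery_months)
    with_overhead = add_overhead(monthly, params.overhead_rate)
    annual_cost = (with_overhead * params.delivery_months
                   + params.cm_cost_month * params.benefit_year_months)
    annual_limit = params.care_plan_limit_month * params.benefit_year_months
    return annual_cost / annual_limit, annual_cost


def max_cost_share(limit_month: float, share_rate: float) -> float:
    """Maximum monthly amount a participant can be asked to contribute."""
    if limit_month < 0 or not 0.0 <= share_rate <= 1.0:
        raise ParameterError("limit must be >= 0 and share_rate in [0, 1]")
    return limit_month * share_rate


def copay_feasibility(
    cost_share: CostShareParams, limit_month: float
) -> tuple[float, bool]:
    """Monthly copayment and whether it fits under the cost-share ceiling."""
    monthly_copay = cost_share.copay_per_session * cost_share.sessions_per_month
    ceiling = max_cost_share(limit_month, cost_share.share_rate)
    return monthly_copay, monthly_copay <= ceiling


def wtp_summary(
    responses: pd.DataFrame, threshold: float = 25.0
) -> tuple[float, dict[int, float]]:
    """Median willingness to pay per session, and per benefit category the
    fraction of caregivers willing to pay at least ``threshold``."""
    if len(responses) == 0:
        raise ParameterError("no WTP responses")
    wtp = responses["wtp_per_session"].astype(float)
    median = float(np.median(wtp))
    fractions = {
        int(cat): float((grp["wtp_per_session"] >= threshold).mean())
        for cat, grp in responses.groupby("chcpe_category")
    }
    return median, fractions


def payment_table(
    categories=(2, 3), **overrides
) -> pd.DataFrame:
    """Payment-model summary, one row per benefit category, display-rounded."""
    rows = []
    for cat in categories:
        params = PaymentModelParams.for_category(cat, **overrides)
        monthly = monthly_cope_cost(params.cope_total_delivery_cost,
                                    params.delivery_months)
        with_overhead = add_overhead(monthly, params.overhead_rate)
        share, annual = percent_consumed(params)
        rows.append({
            "chcpe_category": cat,
            "care_plan_limit_month": round_half_up(params.care_plan_limit_month),
            "cope_cost_month": round_half_up(monthly),
            "cope_admin_cost_month": round_half_up(with_overhead),
            "cm_cost_month": round_half_up(params.cm_cost_month),
            "annual_cost_with_cm": round_half_up(annual, 0),
            "pct_consumed": round_half_up(100.0 * share),
        })
    return pd.DataFrame(rows)
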