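"""Synthetic two-arm dyad cohort calibrated to the published cost means.

The generator emulates the trial's cost structure — 130 COPE and 120
usual-care dyads, each observed for a baseline year and a follow-up year —
so the difference-in-difference pipeline can be exercised end-to-end
without access to per-dyad trial records.

Per dyad, period and report row the cost is drawn as a zero-inflated
lognormal: ``Bernoulli(1 - p0) x Lognormal(mu, sigma)`` with ``mu`` chosen
so the unconditional expectation equals the published group mean. Only the
group means are published; the zero-inflation probabilities and the
coefficient of variation of positive costs are stated assumptions chosen
to mimic right-skewed utilization data in which institutional stays are
rare and expensive. Baseline and follow-up positive draws share a Gaussian
copula (default correlation 0.3) because the variance of a within-dyad
change depends on that correlation.

Intervention-delivery rows other than the care plan are deterministic
program costs and are emitted as constants; they appear only in the COPE
arm at month 12 (eligibility screening, and a trace of assessment
materials, also appear under usual care, mirroring the published table).

Costs are emitted as pre-costed utilization records (attribute
``precosted``, quantity in 2019 USD), the same dialect the costing engine
accepts for delivery lines costed upstream from accounting records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import (
    DELIVERY_ROWS,
    PRECOSTED,
    REPORT_ROWS,
)
from .errors import ParameterError
from .config import UnitCostConfig
from .reference import PUBLISHED_MEANS

#: delivery rows emitted as per-dyad constants (known program costs)
CONSTANT_ROWS = tuple(r for r in DELIVERY_ROWS if r != "care_plan")

#: report row -> utilization category used when emitting records
_EMIT_CATEGORY = {r: r for r in REPORT_ROWS}
_EMIT_CATEGORY["nursing_home"] = "nursing_home_long_term"

#: assumed probability that a dyad incurs zero cost in a category-period
DEFAULT_ZERO_PROBABILITY: dict[str, float] = {
    "care_plan": 0.0,
    "nursing_home": 0.90,
    "respite": 0.95,
    "inpatient": 0.70,
    "ed": 0.60,
    "outpatient": 0.20,
    "medications": 0.10,
    "dme": 0.80,
    "visiting_nurse": 0.85,
    "hha": 0.80,
    "social_worker": 0.90,
    "meals": 0.85,
    "transportation": 0.80,
    "adult_day": 0.85,
    "caregiver_time": 0.05,
}

#: assumed coefficient of variation of positive costs
DEFAULT_CV: dict[str, float] = {"care_plan": 0.3}
DEFAULT_CV_OTHER = 2.0

WTP_SUPPORT = (0.0, 10.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0)
#: per-session willingness-to-pay masses by benefit category, chosen so the
#: median is $50/session and the share willing to pay >= $25 is 84% in
#: category 2 (9% cost sharing) and 75% in category 3 (no cost sharing)
WTP_PROBS = {
    1: (0.10, 0.06, 0.20, 0.34, 0.12, 0.10, 0.05, 0.03),
    2: (0.10, 0.06, 0.20, 0.34, 0.12, 0.10, 0.05, 0.03),
    3: (0.15, 0.10, 0.20, 0.30, 0.10, 0.08, 0.04, 0.03),
}


@dataclass
class CohortParams:
    """Study conditions for the synthetic cohort."""

    n_cope: int = 130
    n_usual: int = 120
    mean_targets: dict = field(
        default_factory=lambda: {a: dict(PUBLISHED_MEANS[a]) for a in PUBLISHED_MEANS}
    )
    zero_probability: dict = field(
        default_factory=lambda: dict(DEFAULT_ZERO_PROBABILITY)
    )
    cv: dict = field(default_factory=lambda: dict(DEFAULT_CV))
    cv_default: float = DEFAULT_CV_OTHER
    within_dyad_corr: float = 0.3
    chcpe_category_probs: dict = field(
        default_factory=lambda: {1: 0.012, 2: 0.30, 3: 0.688}
    )
    wtp_support: tuple = WTP_SUPPORT
    wtp_probs: dict = field(default_factory=lambda: {k: v for k, v in WTP_PROBS.items()})
    ot_visits: int = 12  # 10 OT sessions + APN visit + APN call
    seed: int = 20190416

    def __post_init__(self) -> None:
        if self.n_cope <= 0 or self.n_usual <= 0:
            raise ParameterError("group sizes must be positive")
        if not -1.0 < self.within_dyad_corr < 1.0:
            raise ParameterError("within_dyad_corr must be in (-1, 1)")
        total = sum(self.chcpe_category_probs.values())
        if abs(total - 1.0) > 1e-9 or any(
            p < 0 for p in self.chcpe_category_probs.values()
        ):
            raise ParameterError("chcpe_category_probs must be a distribution")
        if not self.wtp_support:
            raise ParameterError("wtp_support must be non-empty")
        if any(not 0 <= w <= 200 for w in self.wtp_support):
            raise ParameterError("wtp_support must lie in [0, 200]")
        for cat, probs in self.wtp_probs.items():
            if len(probs) != len(self.wtp_support) or abs(sum(probs) - 1.0) > 1e-9:
                raise ParameterError(f"wtp_probs[{cat}] must match the support")
        for arm, rows in self.mean_targets.items():
            for row, (bl, m12) in rows.items():
                if bl < 0 or m12 < 0:
                    raise ParameterError(f"negative mean target for {arm}/{row}")
                p0 = self.zero_probability.get(row, 0.0)
                if p0 >= 1.0 and (bl > 0 or m12 > 0):
                    raise ParameterError(
                        f"infeasible calibration for {arm}/{row}: "
                        f"positive target with zero_probability = 1"
                    )

    def cv_for(self, row: str) -> float:
        return self.cv.get(row, self.cv_default)


def _lognormal_mu(target: float, p0: float, sigma2: float) -> float:
    """Location so that (1 - p0) * E[lognormal] hits the target mean."""
    return math.log(target / (1.0 - p0)) - sigma2 / 2.0


def _draw_row(
    rng: np.random.Generator,
    targets: tuple[float, float],
    p0: float,
    cv: float,
    rho: float,
) -> tuple[float, float]:
    """Draw the (baseline, month-12) cost pair for one dyad and row."""
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    # correlated standard normals for the positive part (Gaussian copula);
    # zero indicators are independent between periods
    z1 = rng.standard_normal()
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
    u = rng.random(2)
    out = []
    for target, z, ui in zip(targets, (z1, z2), u):
        if target == 0.0 or ui < p0:
            out.append(0.0)
        else:
            mu = _lognormal_mu(target, p0, sigma2)
            out.append(math.exp(mu + sigma * z))
    return out[0], out[1]


def generate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the dyad roster and pre-costed utilization records.

    Returns ``(dyads, records)``: a dyad roster (dyad_id, arm,
    chcpe_category) and a utilization table in the costing engine's CSV
    dialect. Reproducible under a fixed seed; per-dyad random streams are
    keyed by dyad index, so enlarging the cohort leaves earlier dyads'
    draws unchanged.
    """
    dyad_rows, record_rows = [], []
    arms = [("cope", params.n_cope), ("usual_care", params.n_usual)]
    index = 0
    cats = sorted(params.chcpe_category_probs)
    cat_p = [params.chcpe_category_probs[c] for c in cats]
    for arm, n in arms:
        targets = params.mean_targets[arm]
        for _ in range(n):
            rng = np.random.default_rng([params.seed, index])
            dyad_id = f"D{index:04d}"
            chcpe = cats[rng.choice(len(cats), p=cat_p)]
            dyad_rows.append((dyad_id, arm, chcpe))
            for row in REPORT_ROWS:
                bl_t, m12_t = targets.get(row, (0.0, 0.0))
                if row in CONSTANT_ROWS:
                    bl, m12 = bl_t, m12_t
                else:
                    bl, m12 = _draw_row(
                        rng, (bl_t, m12_t),
                        params.zero_probability.get(row, 0.0),
                        params.cv_for(row), params.within_dyad_corr,
                    )
                for period, cost in (("baseline", bl), ("month12", m12)):
                    if cost > 0.0:
                        record_rows.append(
                            (dyad_id, arm, period, _EMIT_CATEGORY[row],
                             cost, PRECOSTED)
                        )
            index += 1
    dyads = pd.DataFrame(dyad_rows, columns=["dyad_id", "arm", "chcpe_category"])
    records = pd.DataFrame(
        record_rows,
        columns=["dyad_id", "arm", "period", "category", "quantity", "attribute"],
    )
    return dyads, records


def generate_wtp(params: CohortParams, dyads: pd.DataFrame) -> pd.DataFrame:
    """Per-dyad willingness to pay per program session, by benefit category."""
    support = np.asarray(params.wtp_support, dtype=float)
    rows = []
    for i, r in enumerate(dyads.itertuples(index=False)):
        rng = np.random.default_rng([params.seed, 104729, i])
        probs = params.wtp_probs[int(r.chcpe_category)]
        wtp = support[rng.choice(len(support), p=np.asarray(probs))]
        rows.append((r.dyad_id, int(r.chcpe_category), wtp))
    return pd.DataFrame(rows, columns=["dyad_id", "chcpe_category", "wtp_per_session"])


def generate_delivery_components(
    params: CohortParams, config: UnitCostConfig
) -> pd.DataFrame:
    """Per-dyad intervention delivery components for the sensitivity module.

    Seven components are the known per-dyad program costs; travel time and
    mileage are rebuilt from per-visit round-trip minutes and miles drawn
    per dyad (lognormal, CV 0.3) with means chosen so the expected costs
    equal the published components. The per-visit detail is what the
    travel-cap scenarios act on.
    """
    cope = params.mean_targets["cope"]
    wage = config.wage_2019(config.occupation_wage_table["occupational_therapist"])
    visits = params.ot_visits
    mean_minutes = cope["travel_time"][1] * 60.0 / (visits * wage)
    mean_miles = cope["mileage"][1] / (visits * config.mileage_rate)
    sigma2 = math.log(1.0 + 0.3 ** 2)
    sigma = math.sqrt(sigma2)
    rows = []
    for i in range(params.n_cope):
        rng = np.random.default_rng([params.seed, 7919, i])
        minutes = math.exp(math.log(mean_minutes) - sigma2 / 2 + sigma * rng.standard_normal())
        miles = math.exp(math.log(mean_miles) - sigma2 / 2 + sigma * rng.standard_normal())
        row = {"dyad_id": f"D{i:04d}"}
        for comp in ("formal_staff_training", "screening", "ot_apn_client_time",
                     "ot_apn_outside_work", "debriefing", "supplies",
                     "lab_testing"):
            row[comp] = cope[comp][1]
        row["travel_time"] = visits * (minutes / 60.0) * wage
        row["mileage"] = visits * miles * config.mileage_rate
        row["visits"] = visits
        row["travel_minutes_per_visit"] = minutes
        row["travel_miles_per_visit"] = miles
        rows.append(row)
    return pd.DataFrame(rows)


def true_did(params: CohortParams) -> dict[str, float]:
    """Analytic difference-in-difference implied by the mean targets."""
    out = {}
    for row in REPORT_ROWS:
        c_bl, c_m12 = params.mean_targets["cope"].get(row, (0.0, 0.0))
        u_bl, u_m12 = params.mean_targets["usual_care"].get(row, (0.0, 0.0))
        out[row] = (c_m12 - c_bl) - (u_m12 - u_bl)
    out["total"] = sum(out[row] for row in REPORT_ROWS)
    return out
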