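"""Univariate sensitivity (tornado) analysis of intervention delivery costs.

Five efficiency scenarios probe how much cheaper the program could be:

* ``training_zero`` — interventionists arrive already trained, so formal
  staff training costs nothing;
* ``omit_external_calls`` — telephone work outside program delivery is
  replaced by asynchronous messages (a configurable share of the
  "work outside intervention" line, all of it by default);
* ``cap_travel_time_40min`` — round-trip travel time per visit capped at
  40 minutes (a smaller service area);
* ``cap_travel_miles_20`` — round-trip mileage per visit capped at 20
  miles;
* ``half_debriefing`` — fidelity debriefings at half cost once
  interventionists are proficient.

``min_all`` applies all five at once, giving the minimum delivery cost.
Caps act per visit, so they bind only for dyads whose drawn per-visit
travel exceeds the cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ParameterError

COMPONENT_COLUMNS = (
    "formal_staff_training",
    "screening",
    "ot_apn_client_time",
    "ot_apn_outside_work",
    "travel_time",
    "mileage",
    "debriefing",
    "supplies",
    "lab_testing",
)

ADJUSTMENTS = frozenset({
    "training_zero",
    "omit_external_calls",
    "cap_travel_time_40min",
    "cap_travel_miles_20",
    "half_debriefing",
})


@dataclass(frozen=True)
class Scenario:
    name: str
    adjustments: frozenset

    def __post_init__(self) -> None:
        if not self.adjustments:
            raise ParameterError("a scenario needs at least one adjustment")
        unknown = self.adjustments - ADJUSTMENTS
        if unknown:
            raise ParameterError(f"unknown adjustment(s): {sorted(unknown)}")


DEFAULT_SCENARIOS = tuple(
    [Scenario(a, frozenset({a})) for a in sorted(ADJUSTMENTS)]
    + [Scenario("min_all", frozenset(ADJUSTMENTS))]
)


def apply_scenario(
    components: pd.DataFrame,
    scenario: Scenario,
    external_call_fraction: float = 1.0,
    travel_minutes_cap: float = 40.0,
    travel_miles_cap: float = 20.0,
) -> pd.DataFrame:
    """Return per-dyad components with the scenario's adjustments applied.

    Travel caps rescale the travel cost lines by the capped-to-observed
    per-visit ratio, which equals recosting capped minutes (miles) at the
    same wage (mileage rate). Components the scenario does not touch are
    unchanged.
    """
    if not 0.0 <= external_call_fraction <= 1.0:
        raise ParameterError("external_call_fraction must be in [0, 1]")
    out = components.copy()
    adj = scenario.adjustments
    if "training_zero" in adj:
        out["formal_staff_training"] = 0.0
    if "half_debriefing" in adj:
        out["debriefing"] = out["debriefing"] * 0.5
    if "omit_external_calls" in adj:
        out["ot_apn_outside_work"] = (
            out["ot_apn_outside_work"] * (1.0 - external_call_fraction)
        )
    if "cap_travel_time_40min" in adj:
        m = out["travel_minutes_per_visit"]
        ratio = (m.clip(upper=travel_minutes_cap) / m).where(m > 0, 1.0)
        out["travel_time"] = out["travel_time"] * ratio
        out["travel_minutes_per_visit"] = m.clip(upper=travel_minutes_cap)
    if "cap_travel_miles_20" in adj:
        m = out["travel_miles_per_visit"]
        ratio = (m.clip(upper=travel_miles_cap) / m).where(m > 0, 1.0)
        out["mileage"] = out["mileage"] * ratio
        out["travel_miles_per_visit"] = m.clip(upper=travel_miles_cap)
    return out


def delivery_total(components: pd.DataFrame) -> pd.Series:
    return components[list(COMPONENT_COLUMNS)].sum(axis=1)


def tornado(
    components: pd.DataFrame,
    scenarios=DEFAULT_SCENARIOS,
    external_call_fraction: float = 1.0,
) -> pd.DataFrame:
    """Mean per-dyad cost reduction for each scenario, largest first.

    Also reports the adjusted mean delivery cost. Since the five
    univariate scenarios touch disjoint component lines, the ``min_all``
    reduction equals the sum of the single-scenario reductions.
    """
    if not scenarios:
        raise ParameterError("at least one scenario is required")
    base = delivery_total(components).mean()
    rows = []
    for scenario in scenarios:
        adjusted = apply_scenario(components, scenario,
                                  external_call_fraction=external_call_fraction)
        mean_cost = delivery_total(adjusted).mean()
        rows.append({
            "scenario": scenario.name,
            "mean_cost": mean_cost,
            "mean_reduction": base - mean_cost,
        })
    out = pd.DataFrame(rows).sort_values(
        "mean_reduction", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    out.insert(1, "base_mean_cost", base)
    return out
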