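"""Cost-category taxonomy.

Utilization records carry one of 25 fine-grained categories; costed lines
are reported under 24 report rows (long-term and rehabilitation nursing-home
stays are costed separately but reported as a single "nursing home stays"
row). Report rows group into four blocks — intervention/usual-care
delivery, direct health-care services, formal care and social services,
and indirect caregiver time — whose subtotals plus a grand total make up
the cost report.
"""

# --- utilization categories -------------------------------------------------

DELIVERY_CATEGORIES = (
    "formal_staff_training",
    "screening",
    "ot_apn_client_time",
    "ot_apn_outside_work",
    "travel_time",
    "mileage",
    "debriefing",
    "supplies",
    "lab_testing",
    "care_plan",
)

HEALTH_CATEGORIES = (
    "nursing_home_long_term",
    "nursing_home_rehab",
    "respite",
    "inpatient",
    "ed",
    "outpatient",
    "medications",
    "dme",
    "visiting_nurse",
    "hha",
)

FORMAL_CATEGORIES = (
    "social_worker",
    "meals",
    "transportation",
    "adult_day",
)

INDIRECT_CATEGORIES = ("caregiver_time",)

ALL_CATEGORIES = (
    DELIVERY_CATEGORIES + HEALTH_CATEGORIES + FORMAL_CATEGORIES + INDIRECT_CATEGORIES
)

#: categories whose costing rule needs a lookup key in ``attribute``
ATTRIBUTE_REQUIRED = {
    "inpatient",        # diagnosis code
    "ed",               # diagnosis code
    "nursing_home_long_term",  # facility
    "medications",      # drug key
    "outpatient",       # visit type
    "dme",              # item
}

#: sentinel attribute marking a record whose quantity is already in 2019 USD
PRECOSTED = "precosted"

# --- report rows ------------------------------------------------------------

_REPORT_MAP = {c: c for c in ALL_CATEGORIES}
_REPORT_MAP["nursing_home_long_term"] = "nursing_home"
_REPORT_MAP["nursing_home_rehab"] = "nursing_home"


def report_category(category: str) -> str:
    """Map a utilization category to its report row (deterministic)."""
    return _REPORT_MAP[category]


DELIVERY_ROWS = DELIVERY_CATEGORIES
HEALTH_ROWS = (
    "nursing_home",
    "respite",
    "inpatient",
    "ed",
    "outpatient",
    "medications",
    "dme",
    "visiting_nurse",
    "hha",
)
FORMAL_ROWS = FORMAL_CATEGORIES
INDIRECT_ROWS = INDIRECT_CATEGORIES

REPORT_ROWS = DELIVERY_ROWS + HEALTH_ROWS + FORMAL_ROWS + INDIRECT_ROWS

SUBTOTALS = {
    "subtotal_delivery": DELIVERY_ROWS,
    "subtotal_health_care": HEALTH_ROWS,
    "subtotal_formal_social": FORMAL_ROWS,
    "subtotal_caregiver_time": INDIRECT_ROWS,
}

GRAND_TOTAL = "total"

#: rows carrying a rank-sum p-value in the default 18-test family:
#: the 15 report rows with between-dyad variation (care plan, the nine
#: health-service rows, the four formal/social rows, caregiver time) plus
#: the health-care and formal/social subtotals and the grand total.
TESTED_COMPONENT_ROWS = (
    ("care_plan",) + HEALTH_ROWS + FORMAL_ROWS + INDIRECT_ROWS
)
TESTED_SUBTOTAL_ROWS = ("subtotal_health_care", "subtotal_formal_social", GRAND_TOTAL)

ARMS = ("cope", "usual_care")
PERIODS = ("baseline", "month12")
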