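"""Published per-dyad mean costs from the COPE-CT cost study.

These are the reported 2019-USD group means (130 COPE dyads, 120
usual-care dyads) for each report row at baseline (BL) and month 12 (M12),
together with the printed difference-in-difference (DID) column and
subtotals. They serve two roles:

* calibration targets for the synthetic cohort generator, and
* inputs to the payment-model chain, which starts from the nine printed
  COPE delivery components.

All values are exactly as printed in the trial's cost report; rows printed
to the dollar are stored to the dollar.
"""

from .categories import REPORT_ROWS

# (baseline, month12) mean per-dyad cost, 2019 USD
PUBLISHED_MEANS: dict[str, dict[str, tuple[float, float]]] = {
    "cope": {
        "formal_staff_training": (0.00, 218.75),
        "screening": (0.00, 3.87),
        "ot_apn_client_time": (0.00, 677.48),
        "ot_apn_outside_work": (0.00, 59.79),
        "travel_time": (0.00, 402.79),
        "mileage": (0.00, 170.63),
        "debriefing": (0.00, 177.43),
        "supplies": (0.00, 60.34),
        "lab_testing": (0.00, 340.97),
        "care_plan": (1362.0, 1297.0),
        "nursing_home": (3023.0, 6695.0),
        "respite": (98.05, 74.71),
        "inpatient": (6548.0, 6077.0),
        "ed": (4829.0, 4089.0),
        "outpatient": (239.96, 1731.0),
        "medications": (16827.0, 10407.0),
        "dme": (148.97, 69.59),
        "visiting_nurse": (45.87, 23.25),
        "hha": (411.48, 341.74),
        "social_worker": (7.79, 44.01),
        "meals": (56.50, 36.05),
        "transportation": (3.36, 4.01),
        "adult_day": (280.37, 259.11),
        "caregiver_time": (5094.0, 3361.0),
    },
    "usual_care": {
        "formal_staff_training": (0.00, 0.00),
        "screening": (0.00, 3.87),
        "ot_apn_client_time": (0.00, 0.00),
        "ot_apn_outside_work": (0.00, 0.00),
        "travel_time": (0.00, 0.00),
        "mileage": (0.00, 0.00),
        "debriefing": (0.00, 0.00),
        "supplies": (0.00, 0.14),
        "lab_testing": (0.00, 0.00),
        "care_plan": (1277.0, 1274.0),
        "nursing_home": (1334.0, 6668.0),
        "respite": (37.94, 25.30),
        "inpatient": (6091.0, 8345.0),
        "ed": (4104.0, 6261.0),
        "outpatient": (255.08, 1880.0),
        "medications": (18192.0, 13240.0),
        "dme": (175.68, 79.56),
        "visiting_nurse": (32.90, 28.59),
        "hha": (456.37, 355.52),
        "social_worker": (4.03, 45.48),
        "meals": (39.16, 31.40),
        "transportation": (3.63, 3.94),
        "adult_day": (330.19, 292.64),
        "caregiver_time": (5256.0, 3368.0),
    },
}

# printed DID (95% CI omitted) per report row
PUBLISHED_DID: dict[str, float] = {
    "formal_staff_training": 218.75,
    "screening": 0.00,
    "ot_apn_client_time": 677.48,
    "ot_apn_outside_work": 59.79,
    "travel_time": 402.79,
    "mileage": 170.63,
    "debriefing": 177.43,
    "supplies": 60.21,
    "lab_testing": 340.97,
    "care_plan": -61.21,
    "nursing_home": -1662.0,
    "respite": -10.70,
    "inpatient": -2725.0,
    "ed": -2897.0,
    "outpatient": -133.93,
    "medications": -1467.0,
    "dme": 16.74,
    "visiting_nurse": -18.31,
    "hha": 31.11,
    "social_worker": -5.22,
    "meals": -12.70,
    "transportation": 0.34,
    "adult_day": 16.28,
    "caregiver_time": 154.32,
}

# printed subtotal DIDs and grand total
PUBLISHED_SUBTOTAL_DID: dict[str, float] = {
    "subtotal_delivery": 2047.0,
    "subtotal_health_care": -8867.0,
    "subtotal_formal_social": -1.29,
    "subtotal_caregiver_time": 154.32,
}
PUBLISHED_TOTAL_DID = -6667.0

#: the nine COPE delivery components (month-12 COPE means, excluding the
#: care-plan row which enters the payment model separately as a monthly
#: care-management cost)
DELIVERY_COMPONENTS: dict[str, float] = {
    "formal_staff_training": 218.75,
    "screening": 3.87,
    "ot_apn_client_time": 677.48,
    "ot_apn_outside_work": 59.79,
    "travel_time": 402.79,
    "mileage": 170.63,
    "debriefing": 177.43,
    "supplies": 60.34,
    "lab_testing": 340.97,
}

assert set(PUBLISHED_MEANS["cope"]) == set(REPORT_ROWS)
assert set(PUBLISHED_DID) == set(REPORT_ROWS)
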