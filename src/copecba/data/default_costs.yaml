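fringe_rate: 0.313
cost_to_charge_divisor: 3.4
mileage_rate: 0.58
visiting_nurse_minutes: 30.0
hha_minutes: 60.0
respite_hha_hours_per_day: 8.0
adult_day_rate: 12.8
adult_day_hours_per_day: 8.0
meal_cost: 11.92
transport_fare: 1.5
social_worker_wage: 31.09
social_worker_minutes: 60.0
caregiving_cap_hours_per_day: 16.0
caregiving_weeks_per_period: 52.0
rehab_per_diem: 450.0
hha_wage: 10.87
visiting_nurse_wage: 34.14
cm_cost_month: 108.1
wage_year: 2015
target_year: 2019
occupation_wage_table:
  registered_nurse: 34.14
  occupational_therapist: 38.57
  advanced_practice_nurse: 48.68
  teacher: 27.35
  office_clerk: 15.29
  retail_salesperson: 12.79
  manager: 55.22
  accountant: 36.19
inflation_index:
  2015: 237.017
  2016: 240.007
  2017: 245.12
  2018: 251.107
  2019: 255.657
nursing_home_daily_rates:
  facility_a: 400.0
  facility_b: 330.0
  facility_c: 465.0
charge_table:
  I50.9: 34000.0
  N39.0: 21000.0
  S72.0: 51000.0
  F03.90: 18000.0
  J18.9: 28000.0
  R41.0: 15300.0
cpt_cost_table:
  primary_care: 104.0
  geriatrician: 130.0
  neurologist: 200.0
  psychiatrist: 180.0
  psychologist: 120.0
  physical_therapist: 85.0
  occupational_therapist: 90.0
  speech_language_pathologist: 95.0
wac_table:
  donepezil_10mg: 1.25
  memantine_10mg: 3.8
  quetiapine_25mg: 0.6
  sertraline_50mg: 0.35
  lisinopril_10mg: 0.18
dme_table:
  walker: 65.0
  wheelchair: 240.0
  hospital_bed: 810.0
  shower_chair: 45.0
  grab_bars: 30.0
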