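chcpe_category,care_plan_limit_month,cope_cost_month,cope_admin_cost_month,cm_cost_month,annual_cost_with_cm,pct_consumed
2,3143.0,528.01,739.22,108.1,4254.0,11.28
3,6286.0,528.01,739.22,108.1,4254.0,5.64
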