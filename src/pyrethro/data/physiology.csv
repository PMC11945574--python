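age_group,body_weight_gm,body_weight_gsd,daily_urine_volume,daily_creatinine
<6,18.0,1.25,0.60,0.35
6-11,31.0,1.30,0.80,0.60
12-19,62.0,1.25,1.20,1.30
20-65,80.0,1.22,1.50,1.50
>65,78.0,1.20,1.40,1.20
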