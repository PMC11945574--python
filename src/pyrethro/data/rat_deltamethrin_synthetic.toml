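# SYNTHETIC rat deltamethrin kinetic parameterization.
# A stand-in constructed to give literature-plausible rat kinetics (slow oral
# absorption, high lipophilicity, limited brain penetration) for exercising
# the systemic point-of-departure machinery.  It is not a transcription of any
# published rat model and its dose metrics are not calibrated to reported
# values.

[deltamethrin]
ka = 0.35
kf = 0.55
fu = 0.1
cl_metabolic = 1.2
pa_brain = 0.025
k_urine = 0.12

[deltamethrin.partition]
liver = 3.5
fat = 100.0
brain = 2.0
rich = 2.5
slow = 1.8

[physiology]
body_weight = 0.3          # kg
daily_urine_volume = 0.015 # L/day
daily_creatinine = 0.005   # g/day
cardiac_output = 2.2       # L plasma/h
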