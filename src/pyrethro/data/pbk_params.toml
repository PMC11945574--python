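# Default human kinetic parameters per parent compound.
# Cyfluthrin and cypermethrin isomers reuse deltamethrin's chemical-specific
# values (no compound-specific human TK data); permethrin isomers carry their
# own absorption/clearance values.  Urinary elimination rates correspond to
# metabolite urinary half-lives of roughly 6-13 h.

[deltamethrin]
ka = 0.6            # 1/h, oral absorption from gut lumen
kf = 0.25           # 1/h, fecal elimination from gut lumen
fu = 0.3            # unbound fraction in plasma
cl_metabolic = 120.0 # L/h hepatic clearance (venous equilibration)
pa_brain = 2.0      # L/h brain permeability-area product
k_urine = 0.08      # 1/h, first-order urinary elimination of metabolites

[deltamethrin.partition]
liver = 4.0
fat = 60.0
brain = 2.5
rich = 3.0
slow = 2.0

[cis-permethrin]
ka = 0.8
kf = 0.35
fu = 0.3
cl_metabolic = 150.0
pa_brain = 2.0
k_urine = 0.09

[cis-permethrin.partition]
liver = 4.5
fat = 70.0
brain = 2.8
rich = 3.2
slow = 2.1

[trans-permethrin]
ka = 0.9
kf = 0.30
fu = 0.3
cl_metabolic = 220.0
pa_brain = 2.0
k_urine = 0.10

[trans-permethrin.partition]
liver = 4.5
fat = 70.0
brain = 2.8
rich = 3.2
slow = 2.1

[cis-cypermethrin]
ka = 0.6
kf = 0.25
fu = 0.3
cl_metabolic = 120.0
pa_brain = 2.0
k_urine = 0.08

[cis-cypermethrin.partition]
liver = 4.0
fat = 60.0
brain = 2.5
rich = 3.0
slow = 2.0

[trans-cypermethrin]
ka = 0.6
kf = 0.25
fu = 0.3
cl_metabolic = 120.0
pa_brain = 2.0
k_urine = 0.08

[trans-cypermethrin.partition]
liver = 4.0
fat = 60.0
brain = 2.5
rich = 3.0
slow = 2.0

[cis-cyfluthrin]
ka = 0.6
kf = 0.25
fu = 0.3
cl_metabolic = 120.0
pa_brain = 2.0
k_urine = 0.08

[cis-cyfluthrin.partition]
liver = 4.0
fat = 60.0
brain = 2.5
rich = 3.0
slow = 2.0

[trans-cyfluthrin]
ka = 0.6
kf = 0.25
fu = 0.3
cl_metabolic = 120.0
pa_brain = 2.0
k_urine = 0.08

[trans-cyfluthrin.partition]
liver = 4.0
fat = 60.0
brain = 2.5
rich = 3.0
slow = 2.0
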