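id,role,molar_mass,measured
3PBA,metabolite,214.22,True
FPBA,metabolite,232.21,True
DBCA,metabolite,297.95,True
cis-DCCA,metabolite,209.07,True
trans-DCCA,metabolite,209.07,True
4OH-3PBA,metabolite,230.22,False
PBAlc,metabolite,200.23,False
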