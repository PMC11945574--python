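compound,metabolite,phi
deltamethrin,DBCA,0.43
deltamethrin,3PBA,0.19
deltamethrin,4OH-3PBA,0.05
cis-permethrin,cis-DCCA,0.42
cis-permethrin,3PBA,0.30
cis-permethrin,4OH-3PBA,0.06
trans-permethrin,trans-DCCA,0.62
trans-permethrin,3PBA,0.33
trans-permethrin,PBAlc,0.03
cis-cypermethrin,cis-DCCA,0.35
cis-cypermethrin,3PBA,0.28
cis-cypermethrin,4OH-3PBA,0.05
trans-cypermethrin,trans-DCCA,0.50
trans-cypermethrin,3PBA,0.32
trans-cypermethrin,PBAlc,0.03
cis-cyfluthrin,cis-DCCA,0.35
cis-cyfluthrin,FPBA,0.25
trans-cyfluthrin,trans-DCCA,0.48
trans-cyfluthrin,FPBA,0.27
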