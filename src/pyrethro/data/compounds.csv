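id,role,molar_mass,parent_group,isomer_fraction
deltamethrin,compound,505.20,deltamethrin,1.0
cis-permethrin,compound,391.29,permethrin,0.4
trans-permethrin,compound,391.29,permethrin,0.6
cis-cypermethrin,compound,416.30,cypermethrin,0.4
trans-cypermethrin,compound,416.30,cypermethrin,0.6
cis-cyfluthrin,compound,434.29,cyfluthrin,0.4
trans-cyfluthrin,compound,434.29,cyfluthrin,0.6
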