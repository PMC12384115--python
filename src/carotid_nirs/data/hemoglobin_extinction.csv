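wavelength_nm,chromophore,epsilon_cm1_per_M
670,HbO2,298.0
670,Hb,2795.0
780,HbO2,740.0
780,Hb,1075.0
808,HbO2,830.0
808,Hb,740.0
850,HbO2,1058.0
850,Hb,691.0
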