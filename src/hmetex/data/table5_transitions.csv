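# DSC phase-transition parameters at Xw = 0.6: peak temperature, melting
# enthalpy (peak area), onset and end temperatures, and the total applied
# enthalpy from 20 degC to Tend.  sd columns are between-replicate spreads.
protein,Tm_C,Tm_sd,dHm_J_per_g,dHm_sd,Tonset_C,Tonset_sd,Tend_C,Tend_sd,dH_DSC_J_per_g,dH_DSC_sd
SPC Procon,115.9,4.7,834.1,13.5,86.0,3.4,129.9,3.5,1205,29.6
SPI Wilpro,114.6,0.4,673.2,31.7,83.4,1.7,126.5,2.3,1036,8.7
PPI Pisane,117.9,0.2,781.4,1.2,90.0,2.8,133.6,0.6,1125,41.4
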