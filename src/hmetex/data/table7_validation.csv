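# Validation campaign: process settings, measured responses, reference EMH
# temperature, sensory texture label and the reference two-decimal TI.
protein,run_id,X1_rpm,X2_moisture_pct,X3_kg_per_h,X4_barrel_C,pressure_bar,SME_Wh_per_kg,Tin_C,Tin_calc_C,texture_label,TI_ref
SPC Procon,No.1,400,60,13,130,40.00,42.47,125.17,128.00,poorly-textured,0.99
SPC Procon,No.2,400,60,13,140,38.50,40.00,137.20,128.00,well-textured,1.03
SPI Wilpro,No.1,400,60,13,120,30.18,33.72,109.59,124.15,poorly-textured,0.95
SPI Wilpro,No.2,400,60,13,130,41.10,48.90,129.70,124.15,well-textured,1.02
PPI Pisane,No.1,400,60,9,130,16.60,16.20,120.10,120.40,textured,1.00
PPI Pisane,No.2,400,60,9,155,12.40,11.77,134.15,120.40,well-textured,1.05
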