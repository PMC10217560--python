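# Validation-study design: two runs per protein at 60% moisture with
# deliberately different barrel temperatures.
protein,run_id,screw_speed_rpm,moisture_pct,mass_flow_kg_per_h,barrel_temperature_C
SPC Procon,No.1,400,60,13,130
SPC Procon,No.2,400,60,13,140
SPI Wilpro,No.1,400,60,13,120
SPI Wilpro,No.2,400,60,13,130
PPI Pisane,No.1,400,60,9,130
PPI Pisane,No.2,400,60,9,155
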