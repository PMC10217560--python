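# Reference minimum texturization (extrusion melting hurdle) temperatures
# at 60% moisture, solved from the TI = 1 enthalpy balance.
protein,moisture_pct,EMH_C
SPC Procon,60,128.00
SPI Wilpro,60,124.15
PPI Pisane,60,120.40
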