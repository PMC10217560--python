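# Multiple-linear-regression cp models, cp = y0 + a*Xw + b*T in J/(kg K),
# fitted on Xw in [0.6, 0.7] and T in [40, 115] degC.  se is the residual
# standard error of the fit.
protein,y0,a,b,r2,se
SPC Procon,1675.38,2408.56,4.6196,0.96,24.16
SPI Wilpro,1867.48,2393.64,2.6710,0.92,29.41
PPI Pisane,1939.57,1939.20,4.6319,0.94,26.41
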