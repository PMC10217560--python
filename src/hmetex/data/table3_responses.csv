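# SPC Alpha 8 CCD campaign with system responses and texture assessment.
# X3 for run 25 is kept as logged (14.25 kg/h).  SME zeros mean "not
# recordable" (melt viscosity too low for measurable shear), not zero
# mechanical input; the loader flags them as unmeasured.  SI is N/A where
# no slice-shear-force specimen could be taken.
run_id,X1_rpm,X2_moisture_pct,X3_kg_per_h,X4_barrel_C,Y1_material_C,Y2_pressure_bar,Y3_SME_Wh_per_kg,SI,texture_label
1,400,60,13,160,133.10,21.06,30.68,1.64,well-textured
2,400,60,6,120,102.57,16.20,35.34,1.27,poorly-textured
3,175,65,9.5,140,113.49,10.54,9.28,1.33,textured
4,220,70,6,120,93.90,3.84,0,N/A,poorly-textured
5,310,65,9.5,140,116.84,7.96,9.78,1.14,textured
6,400,70,13,160,120.11,6.63,6.09,1.25,textured
7,445,65,9.5,140,113.15,8.40,13.98,1.42,textured
8,400,60,6,160,128.48,15.95,26.74,1.57,well-textured
9,400,70,6,120,92.62,3.80,0,N/A,poorly-textured
10,220,70,6,160,121.53,4.03,0,1.25,poorly-textured
11,310,57.5,9.5,140,117.76,28.80,32.75,1.31,well-textured
12,310,65,9.5,140,114.44,8.94,8.62,1.23,textured
13,400,70,6,160,117.73,4.47,0,1.29,poorly-textured
14,220,60,13,120,101.80,22.47,17.86,1.11,poorly-textured
15,310,65,4.25,140,114.22,7.98,9.81,1.22,textured
16,220,70,13,120,96.28,6.84,0,N/A,poorly-textured
17,310,65,9.5,170,137.76,9.69,9.71,1.77,well-textured
18,220,60,6,120,106.82,20.96,25.34,1.43,poorly-textured
19,400,60,13,120,104.85,16.73,26.20,1.14,poorly-textured
20,310,72.5,9.5,140,105.67,1.61,0,N/A,poorly-textured
21,310,65,9.5,140,110.95,6.67,6.72,1.26,textured
22,310,65,9.5,110,90.42,10.49,11.85,N/A,poorly-textured
23,220,70,13,160,122.68,7.51,1.73,1.26,textured
24,220,60,13,160,130.22,19.08,22.70,1.62,well-textured
25,310,65,14.25,140,111.89,12.91,13.51,1.41,textured
26,220,60,6,160,133.58,17.45,18.70,1.60,well-textured
27,400,70,13,120,98.18,5.44,2.38,N/A,poorly-textured
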