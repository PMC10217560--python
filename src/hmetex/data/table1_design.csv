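# 27-run central composite design for the SPC Alpha 8 extrusion campaign
# (4 factors, alpha = 1.5, 3 centre replicates), in the campaign's run order.
# Provenance note: the published design prints the high axial mass-flow level
# of run 25 as 14.25 kg/h, which is inconsistent with its mirror point
# (4.25 = 9.5 - 1.5*3.5 fixes alpha = 1.5, implying 14.75); the value below
# is the internally consistent 14.75.
run_id,screw_speed_rpm,moisture_pct,mass_flow_kg_per_h,barrel_temperature_C
1,400,60,13,160
2,400,60,6,120
3,175,65,9.5,140
4,220,70,6,120
5,310,65,9.5,140
6,400,70,13,160
7,445,65,9.5,140
8,400,60,6,160
9,400,70,6,120
10,220,70,6,160
11,310,57.5,9.5,140
12,310,65,9.5,140
13,400,70,6,160
14,220,60,13,120
15,310,65,4.25,140
16,220,70,13,120
17,310,65,9.5,170
18,220,60,6,120
19,400,60,13,120
20,310,72.5,9.5,140
21,310,65,9.5,140
22,310,65,9.5,110
23,220,70,13,160
24,220,60,13,160
25,310,65,14.75,140
26,220,60,6,160
27,400,70,13,120
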