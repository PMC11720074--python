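variant_id,label,rs_id,dg_mean,dg_sd,n_snapshots,kd_printed_uM,flagged_printed
WT,hNav1.5 wild-type,,−8.8912,2.4548,50,0.287734,False
N927S,N927S,rs199473589,−11.6432,2.2684,50,0.002719,True
N932K,N932K,rs2125871972,−12.0383,2.3951,50,0.001392,True
N932S,N932S,rs2061582195,−14.0262,2.1880,50,0.000048,True
L935V,L935V,,−10.3997,2.8926,50,0.022348,True
S1458Y,S1458Y,rs199473253,−11.8620,2.0938,50,0.001877,True
N1463K,N1463K,rs1064795922,−11.5250,1.9787,50,0.003322,True
N1463Y,N1463Y,rs199473614,−9.9455,2.3765,50,0.048236,True
M1766R,M1766R,rs752476527,−9.4284,2.0207,50,0.115821,True
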