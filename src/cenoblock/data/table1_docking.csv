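variant_id,label,rs_id,rep1,rep2,rep3,kd_printed_uM,flagged_printed
WT,hNav1.5 wild-type,,−5.479,−5.523,−5.489,90.37,False
N927S,N927S,rs199473589,−5.087,−5.033,−6.741,73.33,True
N932K,N932K,rs2125871972,−5.008,−4.979,−5.022,208.66,False
N932S,N932S,rs2061582195,−5.096,−5.080,−4.903,200.57,False
L935V,L935V,,−4.825,−4.807,−4.862,279.08,False
S1458Y,S1458Y,rs199473253,−5.102,−5.137,−5.091,174.07,False
N1463K,N1463K,rs1064795922,−6.110,−6.253,−6.227,27.62,True
N1463Y,N1463Y,rs199473614,−6.324,−5.536,−6.159,38.13,True
M1766R,M1766R,rs752476527,−6.229,−6.068,−5.783,36.84,True
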